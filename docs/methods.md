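# Methods note

This note records the model implemented by `spreadday`, the assumptions each
stage makes, the default parameters and why they were chosen, what the
synthetic-data generator does and does not emulate, the numerical choices,
and the known limitations. It states no empirical result that the package
does not itself compute.

## 1. FWI engine (`spreadday.fwi`)

The six FWI System indices are updated daily from noon weather
(temperature °C, relative humidity %, 10 m wind km/h, 24 h precipitation mm).
Each moisture code (FFMC, DMC, DC) applies a rain phase when precipitation
exceeds its trigger (0.5 mm for FFMC, 1.5 mm for DMC, 2.8 mm for DC),
followed by a drying/wetting phase; DMC and DC use month-indexed day-length
factors for the northern band. The behaviour indices (ISI, BUI, FWI) are
closed-form functions of the codes and wind.

**Assumptions and defaults.**

- Startup codes are the conventional spring triple (FFMC 85, DMC 6, DC 15);
  series restart each calendar year (`restart_each_year=True`). No drought
  carry-over between years is modelled.
- Day-length factors use the standard 46.6° N–66.5° N band; `latitude_adjust`
  is off by default because the synthetic domain is a single mid-boreal
  latitude (55° N).
- Inputs are validated (RH ∈ [0, 100], non-negative wind and precipitation);
  FFMC is bounded in [0, 101] by construction.

One behavioural subtlety worth recording: ISI is monotone non-decreasing in
wind *at fixed fine-fuel moisture*, but not through a full daily update —
wind also speeds FFMC drying, and when FFMC starts above its equilibrium a
small wind increase can lower day-end FFMC enough to outweigh the direct
wind term in ISI. The property tests therefore pin FFMC.

The engine is checked against an independently coded scalar reference
implementation of the same equations (`tests/reference_fwi.py`), written
before the engine, to ≤ 1e−6 per index over a year of random weather.

## 2. Growth mapping (`spreadday.growth`)

The final fire perimeter is rasterized by testing cell centres for
containment. Each cell receives the detection date of its nearest usable
hotspot (`scipy.spatial.cKDTree`); equidistant ties go to the **earlier**
date, reflecting that fire must have passed through earlier-burned ground.
Cells sharing a date form one daily-growth record whose area is the cell
count times the cell area.

**Assumptions and defaults.**

- `cell_size=30` m: fine enough that boundary-cell quantization error is
  small relative to the ≥ 50 ha minimum fire size; coarser cells are
  supported and used in tests where speed matters.
- A hotspot is *usable* if it lies within half its sensor footprint of the
  perimeter (MODIS 500 m, VIIRS 187.5 m); more distant detections are
  treated as noise or neighbouring fires and ignored.
- Fires under 50 ha are rejected: with only a handful of detections the
  daily decomposition is not meaningful.
- An optional inverse-distance-weighted date surface (`method="idw"`) gives
  a smoothed day-of-burn interpolation; nearest-hotspot assignment is the
  default because it is the convention the oracle tests pin down.

Area is conserved exactly across the daily decomposition (cells partition
the raster); the rasterized total differs from the polygon area only by
boundary-cell quantization, bounded by perimeter-length/cell-size cells.

## 3. Weather pairing (`spreadday.pairing`)

Grid-point index values are paired to each daily-growth footprint by
regression kriging: a linear elevation trend (`np.polyfit`) is removed, the
residuals are kriged to the footprint cells, and the trend is added back at
the cells' elevations.

**Assumptions and defaults.**

- Grid points within 50 km of the footprint are used; if none, the search
  extends to 200 km; if still none, the pairing fails explicitly.
- The residual variogram is fit by weighted least squares (weights ∝ √pair
  count) over spherical, exponential and Gaussian models, binned to half the
  maximum separation; the best model by weighted RSS is used.
- At least 4 grid points are required (`MIN_KRIGING_POINTS=4`); below that,
  or when variogram fitting fails (e.g. co-located points), the code falls
  back to inverse-distance weighting, and when residuals are numerically
  zero the elevation trend alone is used ("trend" path). The method actually
  used is reported with the result.
- Aggregation over footprint cells: arithmetic mean for FFMC, DMC, DC, ISI,
  BUI; **median** for FWI (robust to the heavy right tail of FWI across a
  footprint). Seasons are labelled MAM/JJA/SON; winter months carry no
  label.

## 4. Threshold estimation (`spreadday.thresholds`)

The cumulative area-burned fraction along a variable (ties merged, final
value exactly 1) is smoothed with a penalized cubic B-spline (basis
dimension 10, second-difference penalty, smoothing parameter chosen by GCV
over 25 log-spaced values in [1e−6, 1e4]), projected to a monotone curve by
isotonic regression, evaluated on a 1000-point grid, and its 0.5 crossing
refined by bisection. That crossing is the spread-day threshold.

- Degenerate inputs are handled explicitly: a single distinct value returns
  that value; fewer than 5 distinct values use the area-weighted median
  directly (a spline on so few knots is unstable). The area-weighted
  quantile uses midpoint plotting positions with linear interpolation, so
  two equal masses at 80 and 90 give 85.
- Uncertainty: 100 replicates, each drawing 10 fire years without
  replacement (fewer if fewer years exist); the mean and sample s.d.
  (ddof = 1) across replicates are reported. Estimates from fewer than 30
  rows are flagged unreliable (`MIN_ROWS_PER_FIT=30`).
- Reproducibility: every (variable, stratum, season) cell gets its own RNG
  stream derived from the master seed by a hash of the cell label, so
  results are independent of evaluation order and identical across reruns.

## 5. Percentile analysis (`spreadday.percentiles`)

Percentiles use linear interpolation between order statistics (numpy's
default, type 7), with a midpoint convention for ties, so an observation
equal to the threshold contributes half its mass below. The default ladder
is 50, 55, …, 95, 99. Area above each percentile cutoff reuses the smoothed
monotone cumulative curve and the same year-resampling machinery.

## 6. Spread-day accounting (`spreadday.accounting`)

A potential spread day (PSD) is a day whose spatially aggregated index
**strictly exceeds** the threshold (a day exactly at the threshold does not
count). Daily aggregation over grid points is the mean for FFMC and ISI and
the median for FWI, mirroring the pairing conventions. The counting window
is either the calendar year or the April–October fire season. A realized
spread day (RSD) is a mapped growth day whose paired value strictly exceeds
the same threshold. The per-fire ratio RSD/PSD is undefined (NaN) when
PSD = 0; summaries report the count of such fires separately.

## 7. Reference tables (`spreadday.reference_tables`)

The module embeds the published per-ecozone spread-day thresholds,
threshold percentiles, and RSD/PSD ratios from the 2001–2021 Canadian
analysis, in long format. Summary footers are recomputed, not stored:
thresholds and ratios as the mean of the printed per-ecozone means (and of
the printed s.d. values); percentiles as the mean with **population** s.d.
(ddof = 0). These conventions were verified to reproduce the printed
summary rows exactly before being encoded.

## 8. Synthetic-data generator (`spreadday.synthetic`)

The generator produces a ground-truthed dataset: daily weather per year,
the FWI series computed from it by the package's own engine, fire
perimeters, hotspot detections, and a paired growth-day table.

**What it emulates.**

- Seasonal boreal weather: sinusoidal annual cycles with AR(1) anomalies
  for temperature, humidity and wind; Bernoulli wet days with
  gamma-distributed amounts. Defaults are tuned dry enough that each year's
  FFMC range comfortably spans values above 91, so a configured threshold
  near 89 is reachable in every year.
- Fire-day selection with known truth: each fire's growth days are matched
  to the days whose index value is nearest to draws from a Gaussian
  centred on the configured `true_threshold` (default FFMC 89.4, width 3),
  making the area-weighted median of the growth table a known target.
- Geometry: fires are concentric annuli around a random centre, one ring
  per growth day, with lognormal areas (median 150 ha, σ = 0.8) scaled to
  at least 60 ha total; area is conserved exactly by construction.
- Observation: hotspots are laid on a jittered grid (default 4 per km²)
  within each day's annulus, emulating a sensor sampling lattice, with
  per-sensor footprints and optional date jitter.
- A gridded weather product: the station series perturbed by smooth
  spatial fields plus an elevation lapse on a 25 km grid, with a smooth
  synthetic elevation surface, for exercising the pairing stage.

**What it does not emulate.** Fire shapes are circular, growth is strictly
outward and single-day rings do not interleave; hotspot detection has no
cloud gaps or false alarms; weather has no spatial advection, fronts, or
inter-station correlation structure beyond the smooth perturbation; there
is no fuel heterogeneity or suppression. The generator validates its
configuration and refuses thresholds outside the generated weather range.

## 9. Numerical choices

- GCV for the spline penalty: `n·RSS/(n − edf)²`, with the effective
  degrees of freedom from the penalized hat matrix trace.
- Isotonic projection uses `scipy.optimize.isotonic_regression`; bisection
  on the monotone grid refines the 0.5 crossing to grid resolution.
- RNG streams use `numpy.random.default_rng` with seeds derived as
  `(master · 2654435761 + crc32(label)) mod (2³¹ − 1)`, keeping all seeds
  below 2³¹.
- Kriging solves the ordinary-kriging system in semivariogram form with a
  Lagrange multiplier; zero-nugget systems reproduce their data exactly.

## 10. Limitations

- **Day-matching bias.** Matching Gaussian draws to the nearest available
  weather day biases the realized area-weighted median slightly low
  (≈ 0.2 FFMC units at the defaults), because weather days thin out near
  each year's maximum: draws above the centre snap down further than draws
  below snap up. The estimator itself is unbiased on directly constructed
  Gaussian area densities; the package documents recovery within ±0.5 and
  the tests enforce that band.
- **Observation-limited date recovery.** Per-cell burn-date recovery from
  hotspots depends strongly on detection density; with the default
  4 per km² a substantial minority of cells inherit a neighbouring day's
  date. The nearest-hotspot oracle property holds at any density; the
  ≥ 90% true-date property is tested under a well-observed configuration
  (16 per km², larger fires).
- The variogram fit assumes isotropy and stationarity of residuals; the
  fallback hierarchy (kriging → IDW → trend) trades optimality for
  robustness and reports which path was taken rather than failing.
- Thresholds from short records (few years, < 30 rows) are flagged rather
  than suppressed; their resampled s.d. understates true uncertainty.
- The smoothed cumulative curve is only evaluated where data exist; the
  threshold is not extrapolated beyond the observed value range.
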