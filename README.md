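# spreadday

Estimation of wildfire **spread-day thresholds** from Canadian Fire Weather
Index (FWI) System data, with the full analysis chain around them: daily FWI
computation from noon weather, daily fire-growth delineation from satellite
hotspots, weather–growth pairing by regression kriging, threshold and
percentile estimation on area-burned curves, and potential- versus
realized-spread-day accounting. A seeded synthetic-data generator provides
ground-truthed inputs for every stage.

## The scientific problem

Most area burned in boreal fire regimes accrues on a small number of *spread
days* — days whose fire weather exceeds a regime-specific threshold. Given a
set of fire perimeters, satellite active-fire detections, and gridded daily
weather, the analysis asks:

1. At what value of each FWI System variable (FFMC, DMC, DC, ISI, BUI, FWI)
   has half of all burned area accrued? That 50% crossing of the smoothed
   cumulative area-burned curve defines the **spread-day threshold**.
2. Where does that threshold sit in the climatological distribution of the
   variable (its percentile), and how much area burns above each percentile?
3. Of the days whose weather exceeded the threshold (**potential spread
   days**, PSD), how many did a given fire actually use (**realized spread
   days**, RSD)? The RSD/PSD ratio measures how much of the weather
   opportunity fires exploit.

The package implements each stage as an independent, testable operation and
ships the published per-ecozone reference tables from the 2001–2021 Canadian
analysis (in `spreadday.reference_tables`) so summary conventions can be
checked exactly.

## The model, briefly

- **FWI engine** (`spreadday.fwi`): the standard daily update equations for
  the six FWI System indices from noon temperature, relative humidity, wind
  and 24 h precipitation, with spring startup codes (85, 6, 15) and yearly
  restart.
- **Growth mapping** (`spreadday.growth`): the final perimeter is rasterized
  and each cell is dated by its nearest usable hotspot (ties go to the
  earlier date); cells with a common date form one daily-growth polygon.
- **Weather pairing** (`spreadday.pairing`): grid-point indices within 50 km
  (extended to 200 km if needed) are downscaled to the growth footprint by an
  elevation-trend regression plus ordinary kriging of the residuals, then
  aggregated (mean for most variables, median for FWI).
- **Threshold estimation** (`spreadday.thresholds`): the cumulative
  area-burned fraction along each variable is smoothed with a penalized
  B-spline, constrained monotone, and its 50% crossing found by bisection;
  uncertainty comes from resampling 10-of-N fire years 100 times.
- **Percentile analysis** (`spreadday.percentiles`): threshold percentiles
  and the area burned above each climatological percentile cutoff.
- **Accounting** (`spreadday.accounting`): strict-exceedance PSD counts on
  spatially aggregated daily series, RSD counts on mapped growth days, and
  per-fire RSD/PSD ratios with ecozone summaries.
- **Synthetic data** (`spreadday.synthetic`): a seeded generator producing
  weather, FWI series, fire perimeters, hotspots and a paired growth table
  whose true spread-day threshold is configured, so every estimator can be
  validated against known truth.

Details, parameter defaults and limitations are in
[docs/methods.md](docs/methods.md).

## Running the tests

```bash
python -m pytest -q tests/
```

## Worked example

Generate a synthetic decade of fires whose true FFMC spread-day threshold is
89.0, then recover it:

```python
from spreadday.synthetic import SyntheticConfig, generate_dataset
from spreadday.thresholds import (ResampleConfig, resample_thresholds,
                                  threshold_at_half)
from spreadday.percentiles import percentile_of_threshold

cfg = SyntheticConfig(seed=42, n_years=10, n_fires_per_year=20,
                      true_threshold={"ffmc": 89.0})
ds = generate_dataset(cfg)
print(f"growth table: {len(ds.growth)} fire-days from "
      f"{ds.growth['fire_id'].nunique()} fires")

t = threshold_at_half(ds.growth, "ffmc")
print(f"FFMC spread-day threshold (50% area crossing): {t:.1f}")

est = resample_thresholds(
    ds.growth, ResampleConfig(n_reps=100, years_per_rep=5, seed=0), "ffmc")
print(f"year-resampled estimate: {est.mean:.1f} (s.d. {est.sd:.1f}, "
      f"{est.n_reps_used} replicates)")

p, clamped = percentile_of_threshold(
    ds.fwi["ffmc"].to_numpy(), None, est.mean)
print(f"percentile of the threshold among all station-days: {p:.0f}")
```

Output:

```
growth table: 786 fire-days from 200 fires
FFMC spread-day threshold (50% area crossing): 88.8
year-resampled estimate: 88.8 (s.d. 0.2, 100 replicates)
percentile of the threshold among all station-days: 91
```

The same pipeline is available on the command line; each stage reads and
writes plain CSV/GeoJSON files:

```bash
spreadday synth  --seed 42 --outdir run/
spreadday fwi    --weather run/weather.csv --out run/fwi.csv
spreadday growth --perimeters run/perimeters.geojson \
                 --hotspots run/hotspots.csv --out run/growth.csv
spreadday thresholds --paired run/growth_truth.csv --seed 1 \
                 --out run/thresholds.csv
spreadday percentiles --paired run/growth_truth.csv \
                 --thresholds run/thresholds.csv --out run/percentiles.csv
spreadday spreaddays --paired run/growth_truth.csv --fwi-series run/fwi.csv \
                 --thresholds run/thresholds.csv --out run/accounts.csv
```

## Reproduction

`scripts/acceptance.py` recomputes the package's headline quantities — the
reference-table summary footers, threshold recovery on Gaussian and
fully synthetic data, the uniform-density percentile identity, and a
deterministic FWI engine step — and writes them as JSON:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

All randomness derives from `--seed`; the same seed reproduces the output
file exactly.
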