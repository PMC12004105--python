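"""Synthetic fire-weather and fire-growth data with known ground truth.

Generates every input the analysis pipeline consumes — multi-year daily noon
weather, the derived FWI System series, fire perimeters, dated hotspots,
daily-growth truth tables and a coarse weather grid — from a single seeded
configuration, so that every downstream stage is testable without any external
download and parameter recovery can be checked against a known truth.

Construction of the truth: daily growth events are placed on calendar days
whose chosen index variable (default FFMC) is nearest to target values drawn
from a Gaussian area-density centred on the configured true threshold. Daily
growth areas are lognormal and independent of the index value, so the
area-weighted distribution of the paired variable converges to that Gaussian
and its centre is the true 50%-area threshold by construction. Fires are
concentric-annulus discs on a planar metric CRS: each growth day is an
annulus, so daily areas sum exactly to the perimeter area and footprints are
disjoint. Hotspots are scattered uniformly within each day's annulus at a
configurable density (at least one per growth day), dated that day, with an
optional ±1 day jitter for robustness experiments.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from datetime import date as _date

import numpy as np
import pandas as pd
from shapely.geometry import Point, mapping

from .fwi import compute_fwi_series
from .growth import FirePerimeter, Hotspot
from .thresholds import FWI_VARIABLES

__all__ = [
    "WeatherModel",
    "SyntheticConfig",
    "SyntheticTruth",
    "SyntheticDataset",
    "ConfigurationError",
    "DEFAULT_ECOZONES",
    "generate_weather",
    "generate_fires",
    "generate_weather_grid",
    "elevation_surface",
    "generate_dataset",
    "write_dataset",
]

#: The 11 analysis strata: Canadian ecozones with Taiga/Boreal Shield split
#: into west and east components.
DEFAULT_ECOZONES = ("TP", "TSW", "BSW", "BP", "TC", "BC",
                    "PM", "MC", "HP", "BSE", "TSE")

_BLOCK_M = 300_000.0  # spatial block per ecozone, planar metric CRS
M2_PER_HA = 10_000.0


class ConfigurationError(ValueError):
    """Raised when a generator configuration field is invalid."""


@dataclass(frozen=True)
class WeatherModel:
    """Seasonal-cycle + AR(1) parameters per noon weather element.

    Seasonal cycles are sinusoids with the annual minimum in mid-January;
    day-to-day persistence is AR(1) on the residual. Defaults emulate a
    boreal continental station: −15 °C January / +18 °C July means, drier
    summers, intermittent precipitation.
    """

    temp_mean: float = 2.5        # deg C annual mean
    temp_amplitude: float = 17.5  # deg C half-range of the seasonal cycle
    temp_sd: float = 3.5          # residual s.d.
    temp_ar1: float = 0.7
    rh_mean: float = 60.0         # %
    rh_amplitude: float = -18.0   # negative: summer is drier
    rh_sd: float = 12.0
    rh_ar1: float = 0.6
    wind_mean: float = 12.0       # km/h
    wind_sd: float = 5.0
    wind_ar1: float = 0.4
    wet_day_prob: float = 0.3
    precip_shape: float = 0.7     # gamma shape of wet-day amounts
    precip_scale: float = 8.0     # gamma scale, mm


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-frame configuration for the synthetic dataset."""

    n_years: int = 21
    year_start: int = 2001
    n_fires_per_year: int = 25
    ecozone_labels: tuple[str, ...] = DEFAULT_ECOZONES
    density_variable: str = "ffmc"
    true_threshold: dict = field(
        default_factory=lambda: {"ffmc": 89.4})
    density_width: float = 3.0          # Gaussian s.d. of the area density
    area_median_ha: float = 150.0       # lognormal daily-growth median
    area_sigma: float = 0.8             # lognormal shape
    growth_days_mean: float = 4.0       # mean growth days per fire
    hotspot_density: float = 4.0        # hotspots per km^2 of daily growth
    hotspot_jitter_days: int = 0        # optional ±1 day dating noise
    weather_model: WeatherModel = field(default_factory=WeatherModel)
    latitude: float = 55.0
    grid_spacing_m: float = 25_000.0    # synthetic coarse weather-grid spacing
    seed: int = 0

    def validate(self) -> "SyntheticConfig":
        if self.n_years < 2:
            raise ConfigurationError("n_years must be >= 2")
        if self.n_fires_per_year < 1:
            raise ConfigurationError("n_fires_per_year must be >= 1")
        if self.hotspot_density <= 0:
            raise ConfigurationError("hotspot_density must be > 0")
        if self.density_width <= 0:
            raise ConfigurationError("density_width must be > 0")
        if self.density_variable not in FWI_VARIABLES:
            raise ConfigurationError(
                f"density_variable {self.density_variable!r} not an FWI variable")
        if self.density_variable not in self.true_threshold:
            raise ConfigurationError(
                "true_threshold must contain the density variable")
        if not (0.0 <= self.weather_model.wet_day_prob <= 1.0):
            raise ConfigurationError("wet_day_prob must be in [0, 1]")
        return self

    @property
    def years(self) -> range:
        return range(self.year_start, self.year_start + self.n_years)


@dataclass
class SyntheticTruth:
    """Ground truth of one generated dataset."""

    thresholds: dict                    # variable -> true 50%-area value
    growth_schedule: pd.DataFrame       # per-fire growth days with paired truth
    exceedance_by_year: dict            # year -> {variable: days above truth}


@dataclass
class SyntheticDataset:
    config: SyntheticConfig
    weather: pd.DataFrame
    fwi: pd.DataFrame
    perimeters: list
    hotspots: pd.DataFrame
    growth: pd.DataFrame                # the canonical paired analysis table
    truth: SyntheticTruth


def _ar1(rng: np.random.Generator, n: int, sd: float, rho: float) -> np.ndarray:
    """Stationary AR(1) residual series with marginal s.d. ``sd``."""
    eps = rng.normal(0.0, 1.0, n)
    out = np.empty(n)
    innov_sd = sd * np.sqrt(max(1.0 - rho**2, 0.0)) if abs(rho) < 1 else sd
    out[0] = sd * eps[0]
    for i in range(1, n):
        out[i] = rho * out[i - 1] + innov_sd * eps[i]
    return out


def _seasonal(doy: np.ndarray, mean: float, amplitude: float) -> np.ndarray:
    # annual minimum near mid-January (doy 15) for positive amplitude
    return mean - amplitude * np.cos(2.0 * np.pi * (doy - 15.0) / 365.25)


def generate_weather(config: SyntheticConfig,
                     latitude: float | None = None) -> pd.DataFrame:
    """Daily noon weather for every calendar day of the configured years."""
    config.validate()
    wm = config.weather_model
    rng = np.random.default_rng([1, config.seed])
    dates = pd.date_range(
        _date(config.year_start, 1, 1),
        _date(config.year_start + config.n_years - 1, 12, 31), freq="D")
    n = len(dates)
    doy = dates.dayofyear.to_numpy(dtype=float)
    temp = _seasonal(doy, wm.temp_mean, wm.temp_amplitude) \
        + _ar1(rng, n, wm.temp_sd, wm.temp_ar1)
    rh = np.clip(_seasonal(doy, wm.rh_mean, wm.rh_amplitude)
                 + _ar1(rng, n, wm.rh_sd, wm.rh_ar1), 2.0, 100.0)
    wind = np.clip(wm.wind_mean + _ar1(rng, n, wm.wind_sd, wm.wind_ar1),
                   0.0, None)
    wet = rng.random(n) < wm.wet_day_prob
    precip = np.where(
        wet, rng.gamma(wm.precip_shape, wm.precip_scale, n), 0.0)
    return pd.DataFrame({
        "date": dates.date, "temp": temp, "rh": rh, "wind": wind,
        "precip": precip,
        "latitude": latitude if latitude is not None else config.latitude,
    })


def _season_window(fwi: pd.DataFrame, year: int) -> pd.DataFrame:
    d = pd.to_datetime(fwi["date"])
    return fwi[(d.dt.year == year) & d.dt.month.between(4, 10)]


def _match_days(window: pd.DataFrame, variable: str, targets: np.ndarray
                ) -> np.ndarray:
    """Indices (into window) of the days with index value nearest each target."""
    v = np.asarray(window[variable], dtype=float)
    order = np.argsort(v)
    vs = v[order]
    pos = np.clip(np.searchsorted(vs, targets), 1, len(vs) - 1)
    left_closer = (targets - vs[pos - 1]) <= (vs[pos] - targets)
    nearest = np.where(left_closer, pos - 1, pos)
    return order[nearest]


def _stratified_annulus_points(rng: np.random.Generator, r_in: float,
                               r_out: float, density_per_km2: float
                               ) -> tuple[np.ndarray, np.ndarray]:
    """Jittered-grid point scatter inside an annulus (>= 1 point).

    Satellite active-fire detections sit on a sensor grid, so hotspots are
    laid out on a square lattice at the nominal density and jittered, then
    clipped to the annulus. Returns polar coordinates (radius, angle).
    """
    spacing = 1000.0 / np.sqrt(density_per_km2)
    xs = np.arange(-r_out, r_out + spacing, spacing)
    if len(xs) >= 2:
        gx, gy = np.meshgrid(xs, xs)
        gx = gx.ravel() + rng.uniform(-0.25, 0.25, gx.size) * spacing
        gy = gy.ravel() + rng.uniform(-0.25, 0.25, gx.size) * spacing
        rr = np.hypot(gx, gy)
        keep = (rr >= r_in + 1.0) & (rr <= r_out - 1.0)
        if keep.any():
            return rr[keep], np.arctan2(gy[keep], gx[keep])
    # annulus thinner than the sensor grid: one detection at mid radius
    mid = np.array([0.5 * (r_in + r_out)])
    return mid, rng.uniform(0.0, 2.0 * np.pi, 1)


def generate_fires(config: SyntheticConfig, fwi: pd.DataFrame
                   ) -> tuple[list, pd.DataFrame, pd.DataFrame]:
    """Fires with known daily growth: perimeters, hotspots, growth truth.

    Returns ``(perimeters, hotspots, growth)``: a list of
    :class:`~spreadday.growth.FirePerimeter` discs, the hotspot table and the
    per-day growth-truth table whose index columns carry the values the day's
    growth was actually generated under (the canonical paired table for
    parameter-recovery tests).
    """
    config.validate()
    rng = np.random.default_rng([2, config.seed])
    var = config.density_variable
    centre = float(config.true_threshold[var])
    v_all = np.asarray(fwi[var], dtype=float)
    if not (v_all.min() <= centre <= v_all.max()):
        raise ConfigurationError(
            f"true threshold {centre} for {var} outside the generated index "
            f"range [{v_all.min():.2f}, {v_all.max():.2f}]")
    label_idx = {z: i for i, z in enumerate(config.ecozone_labels)}
    perimeters: list[FirePerimeter] = []
    hs_rows: list[dict] = []
    growth_rows: list[dict] = []
    for year in config.years:
        window = _season_window(fwi, year).reset_index(drop=True)
        for i in range(config.n_fires_per_year):
            fire_id = f"F{year}-{i:03d}"
            ecozone = config.ecozone_labels[
                int(rng.integers(len(config.ecozone_labels)))]
            n_days = 1 + int(rng.poisson(max(config.growth_days_mean - 1.0, 0.0)))
            targets = rng.normal(centre, config.density_width, n_days)
            day_idx = np.unique(_match_days(window, var, targets))
            days = window.iloc[day_idx].sort_values("date")
            areas = rng.lognormal(np.log(config.area_median_ha),
                                  config.area_sigma, len(days))
            if areas.sum() < 60.0:   # keep final size above the 50 ha cut
                areas *= 60.0 / areas.sum()
            origin_x = label_idx[ecozone] * _BLOCK_M
            cx = origin_x + rng.uniform(0.15, 0.85) * _BLOCK_M
            cy = rng.uniform(0.15, 0.85) * _BLOCK_M
            radii = np.sqrt(np.cumsum(areas) * M2_PER_HA / np.pi)
            perimeters.append(FirePerimeter(
                fire_id=fire_id, year=year,
                geometry=Point(cx, cy).buffer(radii[-1], quad_segs=64),
                ecozone=ecozone))
            r_prev = 0.0
            for (r_out, area_ha, (_, day)) in zip(radii, areas, days.iterrows()):
                d = day["date"]
                rr, theta = _stratified_annulus_points(
                    rng, r_prev, r_out, config.hotspot_density)
                n_hs = len(rr)
                jitter = (rng.integers(-1, 2, n_hs)
                          if config.hotspot_jitter_days else np.zeros(n_hs, int))
                sensor = ("MODIS" if year <= 2012
                          else ("VIIRS" if rng.random() < 0.5 else "MODIS"))
                for k in range(n_hs):
                    hs_rows.append({
                        "fire_id": fire_id,
                        "x": cx + rr[k] * np.cos(theta[k]),
                        "y": cy + rr[k] * np.sin(theta[k]),
                        "date": d + pd.Timedelta(days=int(jitter[k])).to_pytimedelta(),
                        "sensor": sensor,
                    })
                row = {
                    "fire_id": fire_id, "date": d, "year": year,
                    "ecozone": ecozone, "area": float(area_ha),
                    "season": {3: "MAM", 4: "MAM", 5: "MAM", 6: "JJA", 7: "JJA",
                               8: "JJA", 9: "SON", 10: "SON", 11: "SON"}[d.month],
                }
                for v in FWI_VARIABLES:
                    row[v] = float(day[v])
                growth_rows.append(row)
                r_prev = r_out
    return perimeters, pd.DataFrame(hs_rows), pd.DataFrame(growth_rows)


def elevation_surface(x, y):
    """Smooth synthetic elevation (m) over the planar domain."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return (500.0 + 300.0 * np.sin(x / 120_000.0)
            + 200.0 * np.cos(y / 90_000.0))


# additive spatial perturbation amplitude per index for the synthetic grid
_GRID_AMP = {"ffmc": 1.5, "dmc": 4.0, "dc": 20.0, "isi": 1.0,
             "bui": 5.0, "fwi": 2.0}
# elevation lapse per index (index units per km of elevation)
_GRID_LAPSE = {"ffmc": 0.8, "dmc": 2.0, "dc": 10.0, "isi": 0.5,
               "bui": 2.5, "fwi": 1.0}
_FWI_UPPER = {"ffmc": 101.0}


def generate_weather_grid(config: SyntheticConfig, fwi: pd.DataFrame,
                          bounds: tuple[float, float, float, float],
                          dates) -> pd.DataFrame:
    """Coarse fire-weather grid over a bounding box for the given dates.

    Each grid point carries the base daily index values plus a smooth spatial
    perturbation and an elevation lapse, so the field has genuine spatial
    structure for the downscaling stage to recover. ``bounds`` is
    (minx, miny, maxx, maxy) in metres; points are laid out at the configured
    grid spacing with one ring of margin.
    """
    s = config.grid_spacing_m
    minx, miny, maxx, maxy = bounds
    xs = np.arange(minx - s, maxx + 1.5 * s, s)
    ys = np.arange(miny - s, maxy + 1.5 * s, s)
    gx, gy = np.meshgrid(xs, ys)
    gx, gy = gx.ravel(), gy.ravel()
    elev = elevation_surface(gx, gy)
    base = fwi.copy()
    base["date"] = pd.to_datetime(base["date"]).dt.date
    base = base.set_index("date")
    rows = []
    for d in dates:
        day = base.loc[d]
        pert = np.sin(gx / 80_000.0) * np.cos(gy / 80_000.0)
        rec = {"date": d, "x": gx, "y": gy, "elevation": elev}
        for var in FWI_VARIABLES:
            val = (float(day[var]) + _GRID_AMP[var] * pert
                   - _GRID_LAPSE[var] * (elev - 500.0) / 1000.0)
            rec[var] = np.clip(val, 0.0, _FWI_UPPER.get(var, np.inf))
        rows.append(pd.DataFrame(rec))
    return pd.concat(rows, ignore_index=True)


def _exceedance_by_year(fwi: pd.DataFrame, thresholds: dict) -> dict:
    d = pd.to_datetime(fwi["date"])
    out: dict[int, dict[str, int]] = {}
    for year, sub in fwi.groupby(d.dt.year):
        out[int(year)] = {v: int((sub[v] > t).sum())
                          for v, t in thresholds.items()}
    return out


def generate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Full synthetic dataset: weather → FWI → fires, with ground truth."""
    config.validate()
    weather = generate_weather(config)
    fwi = compute_fwi_series(weather)
    perimeters, hotspots, growth = generate_fires(config, fwi)
    truth = SyntheticTruth(
        thresholds=dict(config.true_threshold),
        growth_schedule=growth[["fire_id", "date", "area",
                                config.density_variable]].copy(),
        exceedance_by_year=_exceedance_by_year(fwi, config.true_threshold),
    )
    return SyntheticDataset(config=config, weather=weather, fwi=fwi,
                            perimeters=perimeters, hotspots=hotspots,
                            growth=growth, truth=truth)


def write_dataset(ds: SyntheticDataset, outdir) -> None:
    """Write the dataset as CSV/GeoJSON/JSON files under ``outdir``."""
    from pathlib import Path
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    ds.weather.to_csv(out / "weather.csv", index=False)
    ds.fwi.to_csv(out / "fwi.csv", index=False)
    ds.hotspots.to_csv(out / "hotspots.csv", index=False)
    ds.growth.to_csv(out / "growth_truth.csv", index=False)
    features = [{
        "type": "Feature",
        "properties": {"fire_id": p.fire_id, "year": p.year,
                       "ecozone": p.ecozone, "area_ha": p.area_ha},
        "geometry": mapping(p.geometry),
    } for p in ds.perimeters]
    with open(out / "perimeters.geojson", "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)
    with open(out / "truth.json", "w") as fh:
        json.dump({
            "thresholds": ds.truth.thresholds,
            "exceedance_by_year": ds.truth.exceedance_by_year,
            "config": {k: v for k, v in asdict(ds.config).items()
                       if k != "weather_model"},
        }, fh, indent=2, default=str)
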