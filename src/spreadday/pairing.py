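"""Pair daily fire-growth footprints with downscaled fire-weather indices.

The coarse fire-weather grid (nominally 0.25 deg spacing) is downscaled to the
footprint cells by regression kriging: a linear trend of each index on
elevation, plus ordinary kriging of the residuals under an automatically
fitted variogram (weighted-least-squares fit over the spherical, exponential
and Gaussian model family). Grid points are taken within a 50 km buffer of the
footprint; if too few points are available or the variogram cannot be fitted,
the buffer is extended to 200 km; if kriging is still impossible the fallback
is the elevation trend plus inverse-distance-weighted residuals (logged).

The footprint aggregate takes the arithmetic mean of FFMC, DMC, DC, ISI and
BUI over the downscaled cells, and the median of FWI (FWI relates
exponentially to potential fire intensity, so its mean would be dominated by
tails). Each paired row also carries a meteorological season label (MAM, JJA,
SON; December–February rows are excluded from seasonal strata but kept in the
annual pool).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .growth import DailyGrowthDay
from .thresholds import FWI_VARIABLES

__all__ = [
    "PairingError",
    "VariogramModel",
    "season_of_month",
    "select_grid_points",
    "fit_variogram",
    "downscale",
    "aggregate_pair",
    "pair_growth",
    "BUFFER_PRIMARY_M",
    "BUFFER_EXTENDED_M",
]

logger = logging.getLogger(__name__)

BUFFER_PRIMARY_M = 50_000.0
BUFFER_EXTENDED_M = 200_000.0
MIN_KRIGING_POINTS = 4

_SEASONS = {3: "MAM", 4: "MAM", 5: "MAM", 6: "JJA", 7: "JJA", 8: "JJA",
            9: "SON", 10: "SON", 11: "SON"}


class PairingError(ValueError):
    """Raised when a growth day cannot be paired with fire weather."""


def season_of_month(month: int) -> str | None:
    """MAM/JJA/SON for March–November; None for the excluded winter months."""
    return _SEASONS.get(month)


def select_grid_points(footprint_xy: np.ndarray, grid: pd.DataFrame,
                       buffer: float = BUFFER_PRIMARY_M) -> pd.DataFrame:
    """Grid points within ``buffer`` metres of any footprint cell.

    ``grid`` holds one date's points (columns x, y, elevation and the index
    variables). Distance is to the nearest footprint cell centre.
    """
    if grid.empty:
        raise PairingError("weather grid empty for this date")
    gx = np.asarray(grid["x"], dtype=float)
    gy = np.asarray(grid["y"], dtype=float)
    fx = np.asarray(footprint_xy[:, 0], dtype=float)
    fy = np.asarray(footprint_xy[:, 1], dtype=float)
    d2 = ((gx[:, None] - fx[None, :]) ** 2
          + (gy[:, None] - fy[None, :]) ** 2).min(axis=1)
    return grid[np.sqrt(d2) <= buffer]


# --- variogram models ---------------------------------------------------------

def _spherical(h, nugget, psill, rng):
    hr = np.minimum(h / rng, 1.0)
    return nugget + psill * (1.5 * hr - 0.5 * hr**3)


def _exponential(h, nugget, psill, rng):
    return nugget + psill * (1.0 - np.exp(-3.0 * h / rng))


def _gaussian(h, nugget, psill, rng):
    return nugget + psill * (1.0 - np.exp(-3.0 * (h / rng) ** 2))


_MODELS = {"spherical": _spherical, "exponential": _exponential,
           "gaussian": _gaussian}


@dataclass(frozen=True)
class VariogramModel:
    model: str
    nugget: float
    psill: float   # partial sill
    range_: float

    def __call__(self, h: np.ndarray) -> np.ndarray:
        gamma = _MODELS[self.model](np.asarray(h, dtype=float),
                                    self.nugget, self.psill, self.range_)
        return np.where(np.asarray(h) > 0, gamma, 0.0)

    @property
    def sill(self) -> float:
        return self.nugget + self.psill


def fit_variogram(xy: np.ndarray, residuals: np.ndarray,
                  n_bins: int = 10) -> VariogramModel:
    """WLS fit of the empirical semivariogram over a small model family.

    Bins pairwise semivariances up to half the maximum separation, fits the
    spherical, exponential and Gaussian models by pair-count-weighted least
    squares, and returns the best. Raises :class:`PairingError` on failure
    (too few points, no spatial structure, non-positive sill, or
    non-convergence of every model).
    """
    n = len(residuals)
    if n < MIN_KRIGING_POINTS:
        raise PairingError(f"variogram needs >= {MIN_KRIGING_POINTS} points, got {n}")
    iu, ju = np.triu_indices(n, k=1)
    h = np.hypot(xy[iu, 0] - xy[ju, 0], xy[iu, 1] - xy[ju, 1])
    gamma = 0.5 * (residuals[iu] - residuals[ju]) ** 2
    hmax = h.max() / 2.0
    if hmax <= 0 or np.var(residuals) <= 0:
        raise PairingError("no spatial structure in residuals")
    edges = np.linspace(0.0, hmax, n_bins + 1)
    which = np.digitize(h, edges[1:-1])
    keep = h <= hmax
    bin_h, bin_g, bin_n = [], [], []
    for b in range(n_bins):
        sel = keep & (which == b)
        if sel.sum() > 0:
            bin_h.append(h[sel].mean())
            bin_g.append(gamma[sel].mean())
            bin_n.append(sel.sum())
    if len(bin_h) < 3:
        raise PairingError("too few variogram bins")
    bh, bg = np.asarray(bin_h), np.asarray(bin_g)
    weights = np.sqrt(np.asarray(bin_n, dtype=float))
    var0 = max(np.var(residuals), 1e-12)
    best: tuple[float, VariogramModel | None] = (np.inf, None)
    for name, fn in _MODELS.items():
        try:
            popt, _ = curve_fit(
                fn, bh, bg,
                p0=[0.0, var0, hmax / 2.0],
                sigma=1.0 / weights,
                bounds=([0.0, 1e-12 * var0, 1e-6 * hmax],
                        [var0 * 10.0, var0 * 10.0, hmax * 10.0]),
                maxfev=5000)
        except (RuntimeError, ValueError):
            continue
        sse = float(np.sum(weights * (fn(bh, *popt) - bg) ** 2))
        model = VariogramModel(name, *map(float, popt))
        if model.sill <= 0:
            continue
        if sse < best[0]:
            best = (sse, model)
    if best[1] is None:
        raise PairingError("variogram fit failed for every model")
    return best[1]


def _ordinary_krige(src_xy: np.ndarray, residuals: np.ndarray,
                    tgt_xy: np.ndarray, vgm: VariogramModel) -> np.ndarray:
    n = len(residuals)
    d_ss = np.hypot(src_xy[:, None, 0] - src_xy[None, :, 0],
                    src_xy[:, None, 1] - src_xy[None, :, 1])
    a = np.empty((n + 1, n + 1))
    a[:n, :n] = vgm(d_ss)
    a[n, :] = 1.0
    a[:, n] = 1.0
    a[n, n] = 0.0
    d_st = np.hypot(tgt_xy[:, None, 0] - src_xy[None, :, 0],
                    tgt_xy[:, None, 1] - src_xy[None, :, 1])
    b = np.empty((len(tgt_xy), n + 1))
    b[:, :n] = vgm(d_st)
    b[:, n] = 1.0
    try:
        lam = np.linalg.solve(a, b.T)
    except np.linalg.LinAlgError:
        lam = np.linalg.lstsq(a, b.T, rcond=None)[0]
    return lam[:n].T @ residuals


def _idw(src_xy: np.ndarray, values: np.ndarray, tgt_xy: np.ndarray,
         power: float = 2.0) -> np.ndarray:
    d = np.hypot(tgt_xy[:, None, 0] - src_xy[None, :, 0],
                 tgt_xy[:, None, 1] - src_xy[None, :, 1])
    exact = d < 1e-9
    w = 1.0 / np.maximum(d, 1e-9) ** power
    est = (w * values).sum(axis=1) / w.sum(axis=1)
    hit = exact.any(axis=1)
    est[hit] = values[exact.argmax(axis=1)[hit]]
    return est


def downscale(points: pd.DataFrame, targets: np.ndarray, variable: str
              ) -> tuple[np.ndarray, str]:
    """Regression-kriging downscale of one index to target cells.

    ``points`` carries x, y, elevation and the variable at the coarse grid;
    ``targets`` is an (n, 3) array of x, y, elevation at the fine cells.
    Returns ``(values, method)`` where method is "kriging", "idw" (variogram
    fallback) or "trend" (residuals spatially constant).
    """
    if len(points) < MIN_KRIGING_POINTS:
        raise PairingError(
            f"{len(points)} grid point(s) < {MIN_KRIGING_POINTS} required")
    xy = np.column_stack([points["x"], points["y"]]).astype(float)
    elev = np.asarray(points["elevation"], dtype=float)
    vals = np.asarray(points[variable], dtype=float)
    tgt_xy = targets[:, :2].astype(float)
    tgt_elev = targets[:, 2].astype(float)
    # linear elevation trend (constant when elevation is flat)
    if np.ptp(elev) > 1e-12:
        slope, intercept = np.polyfit(elev, vals, 1)
    else:
        slope, intercept = 0.0, float(vals.mean())
    resid = vals - (slope * elev + intercept)
    trend_at_tgt = slope * tgt_elev + intercept
    if float(np.max(np.abs(resid))) < 1e-10:
        return trend_at_tgt, "trend"
    try:
        vgm = fit_variogram(xy, resid)
        interp = _ordinary_krige(xy, resid, tgt_xy, vgm)
        method = "kriging"
    except PairingError as exc:
        logger.info("variogram fallback to IDW: %s", exc)
        interp = _idw(xy, resid, tgt_xy)
        method = "idw"
    return trend_at_tgt + interp, method


def aggregate_pair(growth: DailyGrowthDay, fine_values: dict[str, np.ndarray],
                   ecozone: str = "unknown", year: int | None = None) -> dict:
    """Collapse downscaled cell values into one paired analysis row.

    Means for FFMC/DMC/DC/ISI/BUI, median for FWI (midpoint convention for
    even counts via ``numpy``'s median).
    """
    if any(len(v) == 0 for v in fine_values.values()):
        raise PairingError("no downscaled values inside footprint")
    row = {
        "fire_id": growth.fire_id,
        "date": growth.date,
        "area": growth.area_ha,
        "year": year if year is not None else growth.date.year,
        "ecozone": ecozone,
        "season": season_of_month(growth.date.month),
    }
    for var in FWI_VARIABLES:
        v = np.asarray(fine_values[var], dtype=float)
        row[var] = float(np.median(v)) if var == "fwi" else float(v.mean())
    return row


def _targets_with_elevation(cells: np.ndarray, elevation) -> np.ndarray:
    elev = elevation(cells[:, 0], cells[:, 1])
    return np.column_stack([cells, np.asarray(elev, dtype=float)])


def pair_growth(growth_days: list[DailyGrowthDay], grid: pd.DataFrame,
                elevation, ecozone: str = "unknown",
                year: int | None = None) -> pd.DataFrame:
    """Pair each growth day with downscaled fire weather.

    ``grid`` is the full weather grid table (date, x, y, elevation, indices);
    ``elevation`` is a callable ``(x, y) -> elevation`` for the fine cells.
    Growth days that cannot be paired even at the extended buffer are dropped
    with a logged reason.
    """
    grid = grid.copy()
    grid["date"] = pd.to_datetime(grid["date"]).dt.date
    rows = []
    for g in growth_days:
        day_grid = grid[grid["date"] == g.date]
        targets = _targets_with_elevation(g.cells, elevation)
        try:
            pts = select_grid_points(g.cells, day_grid, BUFFER_PRIMARY_M)
            fine, flagged = _downscale_all(pts, targets)
        except PairingError:
            try:
                pts = select_grid_points(g.cells, day_grid, BUFFER_EXTENDED_M)
                fine, flagged = _downscale_all(pts, targets)
            except PairingError as exc:
                logger.warning("fire %s %s: pairing failed (%s) — row excluded",
                               g.fire_id, g.date, exc)
                continue
        rows.append(aggregate_pair(g, fine, ecozone=ecozone, year=year))
    return pd.DataFrame.from_records(rows)


def _downscale_all(points: pd.DataFrame, targets: np.ndarray
                   ) -> tuple[dict[str, np.ndarray], bool]:
    fine = {}
    flagged = False
    for var in FWI_VARIABLES:
        fine[var], method = downscale(points, targets, var)
        flagged |= method == "idw"
    return fine, flagged
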