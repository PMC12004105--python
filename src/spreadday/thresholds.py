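"""Spread-day threshold estimation from cumulative area-burned curves.

The core statistic: for a set of daily fire-growth records paired with fire
weather, accumulate burned area along an FWI System variable, smooth the
cumulative fraction with a penalized regression spline, and report the index
value at which the smoothed curve crosses 50% of the total area burned. The
crossing value is the spread-day threshold for that variable. Uncertainty
comes from resampling years: each replicate pools a random subset of the
available fire years (default 10 of 21), re-estimates the threshold, and the
mean and standard deviation across replicates (default 100) are reported.

Smoother: cubic B-spline basis (default dimension 10) with a second-order
difference penalty; the penalty weight is chosen by generalized
cross-validation on a log-spaced grid. The fitted curve is projected onto the
nondecreasing cone (isotonic regression) before root finding, since a
cumulative fraction must be monotone.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline
from scipy.optimize import isotonic_regression

__all__ = [
    "FWI_VARIABLES",
    "SmootherSpec",
    "ResampleConfig",
    "ThresholdEstimate",
    "EstimationError",
    "cumulative_curve",
    "fit_smooth_cdf",
    "threshold_at_half",
    "resample_thresholds",
    "estimate_all",
    "summarize_ecozone_table",
    "area_weighted_quantile",
]

FWI_VARIABLES = ("ffmc", "dmc", "dc", "isi", "bui", "fwi")

#: Strata×season cells with fewer paired rows than this are flagged unreliable.
MIN_ROWS_PER_FIT = 30


class EstimationError(ValueError):
    """Raised when a threshold cannot be estimated (e.g. zero total area)."""


@dataclass(frozen=True)
class SmootherSpec:
    """Penalized-spline settings for smoothing the cumulative curve."""

    basis_dim: int = 10          # number of B-spline basis functions
    degree: int = 3
    n_lambda: int = 25           # GCV grid size
    lambda_range: tuple[float, float] = (1e-6, 1e4)
    grid_points: int = 1000      # evaluation grid for the 0.5 crossing


@dataclass(frozen=True)
class ResampleConfig:
    """Year-resampling settings for threshold uncertainty."""

    n_reps: int = 100
    years_per_rep: int = 10
    years_available: tuple[int, ...] | None = None  # default: years seen in data
    seed: int = 0
    smoother: SmootherSpec = field(default_factory=SmootherSpec)

    def __post_init__(self) -> None:
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if self.years_per_rep < 1:
            raise ValueError("years_per_rep must be >= 1")


@dataclass(frozen=True)
class ThresholdEstimate:
    """Mean and s.d. of the 50%-area index value across resampling replicates."""

    variable: str
    stratum: str
    season: str          # "annual", "MAM", "JJA" or "SON"
    mean: float
    sd: float
    n_reps_used: int
    n_rows: int
    reliable: bool = True


def cumulative_curve(rows: pd.DataFrame, variable: str
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Accumulated area-burned fraction along an index variable.

    Sorts rows by ``variable``, merges ties, and returns ``(values, cumfrac)``
    where ``cumfrac[i]`` is the fraction of total area burned at index values
    ``<= values[i]``. The implied step curve is nondecreasing, starts above 0
    and ends at exactly 1.
    """
    v = np.asarray(rows[variable], dtype=float)
    a = np.asarray(rows["area"], dtype=float)
    total = a.sum()
    if not len(v) or total <= 0:
        raise EstimationError("zero total area: cannot form cumulative curve")
    order = np.argsort(v, kind="stable")
    v, a = v[order], a[order]
    values, start = np.unique(v, return_index=True)
    mass = np.add.reduceat(a, start)
    cumfrac = np.cumsum(mass) / total
    cumfrac[-1] = 1.0  # guard rounding
    return values, cumfrac


def area_weighted_quantile(values: np.ndarray, areas: np.ndarray,
                           q: float = 0.5) -> float:
    """Area-weighted quantile with linear interpolation between knots.

    The unsmoothed counterpart of the spline threshold: each distinct index
    value is placed at the midpoint of its cumulative area mass (so a mass
    point carrying area fraction [c0, c1] sits at (c0+c1)/2) and the quantile
    is linearly interpolated between those plotting positions. Two equal
    masses at 80 and 90 therefore give 85 at q=0.5.
    """
    values = np.asarray(values, dtype=float)
    areas = np.asarray(areas, dtype=float)
    order = np.argsort(values, kind="stable")
    v, a = values[order], areas[order]
    uniq, start = np.unique(v, return_index=True)
    mass = np.add.reduceat(a, start)
    total = mass.sum()
    pos = (np.cumsum(mass) - 0.5 * mass) / total
    if len(uniq) == 1:
        return float(uniq[0])
    return float(np.interp(q, pos, uniq))


def _bspline_design(x: np.ndarray, lo: float, hi: float,
                    spec: SmootherSpec) -> tuple[np.ndarray, np.ndarray]:
    """Cubic B-spline design matrix with evenly spaced interior knots."""
    k = spec.degree
    n_basis = max(spec.basis_dim, k + 1)
    n_interior = n_basis - k - 1
    interior = np.linspace(lo, hi, n_interior + 2)[1:-1]
    knots = np.concatenate([np.repeat(lo, k + 1), interior, np.repeat(hi, k + 1)])
    design = BSpline.design_matrix(np.clip(x, lo, hi), knots, k).toarray()
    return design, knots


def fit_smooth_cdf(values: np.ndarray, cumfrac: np.ndarray,
                   spec: SmootherSpec | None = None):
    """Penalized-spline smooth of a cumulative fraction curve.

    Fits coefficients ``c`` minimizing ``||y - Bc||^2 + lam * ||D2 c||^2``
    with the penalty weight chosen by generalized cross-validation, and
    returns a callable evaluating the (unprojected) smooth.
    """
    spec = spec or SmootherSpec()
    x = np.asarray(values, dtype=float)
    y = np.asarray(cumfrac, dtype=float)
    lo, hi = float(x[0]), float(x[-1])
    n_basis = min(spec.basis_dim, max(len(np.unique(x)), 4))
    local = SmootherSpec(basis_dim=n_basis, degree=min(spec.degree, n_basis - 1),
                         n_lambda=spec.n_lambda, lambda_range=spec.lambda_range,
                         grid_points=spec.grid_points)
    design, knots = _bspline_design(x, lo, hi, local)
    k = design.shape[1]
    d2 = np.diff(np.eye(k), n=2, axis=0) if k > 2 else np.zeros((0, k))
    bt_b = design.T @ design
    bt_y = design.T @ y
    pen = d2.T @ d2
    lambdas = np.geomspace(*spec.lambda_range, spec.n_lambda)
    best = (np.inf, None)
    n = len(x)
    for lam in lambdas:
        a = bt_b + lam * pen
        try:
            coef = np.linalg.solve(a, bt_y)
            # effective degrees of freedom = tr(B (B'B + lam P)^-1 B')
            edf = float(np.trace(np.linalg.solve(a, bt_b)))
        except np.linalg.LinAlgError:
            continue
        resid = y - design @ coef
        denom = max(n - edf, 1e-8)
        gcv = n * float(resid @ resid) / denom**2
        if gcv < best[0]:
            best = (gcv, coef)
    if best[1] is None:  # fully degenerate system: fall back to interpolation
        return lambda q: np.interp(q, x, y)
    coef = best[1]
    spline = BSpline(knots, coef, local.degree, extrapolate=False)

    def evaluate(q):
        q = np.asarray(q, dtype=float)
        out = spline(np.clip(q, lo, hi))
        return np.asarray(out, dtype=float)

    return evaluate


def threshold_at_half(rows: pd.DataFrame, variable: str,
                      smoother: SmootherSpec | None = None,
                      q: float = 0.5) -> float:
    """Index value at which the smoothed cumulative area-burned curve hits ``q``.

    Fits the penalized spline to the cumulative fraction, projects the fitted
    curve onto the nondecreasing cone, and returns the smallest index value on
    a fine grid where the monotone curve reaches ``q`` (refined by bisection
    on the raw spline where it brackets the crossing). The result is clamped
    to the observed range of the variable.
    """
    spec = smoother or SmootherSpec()
    values, cumfrac = cumulative_curve(rows, variable)
    if len(values) == 1:
        return float(values[0])  # degenerate: all mass at one value
    if len(values) < 5:
        # too few knots for a stable spline: area-weighted quantile instead
        return area_weighted_quantile(
            np.asarray(rows[variable]), np.asarray(rows["area"]), q)
    smooth = fit_smooth_cdf(values, cumfrac, spec)
    grid = np.linspace(values[0], values[-1], spec.grid_points)
    fitted = np.clip(smooth(grid), 0.0, 1.0)
    mono = isotonic_regression(fitted).x
    idx = int(np.searchsorted(mono, q))
    if idx == 0:
        return float(grid[0])
    if idx >= len(grid):
        return float(grid[-1])
    lo_x, hi_x = grid[idx - 1], grid[idx]
    f_lo, f_hi = smooth(lo_x) - q, smooth(hi_x) - q
    if f_lo < 0.0 <= f_hi:  # bisect the raw spline inside the bracket
        for _ in range(60):
            mid = 0.5 * (lo_x + hi_x)
            if smooth(mid) - q < 0.0:
                lo_x = mid
            else:
                hi_x = mid
        return float(0.5 * (lo_x + hi_x))
    # non-monotone locally: linear interpolation of the projected curve
    m_lo, m_hi = mono[idx - 1], mono[idx]
    if m_hi == m_lo:
        return float(hi_x)
    w = (q - m_lo) / (m_hi - m_lo)
    return float(grid[idx - 1] + w * (grid[idx] - grid[idx - 1]))


def _stream_seed(master: int, variable: str, stratum: str, season: str) -> int:
    """Stable per-(variable, stratum, season) RNG seed below 2**31."""
    tag = f"{variable}|{stratum}|{season}".encode()
    return (int(master) * 2654435761 + zlib.crc32(tag)) % (2**31 - 1)


def resample_thresholds(rows: pd.DataFrame, config: ResampleConfig,
                        variable: str, stratum: str = "national",
                        season: str = "annual") -> ThresholdEstimate:
    """Threshold mean and s.d. over year-resampling replicates.

    Each replicate samples ``years_per_rep`` distinct years uniformly without
    replacement, pools their rows and computes :func:`threshold_at_half`.
    Strata with fewer distinct years than ``years_per_rep``, or fewer rows
    than the minimum per fit, produce a single all-years estimate flagged
    unreliable.
    """
    years = (np.asarray(sorted(config.years_available))
             if config.years_available is not None
             else np.unique(np.asarray(rows["year"])))
    n_rows = len(rows)
    if n_rows == 0:
        raise EstimationError(f"no rows for {variable}/{stratum}/{season}")
    reliable = n_rows >= MIN_ROWS_PER_FIT
    if len(years) < config.years_per_rep:
        value = threshold_at_half(rows, variable, config.smoother)
        return ThresholdEstimate(variable, stratum, season, value, 0.0,
                                 n_reps_used=1, n_rows=n_rows, reliable=False)
    rng = np.random.default_rng(
        _stream_seed(config.seed, variable, stratum, season))
    year_col = np.asarray(rows["year"])
    estimates = np.empty(config.n_reps)
    for r in range(config.n_reps):
        chosen = rng.choice(years, size=config.years_per_rep, replace=False)
        pool = rows[np.isin(year_col, chosen)]
        if pool.empty or pool["area"].sum() <= 0:
            estimates[r] = np.nan
            continue
        estimates[r] = threshold_at_half(pool, variable, config.smoother)
    ok = estimates[~np.isnan(estimates)]
    if len(ok) == 0:
        raise EstimationError(f"all replicates empty for {variable}/{stratum}")
    sd = float(np.std(ok, ddof=1)) if len(ok) > 1 else 0.0
    return ThresholdEstimate(variable, stratum, season, float(np.mean(ok)), sd,
                             n_reps_used=len(ok), n_rows=n_rows,
                             reliable=reliable)


def _season_groups(rows: pd.DataFrame) -> dict[str, pd.DataFrame]:
    groups = {"annual": rows}
    if "season" in rows.columns:
        for s in ("MAM", "JJA", "SON"):
            sub = rows[rows["season"] == s]
            if len(sub):
                groups[s] = sub
    return groups


def estimate_all(paired: pd.DataFrame, config: ResampleConfig,
                 variables: tuple[str, ...] = FWI_VARIABLES,
                 by_ecozone: bool = True,
                 by_season: bool = True) -> pd.DataFrame:
    """Thresholds for every variable × stratum × season cell with data.

    Returns a long-format table (variable, stratum, season, mean, sd,
    n_reps_used, n_rows, reliable).
    """
    strata: dict[str, pd.DataFrame] = {"national": paired}
    if by_ecozone and "ecozone" in paired.columns:
        for z, sub in paired.groupby("ecozone"):
            strata[str(z)] = sub
    records = []
    for stratum, sub in strata.items():
        seasons = _season_groups(sub) if by_season else {"annual": sub}
        for season, cell in seasons.items():
            for var in variables:
                try:
                    est = resample_thresholds(cell, config, var, stratum, season)
                except EstimationError:
                    continue
                records.append(est.__dict__)
    return pd.DataFrame.from_records(records)


def summarize_ecozone_table(estimates: pd.DataFrame,
                            variables: tuple[str, ...] = FWI_VARIABLES
                            ) -> pd.DataFrame:
    """Summary row over ecozones: per-variable mean of means, mean of s.d.s.

    Mirrors the "mean (s.d.)" footer convention of per-ecozone threshold
    tables: the column mean of the ecozone means, with the column mean of the
    ecozone standard deviations in parentheses. Display rounding to 1 decimal.
    """
    rows = []
    for var in variables:
        sub = estimates[estimates["variable"] == var]
        if sub.empty:
            continue
        rows.append({
            "variable": var,
            "mean": round(float(sub["mean"].mean()), 1),
            "sd": round(float(sub["sd"].mean()), 1),
            "n_ecozones": len(sub),
        })
    return pd.DataFrame(rows)
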