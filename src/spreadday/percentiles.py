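"""Percentile expression of spread-day thresholds and area-above analysis.

Two complementary views of how extreme the threshold weather is:

* ``percentile_of_threshold`` places a threshold on the empirical distribution
  of the paired fire-growth-day weather values (the reference distribution is
  the paired rows within the stratum, not an all-days climatology).
* ``area_above_percentiles`` reports, for a ladder of percentiles p of that
  distribution, the percentage of total burned area that burned on days above
  the p-th percentile value — resampled over years exactly like the threshold
  estimator.

Percentile convention: linear interpolation between order statistics (the
"type 7" convention used by ``numpy.percentile``), with exact ties placed at
the midpoint of their run.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import isotonic_regression

from .thresholds import (
    ResampleConfig,
    cumulative_curve,
    fit_smooth_cdf,
    _stream_seed,
)

__all__ = [
    "PercentileLadder",
    "AreaAboveResult",
    "percentile_of_threshold",
    "area_above_percentiles",
    "percentile_table",
    "summarize_percentile_table",
]


@dataclass(frozen=True)
class PercentileLadder:
    """Ordered percentile cut-offs, default 50..95 by 5 then 99."""

    percentiles: tuple[float, ...] = (50, 55, 60, 65, 70, 75, 80, 85, 90, 95, 99)

    def __post_init__(self) -> None:
        p = np.asarray(self.percentiles, dtype=float)
        if len(p) == 0 or np.any(np.diff(p) <= 0) or p[0] <= 0 or p[-1] >= 100:
            raise ValueError("percentiles must be strictly increasing in (0, 100)")


@dataclass(frozen=True)
class AreaAboveResult:
    variable: str
    stratum: str
    percentile: float
    mean: float    # % of total area burned above the percentile value
    sd: float


def percentile_of_threshold(rows: pd.DataFrame | np.ndarray, variable: str | None,
                            threshold: float) -> tuple[float, bool]:
    """Empirical percentile of a threshold among the paired weather values.

    Returns ``(percentile, clamped)``; ``clamped`` is True when the threshold
    fell outside the observed range and the value was pinned to 0 or 100.
    Unweighted over rows: burned area plays no role here.
    """
    x = np.asarray(rows[variable] if variable is not None else rows, dtype=float)
    if len(x) < 2:
        raise ValueError("need at least 2 rows for a percentile")
    n = len(x)
    less = float(np.sum(x < threshold))
    equal = float(np.sum(x == threshold))
    if equal > 0:
        rank = less + 0.5 * equal - 0.5  # midpoint tie convention
        return 100.0 * rank / (n - 1), False
    if threshold < x.min():
        return 0.0, True
    if threshold > x.max():
        return 100.0, True
    below = x[x < threshold]
    above = x[x > threshold]
    x_lo, x_hi = below.max(), above.min()
    r_lo = float(np.sum(x < x_lo)) + 0.5 * float(np.sum(x == x_lo)) - 0.5
    r_hi = float(np.sum(x < x_hi)) + 0.5 * float(np.sum(x == x_hi)) - 0.5
    w = (threshold - x_lo) / (x_hi - x_lo)
    return 100.0 * (r_lo + w * (r_hi - r_lo)) / (n - 1), False


def _smoothed_fraction_at(rows: pd.DataFrame, variable: str, value: float,
                          smoother) -> float:
    """Smoothed cumulative area fraction evaluated at one index value."""
    values, cumfrac = cumulative_curve(rows, variable)
    if len(values) == 1:
        return 1.0 if value >= values[0] else 0.0
    smooth = fit_smooth_cdf(values, cumfrac, smoother)
    grid = np.linspace(values[0], values[-1], smoother.grid_points)
    mono = isotonic_regression(np.clip(smooth(grid), 0.0, 1.0)).x
    return float(np.interp(np.clip(value, grid[0], grid[-1]), grid, mono))


def area_above_percentiles(rows: pd.DataFrame, variable: str,
                           ladder: PercentileLadder,
                           config: ResampleConfig,
                           stratum: str = "national") -> list[AreaAboveResult]:
    """% of burned area above each percentile cut-off, over year replicates.

    Per replicate: resample years, take the p-th percentile of the variable
    over the replicate's rows, evaluate the smoothed monotone cumulative
    area curve there, and report ``100 * (1 - fraction)``. Mean and s.d.
    across replicates are returned per rung of the ladder.
    """
    years = (np.asarray(sorted(config.years_available))
             if config.years_available is not None
             else np.unique(np.asarray(rows["year"])))
    pct = np.asarray(ladder.percentiles, dtype=float)
    year_col = np.asarray(rows["year"])
    if len(years) < config.years_per_rep:
        reps = [rows]
    else:
        rng = np.random.default_rng(
            _stream_seed(config.seed, variable, stratum, "area_above"))
        reps = []
        for _ in range(config.n_reps):
            chosen = rng.choice(years, size=config.years_per_rep, replace=False)
            reps.append(rows[np.isin(year_col, chosen)])
    vals = np.full((len(reps), len(pct)), np.nan)
    for i, pool in enumerate(reps):
        if pool.empty or pool["area"].sum() <= 0:
            continue
        x = np.asarray(pool[variable], dtype=float)
        cutoffs = np.percentile(x, pct)  # type-7 linear interpolation
        values, cumfrac = cumulative_curve(pool, variable)
        if len(values) == 1:
            frac = (cutoffs >= values[0]).astype(float)
        else:
            smooth = fit_smooth_cdf(values, cumfrac, config.smoother)
            grid = np.linspace(values[0], values[-1], config.smoother.grid_points)
            mono = isotonic_regression(np.clip(smooth(grid), 0.0, 1.0)).x
            frac = np.interp(np.clip(cutoffs, grid[0], grid[-1]), grid, mono)
        vals[i] = np.clip(100.0 * (1.0 - frac), 0.0, 100.0)
    ok = vals[~np.isnan(vals).any(axis=1)]
    if len(ok) == 0:
        raise ValueError(f"no usable replicates for {variable}/{stratum}")
    means = ok.mean(axis=0)
    sds = ok.std(axis=0, ddof=1) if len(ok) > 1 else np.zeros(len(pct))
    return [AreaAboveResult(variable, stratum, float(p), float(m), float(s))
            for p, m, s in zip(pct, means, sds)]


def percentile_table(paired: pd.DataFrame, thresholds: pd.DataFrame,
                     variables: tuple[str, ...] | None = None) -> pd.DataFrame:
    """Percentile of each estimated threshold within its own stratum's rows.

    ``thresholds`` is the long-format output of ``estimate_all``; rows are
    matched on (stratum, season) and the threshold mean is placed on the
    stratum's paired-value distribution.
    """
    records = []
    for _, t in thresholds.iterrows():
        if variables is not None and t["variable"] not in variables:
            continue
        sub = paired
        if t["stratum"] != "national":
            sub = sub[sub["ecozone"] == t["stratum"]]
        if t["season"] != "annual":
            sub = sub[sub["season"] == t["season"]]
        if len(sub) < 2:
            continue
        p, clamped = percentile_of_threshold(sub, t["variable"], t["mean"])
        records.append({
            "variable": t["variable"], "stratum": t["stratum"],
            "season": t["season"], "threshold": t["mean"],
            "percentile": p, "clamped": clamped,
        })
    return pd.DataFrame.from_records(records)


def summarize_percentile_table(percentiles: pd.DataFrame,
                               variables: tuple[str, ...] | None = None
                               ) -> pd.DataFrame:
    """Summary row over ecozones: column mean and population s.d. per variable.

    Mirrors the "mean (s.d.)" footer of per-ecozone percentile tables, whose
    parenthetical is the population standard deviation (denominator n) of the
    printed ecozone values. Display rounding to 1 decimal.
    """
    if variables is None:
        variables = tuple(dict.fromkeys(percentiles["variable"]))
    rows = []
    for var in variables:
        x = np.asarray(
            percentiles.loc[percentiles["variable"] == var, "percentile"],
            dtype=float)
        if len(x) == 0:
            continue
        rows.append({
            "variable": var,
            "mean": round(float(x.mean()), 1),
            "sd": round(float(x.std(ddof=0)), 1),
            "n_ecozones": len(x),
        })
    return pd.DataFrame(rows)
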