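"""Potential vs. realized spread-day accounting.

A potential spread day (PSD) is a calendar day whose fire weather at a fire's
location exceeds a spread-day threshold; a realized spread day (RSD) is a
mapped daily-growth day of an actual fire whose paired value exceeds the same
threshold. The per-fire RSD/PSD ratio measures how much of the fire-weather
potential a fire actually used. Accounting is per variable, restricted to the
fast-reacting indices (FFMC, ISI, FWI), under either national or per-ecozone
thresholds.

Conventions: the PSD counting window is the fire's calendar year (optionally a
fire-season window, April–October); exceedance is strict (> threshold); the
daily spatial aggregate over a fire's paired grid points is the mean for FFMC
and ISI and the median for FWI, consistent with the footprint pairing rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FAST_VARIABLES",
    "ThresholdSource",
    "SpreadDayAccount",
    "AccountingError",
    "count_psd",
    "count_rsd",
    "build_accounts",
    "ratio_and_summaries",
    "summarize_ratio_table",
]

FAST_VARIABLES = ("ffmc", "isi", "fwi")

# Per-day spatial aggregation across a fire's paired grid points.
_DAY_AGG = {"ffmc": "mean", "isi": "mean", "fwi": "median"}


class AccountingError(ValueError):
    """Raised when spread days cannot be counted (e.g. empty weather series)."""


@dataclass(frozen=True)
class ThresholdSource:
    """Thresholds used for spread-day counting.

    ``scope`` is "national" (one value per variable) or "ecozone" (values maps
    are per-ecozone). ``values`` maps variable -> threshold for national scope,
    or ecozone -> {variable -> threshold} for ecozone scope.
    """

    scope: str
    values: dict = field(default_factory=dict)

    def threshold_for(self, variable: str, ecozone: str | None = None) -> float:
        if self.scope == "national":
            t = self.values[variable]
        else:
            t = self.values[ecozone][variable]
        if t <= 0:
            raise ValueError(f"threshold for {variable} must be positive")
        return float(t)


@dataclass(frozen=True)
class SpreadDayAccount:
    fire_id: str
    year: int
    ecozone: str
    variable: str
    threshold_source: str
    psd: int
    rsd: int

    @property
    def ratio(self) -> float:
        """RSD/PSD in [0, 1]; NaN when PSD is zero (undefined)."""
        return self.rsd / self.psd if self.psd > 0 else float("nan")


def _window_mask(dates: pd.Series, year: int, window: str) -> np.ndarray:
    d = pd.to_datetime(dates)
    mask = d.dt.year == year
    if window == "season":
        mask &= d.dt.month.between(4, 10)
    elif window != "annual":
        raise ValueError(f"unknown counting window {window!r}")
    return np.asarray(mask)


def count_psd(weather_series: pd.DataFrame, year: int, variable: str,
              threshold: float, window: str = "annual") -> int:
    """Days in the counting window whose aggregated index exceeds the threshold.

    ``weather_series`` holds the daily index values at the fire's paired grid
    points (columns ``date`` and the variable; multiple rows per date are
    aggregated by the variable's daily rule: mean for FFMC/ISI, median for
    FWI). Exceedance is strict.
    """
    if weather_series.empty:
        raise AccountingError("empty weather series for PSD counting")
    sub = weather_series[_window_mask(weather_series["date"], year, window)]
    if sub.empty:
        raise AccountingError(f"weather series does not cover year {year}")
    agg = _DAY_AGG.get(variable, "mean")
    daily = sub.groupby("date")[variable].agg(agg)
    return int((daily > threshold).sum())


def count_rsd(fire: pd.DataFrame, variable: str, threshold: float) -> int:
    """Mapped growth days of one fire whose paired value exceeds the threshold."""
    if fire.empty:
        return 0
    return int((np.asarray(fire[variable], dtype=float) > threshold).sum())


def build_accounts(paired: pd.DataFrame, weather_by_fire, source: ThresholdSource,
                   variables: tuple[str, ...] = FAST_VARIABLES,
                   window: str = "annual") -> list[SpreadDayAccount]:
    """Per-fire PSD/RSD accounts for every variable under one threshold source.

    ``weather_by_fire`` maps fire_id -> daily index table at the fire's paired
    grid points (as taken by :func:`count_psd`).
    """
    accounts = []
    for fire_id, fire in paired.groupby("fire_id"):
        year = int(fire["year"].iloc[0])
        ecozone = str(fire["ecozone"].iloc[0])
        series = weather_by_fire[fire_id]
        for var in variables:
            thr = source.threshold_for(var, ecozone)
            psd = count_psd(series, year, var, thr, window)
            rsd = count_rsd(fire, var, thr)
            accounts.append(SpreadDayAccount(
                fire_id=str(fire_id), year=year, ecozone=ecozone, variable=var,
                threshold_source=source.scope, psd=psd, rsd=rsd))
    return accounts


def ratio_and_summaries(accounts: list[SpreadDayAccount]
                        ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Summarize per-fire RSD/PSD ratios by ecozone × variable × source.

    Fires with zero PSDs have an undefined ratio and are excluded (their count
    is reported in the per-stratum table). Returns ``(per_fire, by_ecozone,
    summary)``: the per-fire ratio table (the density-curve export), the
    per-ecozone mean/s.d. of ratios as percentages, and a summary row per
    variable × source whose mean is the column mean of the ecozone means and
    whose s.d. is the column mean of the ecozone s.d.s.
    """
    per_fire = pd.DataFrame.from_records(
        [{**a.__dict__, "ratio": a.ratio} for a in accounts])
    if per_fire.empty:
        raise AccountingError("no accounts to summarize")
    usable = per_fire[per_fire["psd"] > 0].copy()
    usable["ratio_pct"] = 100.0 * usable["ratio"]
    dropped = (per_fire.groupby(["ecozone", "variable", "threshold_source"])
               .apply(lambda g: int((g["psd"] == 0).sum()), include_groups=False)
               .rename("n_zero_psd"))
    by_ecozone = (usable.groupby(["ecozone", "variable", "threshold_source"])
                  ["ratio_pct"]
                  .agg(mean="mean", sd=lambda x: x.std(ddof=1) if len(x) > 1 else 0.0,
                       n_fires="size")
                  .reset_index()
                  .merge(dropped.reset_index(),
                         on=["ecozone", "variable", "threshold_source"],
                         how="left"))
    return per_fire, by_ecozone, summarize_ratio_table(by_ecozone)


def summarize_ratio_table(by_ecozone: pd.DataFrame) -> pd.DataFrame:
    """Footer row of a per-ecozone ratio table.

    The summary mean is the column mean of the printed ecozone means and the
    parenthetical s.d. is the column mean of the printed ecozone s.d.s, per
    variable × threshold source. Display rounding to 1 decimal.
    """
    out = (by_ecozone.groupby(["variable", "threshold_source"])
           [["mean", "sd"]].mean().reset_index())
    out[["mean", "sd"]] = out[["mean", "sd"]].round(1)
    return out
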