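"""Daily Canadian Forest Fire Weather Index (FWI) System engine.

Implements the standard daily update of the six FWI System indices from noon
weather observations: the three fuel-moisture codes (FFMC, DMC, DC — surface
litter, duff and deep organic layers; higher = drier) and the three behaviour
indices (ISI, BUI, FWI — spread rate, fuel availability, intensity). The
update follows the classic 1985/1987 equation set: a rain phase that wets each
moisture code, a drying/wetting phase driven by temperature, humidity and wind,
month-indexed day-length factors for DMC and DC, then ISI from FFMC and wind,
BUI from DMC and DC, and FWI from ISI and BUI.

Conventions
-----------
* Weather inputs are noon values: temperature (deg C), relative humidity (%),
  10 m open wind speed (km/h), 24 h accumulated precipitation (mm).
* Startup codes default to the conventional spring values FFMC=85, DMC=6,
  DC=15; no overwintering of DC is applied — each season starts fresh.
* Day-length factors use the standard monthly tables for the northern
  (>= 30 deg N) band; set ``latitude_adjust=True`` to pick the band from the
  observation latitude.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from datetime import date as _date

import numpy as np
import pandas as pd

__all__ = [
    "WeatherDay",
    "FWIRecord",
    "WeatherValidationError",
    "StartupError",
    "init_codes",
    "step_codes",
    "compute_fwi_series",
    "DEFAULT_STARTUP",
]

# Conventional spring startup codes (FFMC, DMC, DC).
DEFAULT_STARTUP = (85.0, 6.0, 15.0)

# DMC day-length factors by month, per latitude band.
_DMC_DAYLENGTH = {
    "north": [6.5, 7.5, 9.0, 12.8, 13.9, 13.9, 12.4, 10.9, 9.4, 8.0, 7.0, 6.0],
    "tropical_n": [7.9, 8.4, 8.9, 9.5, 9.9, 10.2, 10.1, 9.7, 9.1, 8.6, 8.1, 7.8],
    "equatorial": [9.0] * 12,
    "tropical_s": [10.1, 9.6, 9.1, 8.5, 8.1, 7.8, 7.9, 8.3, 8.9, 9.4, 9.9, 10.2],
    "south": [11.5, 10.5, 9.2, 7.9, 6.8, 6.2, 6.5, 7.4, 8.7, 10.0, 11.2, 11.8],
}
# DC day-length adjustment by month (north band; sign-flipped offset for south).
_DC_DAYLENGTH = {
    "north": [-1.6, -1.6, -1.6, 0.9, 3.8, 5.8, 6.4, 5.0, 2.4, 0.4, -1.6, -1.6],
    "equatorial": [1.4] * 12,
    "south": [6.4, 5.0, 2.4, 0.4, -1.6, -1.6, -1.6, -1.6, -1.6, 0.9, 3.8, 5.8],
}


class WeatherValidationError(ValueError):
    """Raised when a noon weather observation is out of physical range."""


class StartupError(ValueError):
    """Raised when a daily update is attempted without previous codes."""


@dataclass(frozen=True)
class WeatherDay:
    """One station-day of noon weather inputs to the FWI System."""

    date: _date
    temp: float       # deg C at noon
    rh: float         # relative humidity, % in [0, 100]
    wind: float       # 10 m open wind, km/h
    precip: float     # 24 h accumulated precipitation, mm
    latitude: float = 55.0

    def validate(self) -> "WeatherDay":
        if not (0.0 <= self.rh <= 100.0):
            raise WeatherValidationError(f"rh={self.rh} outside [0, 100]")
        if self.wind < 0.0:
            raise WeatherValidationError(f"wind={self.wind} negative")
        if self.precip < 0.0:
            raise WeatherValidationError(f"precip={self.precip} negative")
        if not math.isfinite(self.temp):
            raise WeatherValidationError(f"temp={self.temp} not finite")
        return self


@dataclass(frozen=True)
class FWIRecord:
    """The six FWI System index values for one location-date."""

    date: _date | None
    ffmc: float
    dmc: float
    dc: float
    isi: float = 0.0
    bui: float = 0.0
    fwi: float = 0.0

    def validate(self) -> "FWIRecord":
        if not (0.0 <= self.ffmc <= 101.0):
            raise ValueError(f"ffmc={self.ffmc} outside [0, 101]")
        for name in ("dmc", "dc", "isi", "bui", "fwi"):
            if getattr(self, name) < 0.0:
                raise ValueError(f"{name}={getattr(self, name)} negative")
        return self


def init_codes(start_values: tuple[float, float, float] | None = None) -> FWIRecord:
    """Startup codes for a new station-year.

    ``start_values`` overrides the default (FFMC, DMC, DC) spring startup
    triple (85, 6, 15); behaviour indices start at zero.
    """
    ffmc, dmc, dc = DEFAULT_STARTUP if start_values is None else start_values
    if not (0.0 <= ffmc <= 101.0) or dmc < 0.0 or dc < 0.0:
        raise ValueError(
            f"invalid startup codes ffmc={ffmc}, dmc={dmc}, dc={dc}"
        )
    return FWIRecord(date=None, ffmc=float(ffmc), dmc=float(dmc), dc=float(dc))


def _daylength_band(latitude: float, adjust: bool) -> tuple[list[float], list[float]]:
    if not adjust or latitude > 30.0:
        return _DMC_DAYLENGTH["north"], _DC_DAYLENGTH["north"]
    if latitude > 10.0:
        return _DMC_DAYLENGTH["tropical_n"], _DC_DAYLENGTH["north"]
    if latitude > -10.0:
        return _DMC_DAYLENGTH["equatorial"], _DC_DAYLENGTH["equatorial"]
    if latitude > -30.0:
        return _DMC_DAYLENGTH["tropical_s"], _DC_DAYLENGTH["south"]
    return _DMC_DAYLENGTH["south"], _DC_DAYLENGTH["south"]


def _update_ffmc(ffmc0: float, temp: float, rh: float, wind: float,
                 precip: float) -> float:
    # fine-fuel moisture content from yesterday's code
    m = 147.2 * (101.0 - ffmc0) / (59.5 + ffmc0)
    if precip > 0.5:
        rf = precip - 0.5
        mr = m + 42.5 * rf * math.exp(-100.0 / (251.0 - m)) * (
            1.0 - math.exp(-6.93 / rf))
        if m > 150.0:
            mr += 0.0015 * (m - 150.0) ** 2 * math.sqrt(rf)
        m = min(mr, 250.0)
    e_dry = (0.942 * rh ** 0.679 + 11.0 * math.exp((rh - 100.0) / 10.0)
             + 0.18 * (21.1 - temp) * (1.0 - math.exp(-0.115 * rh)))
    if m > e_dry:
        k = (0.424 * (1.0 - (rh / 100.0) ** 1.7)
             + 0.0694 * math.sqrt(wind) * (1.0 - (rh / 100.0) ** 8))
        k *= 0.581 * math.exp(0.0365 * temp)
        m = e_dry + (m - e_dry) * 10.0 ** (-k)
    else:
        e_wet = (0.618 * rh ** 0.753 + 10.0 * math.exp((rh - 100.0) / 10.0)
                 + 0.18 * (21.1 - temp) * (1.0 - math.exp(-0.115 * rh)))
        if m < e_wet:
            k = (0.424 * (1.0 - ((100.0 - rh) / 100.0) ** 1.7)
                 + 0.0694 * math.sqrt(wind)
                 * (1.0 - ((100.0 - rh) / 100.0) ** 8))
            k *= 0.581 * math.exp(0.0365 * temp)
            m = e_wet - (e_wet - m) * 10.0 ** (-k)
    return min(max(59.5 * (250.0 - m) / (147.2 + m), 0.0), 101.0)


def _update_dmc(dmc0: float, temp: float, rh: float, precip: float,
                daylength: float) -> float:
    t = max(temp, -1.1)
    drying = 1.894 * (t + 1.1) * (100.0 - rh) * daylength * 1e-4
    if precip > 1.5:
        rw = 0.92 * precip - 1.27
        m0 = 20.0 + 280.0 / math.exp(0.023 * dmc0)
        if dmc0 <= 33.0:
            b = 100.0 / (0.5 + 0.3 * dmc0)
        elif dmc0 <= 65.0:
            b = 14.0 - 1.3 * math.log(dmc0)
        else:
            b = 6.2 * math.log(dmc0) - 17.2
        mr = m0 + 1000.0 * rw / (48.77 + b * rw)
        dmc0 = max(43.43 * (5.6348 - math.log(mr - 20.0)), 0.0)
    return max(dmc0 + drying, 0.0)


def _update_dc(dc0: float, temp: float, precip: float, dc_offset: float) -> float:
    t = max(temp, -2.8)
    evap = max((0.36 * (t + 2.8) + dc_offset) / 2.0, 0.0)
    if precip > 2.8:
        rw = 0.83 * precip - 1.27
        moisture_equiv = 800.0 * math.exp(-dc0 / 400.0)
        dc0 = max(dc0 - 400.0 * math.log(1.0 + 3.937 * rw / moisture_equiv), 0.0)
    return max(dc0 + evap, 0.0)


def _isi_from(ffmc: float, wind: float) -> float:
    m = 147.2 * (101.0 - ffmc) / (59.5 + ffmc)
    wind_fn = math.exp(0.05039 * wind)
    moisture_fn = 91.9 * math.exp(-0.1386 * m) * (1.0 + m ** 5.31 / 4.93e7)
    return 0.208 * wind_fn * moisture_fn


def _bui_from(dmc: float, dc: float) -> float:
    if dmc <= 0.0 and dc <= 0.0:
        return 0.0
    if dmc <= 0.4 * dc:
        return max(0.8 * dmc * dc / (dmc + 0.4 * dc), 0.0)
    return max(
        dmc - (1.0 - 0.8 * dc / (dmc + 0.4 * dc))
        * (0.92 + (0.0114 * dmc) ** 1.7),
        0.0,
    )


def _fwi_from(isi: float, bui: float) -> float:
    if bui <= 80.0:
        duff_fn = 0.626 * bui ** 0.809 + 2.0
    else:
        duff_fn = 1000.0 / (25.0 + 108.64 * math.exp(-0.023 * bui))
    b = 0.1 * isi * duff_fn
    if b <= 1.0:
        return b
    return math.exp(2.72 * (0.434 * math.log(b)) ** 0.647)


def step_codes(prev: FWIRecord, wx: WeatherDay, *,
               latitude_adjust: bool = False) -> FWIRecord:
    """Advance the FWI System by one day.

    Applies the rain phase then the drying/wetting phase to FFMC, DMC and DC,
    then derives ISI, BUI and FWI. ``prev`` carries yesterday's moisture
    codes; use :func:`init_codes` at season start.
    """
    if prev is None:
        raise StartupError("no previous codes; call init_codes() to start a season")
    prev.validate()
    wx.validate()
    month = wx.date.month
    el, fl = _daylength_band(wx.latitude, latitude_adjust)
    ffmc = _update_ffmc(prev.ffmc, wx.temp, wx.rh, wx.wind, wx.precip)
    dmc = _update_dmc(prev.dmc, wx.temp, wx.rh, wx.precip, el[month - 1])
    dc = _update_dc(prev.dc, wx.temp, wx.precip, fl[month - 1])
    isi = _isi_from(ffmc, wx.wind)
    bui = _bui_from(dmc, dc)
    fwi = _fwi_from(isi, bui)
    return FWIRecord(date=wx.date, ffmc=ffmc, dmc=dmc, dc=dc,
                     isi=isi, bui=bui, fwi=fwi).validate()


def compute_fwi_series(weather: pd.DataFrame, *,
                       start_values: tuple[float, float, float] | None = None,
                       restart_each_year: bool = True,
                       latitude: float = 55.0,
                       latitude_adjust: bool = False) -> pd.DataFrame:
    """Run the daily FWI System over a weather table.

    Parameters
    ----------
    weather
        Columns ``date, temp, rh, wind, precip`` (one row per day, sorted or
        sortable by date). An optional ``latitude`` column overrides the
        scalar ``latitude``.
    restart_each_year
        Reset the moisture codes to the startup triple on the first day of
        each calendar year (no overwintering of the Drought Code).

    Returns the input dates with columns ``ffmc, dmc, dc, isi, bui, fwi``.
    """
    wx = weather.sort_values("date").reset_index(drop=True)
    dates = pd.to_datetime(wx["date"])
    lat = wx["latitude"] if "latitude" in wx.columns else None
    out = np.empty((len(wx), 6), dtype=float)
    rec = init_codes(start_values)
    prev_year = None
    for i in range(len(wx)):
        d = dates.iloc[i]
        if restart_each_year and prev_year is not None and d.year != prev_year:
            rec = init_codes(start_values)
        prev_year = d.year
        day = WeatherDay(
            date=d.date(),
            temp=float(wx["temp"].iloc[i]),
            rh=float(wx["rh"].iloc[i]),
            wind=float(wx["wind"].iloc[i]),
            precip=float(wx["precip"].iloc[i]),
            latitude=float(lat.iloc[i]) if lat is not None else latitude,
        )
        rec = step_codes(rec, day, latitude_adjust=latitude_adjust)
        out[i] = (rec.ffmc, rec.dmc, rec.dc, rec.isi, rec.bui, rec.fwi)
    res = pd.DataFrame(out, columns=["ffmc", "dmc", "dc", "isi", "bui", "fwi"])
    res.insert(0, "date", dates.dt.date)
    return res
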