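"""Published Canadian spread-day reference values (2001–2021 analysis).

Per-ecozone results of the national spread-day threshold analysis of Canadian
fires, used as worked-example inputs: the 50%-area FWI System thresholds and
their percentiles by ecozone, and the per-fire RSD/PSD ratio summaries under
national and ecozone thresholds. Each table carries the printed per-ecozone
rows; the corresponding "mean (s.d.)" footer rows are *recomputed* from these
rows by the summary functions in :mod:`spreadday.thresholds`,
:mod:`spreadday.percentiles` and :mod:`spreadday.accounting`.

Ecozone codes: TP Taiga Plains, TSW/TSE Taiga Shield West/East, BSW/BSE
Boreal Shield West/East, BP Boreal Plains, TC Taiga Cordillera, BC Boreal
Cordillera, PM Pacific Maritime, MC Montane Cordillera, HP Hudson Plains.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "NATIONAL_THRESHOLDS",
    "ecozone_thresholds",
    "ecozone_threshold_sds",
    "ecozone_percentiles",
    "rsd_psd_ratios",
]

ECOZONES = ["TP", "TSW", "BSW", "BP", "TC", "BC", "PM", "MC", "HP", "BSE", "TSE"]

#: National all-year 50%-area thresholds (mean over 100 year-resampling reps).
NATIONAL_THRESHOLDS = {
    "ffmc": 89.4, "dmc": 44.0, "dc": 262.8, "isi": 7.5, "bui": 59.8, "fwi": 20.1,
}

_ECOZONE_THRESHOLD_MEANS = {
    "ffmc": [88.8, 89.1, 89.3, 90.1, 86.9, 88.1, 88.3, 90.8, 89.1, 90.2, 89.3],
    "dmc": [48.3, 47.8, 41.5, 47.0, 43.7, 38.7, 41.7, 75.3, 37.6, 39.0, 28.8],
    "dc": [366.1, 302.2, 255.5, 256.3, 238.2, 274.6, 286.3, 442.4, 227.9,
           147.7, 119.2],
    "isi": [6.5, 7.8, 7.4, 8.0, 4.7, 5.5, 4.9, 7.6, 8.5, 10.1, 9.3],
    "bui": [68.4, 66.5, 58.0, 62.7, 53.0, 55.9, 60.5, 106.2, 50.9, 46.7, 35.6],
    "fwi": [19.2, 21.1, 19.3, 22.0, 12.9, 14.7, 13.9, 25.3, 19.5, 21.7, 17.7],
}
_ECOZONE_THRESHOLD_SDS = {
    "ffmc": [0.3, 0.4, 0.3, 0.4, 1.3, 0.5, 1.1, 0.7, 0.9, 0.3, 0.4],
    "dmc": [5.4, 6.6, 1.5, 2.6, 5.8, 3.5, 5.2, 7.6, 5.0, 2.5, 3.0],
    "dc": [41.8, 27.2, 12.8, 36.7, 49.5, 33.1, 33.8, 27.4, 46.0, 18.8, 13.0],
    "isi": [0.3, 0.5, 0.4, 0.4, 0.6, 0.6, 0.6, 0.7, 1.5, 0.3, 1.4],
    "bui": [7.9, 7.5, 2.2, 3.9, 8.2, 4.9, 7.0, 10.2, 4.9, 3.2, 3.2],
    "fwi": [1.4, 1.6, 0.8, 1.1, 1.9, 1.4, 2.6, 3.0, 3.4, 1.0, 1.6],
}

#: Percentiles of the annual ecozone thresholds on the paired-day distribution.
_ECOZONE_PERCENTILES = {
    "ffmc": [63.7, 62.8, 67.6, 65.1, 58.4, 63.3, 57.3, 52.7, 67.5, 64.4, 68.9],
    "dmc": [65.5, 64.4, 66.0, 60.6, 64.1, 58.4, 53.9, 58.8, 68.3, 65.8, 57.1],
    "dc": [63.5, 52.9, 46.9, 38.2, 50.8, 50.7, 51.5, 64.0, 44.0, 58.2, 45.2],
    "isi": [67.3, 68.1, 68.7, 66.3, 61.6, 69.3, 55.3, 56.6, 69.6, 70.0, 72.5],
    "bui": [64.2, 63.8, 65.0, 54.5, 57.4, 58.6, 53.6, 62.3, 62.7, 68.7, 54.3],
    "fwi": [70.2, 69.7, 71.2, 68.4, 63.2, 68.0, 53.2, 58.2, 68.7, 73.1, 70.7],
}

#: Per-ecozone RSD/PSD ratio means (%) and s.d.s under each threshold source,
#: for the three fast-reacting variables.
_RATIO_MEANS = {
    ("national", "ffmc"): [14.4, 19.3, 14.6, 12.9, 26.2, 21.9, 21.3, 17.5,
                           14.6, 16.4, 18.8],
    ("national", "isi"): [13.9, 17.4, 13.2, 11.5, 23.1, 21.4, 23.8, 19.7,
                          14.0, 14.4, 14.0],
    ("national", "fwi"): [23.8, 26.9, 23.3, 16.4, 46.0, 40.2, 27.9, 26.0,
                          21.3, 28.0, 21.4],
    ("ecozone", "ffmc"): [22.2, 22.0, 21.0, 21.6, 28.8, 31.7, 21.1, 24.5,
                          17.8, 19.5, 20.7],
    ("ecozone", "isi"): [21.2, 20.4, 20.1, 21.2, 27.9, 32.1, 21.6, 24.3,
                         19.2, 24.5, 16.0],
    ("ecozone", "fwi"): [28.8, 28.4, 27.7, 25.0, 36.8, 42.1, 32.0, 32.7,
                         23.8, 35.4, 21.8],
}
_RATIO_SDS = {
    ("national", "ffmc"): [19.6, 22.5, 17.9, 18.7, 32.9, 25.7, 30.5, 20.4,
                           18.5, 21.0, 25.4],
    ("national", "isi"): [19.6, 18.8, 15.3, 16.5, 33.4, 27.9, 39.9, 23.0,
                          15.3, 16.3, 16.3],
    ("national", "fwi"): [30.2, 28.9, 27.9, 22.8, 39.9, 38.8, 40.0, 28.3,
                          25.2, 30.5, 28.6],
    ("ecozone", "ffmc"): [24.0, 23.7, 23.2, 25.7, 28.8, 27.4, 30.1, 26.7,
                          22.4, 25.0, 25.4],
    ("ecozone", "isi"): [23.7, 21.7, 21.4, 23.2, 29.4, 28.0, 27.0, 26.3,
                         22.4, 27.5, 21.5],
    ("ecozone", "fwi"): [31.8, 30.6, 29.5, 28.7, 36.1, 34.2, 33.8, 32.8,
                         27.2, 34.2, 26.3],
}


def ecozone_thresholds() -> pd.DataFrame:
    """Annual per-ecozone threshold means in the estimator's long format."""
    rows = []
    for var, means in _ECOZONE_THRESHOLD_MEANS.items():
        for z, m, s in zip(ECOZONES, means, _ECOZONE_THRESHOLD_SDS[var]):
            rows.append({"variable": var, "stratum": z, "season": "annual",
                         "mean": m, "sd": s})
    return pd.DataFrame(rows)


def ecozone_threshold_sds() -> pd.DataFrame:
    return ecozone_thresholds()[["variable", "stratum", "sd"]]


def ecozone_percentiles() -> pd.DataFrame:
    """Annual per-ecozone threshold percentiles in long format."""
    rows = []
    for var, pcts in _ECOZONE_PERCENTILES.items():
        for z, p in zip(ECOZONES, pcts):
            rows.append({"variable": var, "stratum": z, "season": "annual",
                         "percentile": p})
    return pd.DataFrame(rows)


def rsd_psd_ratios() -> pd.DataFrame:
    """Per-ecozone RSD/PSD ratio means and s.d.s (%) in long format."""
    rows = []
    for (source, var), means in _RATIO_MEANS.items():
        for z, m, s in zip(ECOZONES, means, _RATIO_SDS[(source, var)]):
            rows.append({"ecozone": z, "variable": var,
                         "threshold_source": source, "mean": m, "sd": s})
    return pd.DataFrame(rows)
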