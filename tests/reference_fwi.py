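"""Scalar reference implementation of the daily Canadian FWI System update.

A deliberately literal, FORTRAN-style transliteration of the standard 1985/1987
daily update equations (Van Wagner & Pickett constant set), kept independent of
the package implementation so it can serve as the oracle in equivalence tests.
Written before the package engine.
"""

import math

# DMC day-length factors (Le) and DC day-length adjustments (Lf), monthly,
# for the standard northern (>= 30 deg N) band.
_EL = [6.5, 7.5, 9.0, 12.8, 13.9, 13.9, 12.4, 10.9, 9.4, 8.0, 7.0, 6.0]
_FL = [-1.6, -1.6, -1.6, 0.9, 3.8, 5.8, 6.4, 5.0, 2.4, 0.4, -1.6, -1.6]


def ref_ffmc(ffmc0, temp, rh, wind, prec):
    wmo = 147.2 * (101.0 - ffmc0) / (59.5 + ffmc0)
    if prec > 0.5:
        ra = prec - 0.5
        if wmo > 150.0:
            wmo = (wmo + 0.0015 * (wmo - 150.0) ** 2 * math.sqrt(ra)
                   + 42.5 * ra * math.exp(-100.0 / (251.0 - wmo))
                   * (1.0 - math.exp(-6.93 / ra)))
        else:
            wmo = (wmo + 42.5 * ra * math.exp(-100.0 / (251.0 - wmo))
                   * (1.0 - math.exp(-6.93 / ra)))
        if wmo > 250.0:
            wmo = 250.0
    ed = (0.942 * rh ** 0.679 + 11.0 * math.exp((rh - 100.0) / 10.0)
          + 0.18 * (21.1 - temp) * (1.0 - math.exp(-0.115 * rh)))
    ew = (0.618 * rh ** 0.753 + 10.0 * math.exp((rh - 100.0) / 10.0)
          + 0.18 * (21.1 - temp) * (1.0 - math.exp(-0.115 * rh)))
    if wmo < ed and wmo < ew:
        z = (0.424 * (1.0 - ((100.0 - rh) / 100.0) ** 1.7)
             + 0.0694 * math.sqrt(wind) * (1.0 - ((100.0 - rh) / 100.0) ** 8))
        x = z * 0.581 * math.exp(0.0365 * temp)
        wm = ew - (ew - wmo) / (10.0 ** x)
    elif wmo > ed:
        z = (0.424 * (1.0 - (rh / 100.0) ** 1.7)
             + 0.0694 * math.sqrt(wind) * (1.0 - (rh / 100.0) ** 8))
        x = z * 0.581 * math.exp(0.0365 * temp)
        wm = ed + (wmo - ed) / (10.0 ** x)
    else:
        wm = wmo
    ffmc1 = 59.5 * (250.0 - wm) / (147.2 + wm)
    if ffmc1 > 101.0:
        ffmc1 = 101.0
    if ffmc1 < 0.0:
        ffmc1 = 0.0
    return ffmc1


def ref_dmc(dmc0, temp, rh, prec, month):
    if temp < -1.1:
        temp = -1.1
    rk = 1.894 * (temp + 1.1) * (100.0 - rh) * _EL[month - 1] * 1e-4
    if prec > 1.5:
        ra = prec
        rw = 0.92 * ra - 1.27
        wmi = 20.0 + 280.0 / math.exp(0.023 * dmc0)
        if dmc0 <= 33.0:
            b = 100.0 / (0.5 + 0.3 * dmc0)
        elif dmc0 <= 65.0:
            b = 14.0 - 1.3 * math.log(dmc0)
        else:
            b = 6.2 * math.log(dmc0) - 17.2
        wmr = wmi + 1000.0 * rw / (48.77 + b * rw)
        pr = 43.43 * (5.6348 - math.log(wmr - 20.0))
    else:
        pr = dmc0
    if pr < 0.0:
        pr = 0.0
    dmc1 = pr + rk
    if dmc1 < 0.0:
        dmc1 = 0.0
    return dmc1


def ref_dc(dc0, temp, prec, month):
    if temp < -2.8:
        temp = -2.8
    pe = (0.36 * (temp + 2.8) + _FL[month - 1]) / 2.0
    if pe < 0.0:
        pe = 0.0
    if prec > 2.8:
        ra = prec
        rw = 0.83 * ra - 1.27
        smi = 800.0 * math.exp(-dc0 / 400.0)
        dr0 = dc0 - 400.0 * math.log(1.0 + 3.937 * rw / smi)
        if dr0 < 0.0:
            dr0 = 0.0
        dc1 = dr0 + pe
    else:
        dc1 = dc0 + pe
    if dc1 < 0.0:
        dc1 = 0.0
    return dc1


def ref_isi(ffmc, wind):
    fm = 147.2 * (101.0 - ffmc) / (59.5 + ffmc)
    fw = math.exp(0.05039 * wind)
    ff = 91.9 * math.exp(-0.1386 * fm) * (1.0 + fm ** 5.31 / 4.93e7)
    return 0.208 * fw * ff


def ref_bui(dmc, dc):
    if dmc == 0.0 and dc == 0.0:
        return 0.0
    if dmc <= 0.4 * dc:
        bui1 = 0.8 * dc * dmc / (dmc + 0.4 * dc)
    else:
        bui1 = (dmc - (1.0 - 0.8 * dc / (dmc + 0.4 * dc))
                * (0.92 + (0.0114 * dmc) ** 1.7))
    if bui1 < 0.0:
        bui1 = 0.0
    return bui1


def ref_fwi(isi, bui):
    if bui > 80.0:
        bb = 0.1 * isi * (1000.0 / (25.0 + 108.64 / math.exp(0.023 * bui)))
    else:
        bb = 0.1 * isi * (0.626 * bui ** 0.809 + 2.0)
    if bb <= 1.0:
        return bb
    return math.exp(2.72 * (0.434 * math.log(bb)) ** 0.647)


def ref_step(ffmc0, dmc0, dc0, temp, rh, wind, prec, month):
    """One daily FWI System update; returns (ffmc, dmc, dc, isi, bui, fwi)."""
    ffmc1 = ref_ffmc(ffmc0, temp, rh, wind, prec)
    dmc1 = ref_dmc(dmc0, temp, rh, prec, month)
    dc1 = ref_dc(dc0, temp, prec, month)
    isi1 = ref_isi(ffmc1, wind)
    bui1 = ref_bui(dmc1, dc1)
    fwi1 = ref_fwi(isi1, bui1)
    return (ffmc1, dmc1, dc1, isi1, bui1, fwi1)
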