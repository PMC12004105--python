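"""Weather pairing: grid selection, regression kriging, aggregation rules."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest

from spreadday.growth import DailyGrowthDay
from spreadday.pairing import (
    BUFFER_EXTENDED_M,
    BUFFER_PRIMARY_M,
    PairingError,
    VariogramModel,
    _ordinary_krige,
    aggregate_pair,
    downscale,
    fit_variogram,
    pair_growth,
    season_of_month,
    select_grid_points,
)


def grid_df(xy, elevation, values, variable="ffmc"):
    df = pd.DataFrame({"x": xy[:, 0], "y": xy[:, 1],
                       "elevation": np.asarray(elevation, dtype=float)})
    df[variable] = np.asarray(values, dtype=float)
    return df


def footprint(cx=0.0, cy=0.0):
    return np.array([[cx, cy], [cx + 100.0, cy]])


def test_select_grid_points_two_stage():
    near = np.array([[10_000.0, 0.0], [0.0, 10_000.0],
                     [-10_000.0, 0.0], [0.0, -10_000.0]])
    g = grid_df(near, np.zeros(4), np.full(4, 80.0))
    sel = select_grid_points(footprint(), g, BUFFER_PRIMARY_M)
    assert len(sel) == 4
    far = near + 120_000.0  # beyond 50 km, inside 200 km
    g_far = grid_df(far, np.zeros(4), np.full(4, 80.0))
    assert len(select_grid_points(footprint(), g_far, BUFFER_PRIMARY_M)) == 0
    assert len(select_grid_points(footprint(), g_far, BUFFER_EXTENDED_M)) == 4
    with pytest.raises(PairingError):
        select_grid_points(footprint(), g.iloc[:0], BUFFER_PRIMARY_M)


def test_constant_field_reproduced():
    xy = np.array([[0.0, 0], [20_000, 0], [0, 20_000], [20_000, 20_000],
                   [10_000, 10_000]])
    g = grid_df(xy, np.zeros(5), np.full(5, 87.5))
    targets = np.array([[5_000.0, 5_000.0, 0.0], [15_000.0, 5_000.0, 0.0]])
    vals, method = downscale(g, targets, "ffmc")
    assert vals == pytest.approx(np.full(2, 87.5), abs=1e-9)
    assert method == "trend"


def test_linear_elevation_law_recovered():
    """Values exactly linear in elevation downscale to the same linear law."""
    rng = np.random.default_rng(0)
    xy = rng.uniform(0, 50_000, (12, 2))
    elev = rng.uniform(200, 1500, 12)
    vals = 40.0 + 0.01 * elev
    g = grid_df(xy, elev, vals, variable="dmc")
    tgt_elev = np.array([300.0, 900.0, 1400.0])
    targets = np.column_stack([rng.uniform(0, 50_000, (3, 2)), tgt_elev])
    out, method = downscale(g, targets, "dmc")
    assert out == pytest.approx(40.0 + 0.01 * tgt_elev, abs=1e-6)
    assert method == "trend"


def test_kriging_exactness_at_sources_with_zero_nugget():
    """Ordinary kriging honours the data exactly when the nugget is zero."""
    rng = np.random.default_rng(1)
    xy = rng.uniform(0, 40_000, (15, 2))
    resid = rng.normal(0, 2.0, 15)
    vgm = VariogramModel("exponential", nugget=0.0, psill=4.0, range_=20_000.0)
    back = _ordinary_krige(xy, resid, xy, vgm)
    assert back == pytest.approx(resid, abs=1e-6)


def test_spatial_field_interpolated_by_kriging():
    """A smooth spatial residual field engages the kriging path."""
    rng = np.random.default_rng(2)
    xy = rng.uniform(0, 60_000, (40, 2))
    vals = 50.0 + 10.0 * np.sin(xy[:, 0] / 20_000.0)
    g = grid_df(xy, np.zeros(40), vals, variable="dc")
    targets = np.column_stack([rng.uniform(10_000, 50_000, (5, 2)), np.zeros(5)])
    out, method = downscale(g, targets, "dc")
    truth = 50.0 + 10.0 * np.sin(targets[:, 0] / 20_000.0)
    assert method == "kriging"
    assert out == pytest.approx(truth, abs=2.5)


def test_variogram_requires_spread_and_points():
    xy = np.zeros((5, 2))  # all points co-located: no spatial structure
    with pytest.raises(PairingError):
        fit_variogram(xy, np.array([1.0, 2.0, 3.0, 4.0, 5.0]))
    with pytest.raises(PairingError):
        fit_variogram(np.zeros((3, 2)), np.zeros(3))


def test_degenerate_geometry_falls_back_to_idw():
    """Co-located grid points defeat the variogram; IDW fallback is used."""
    xy = np.array([[0.0, 0.0]] * 4 + [[1.0, 0.0]])
    g = grid_df(xy, np.zeros(5), [80, 80, 80, 80, 84.0])
    targets = np.array([[1.0, 0.0, 0.0]])
    out, method = downscale(g, targets, "ffmc")
    assert method == "idw"
    assert out[0] == pytest.approx(84.0, abs=1e-6)  # exact hit at a source


def test_too_few_points_is_a_pairing_failure():
    xy = np.array([[0.0, 0.0], [1000.0, 0.0], [0.0, 1000.0]])
    g = grid_df(xy, np.zeros(3), np.full(3, 80.0))
    with pytest.raises(PairingError, match="< 4"):
        downscale(g, np.array([[0.0, 0.0, 0.0]]), "ffmc")


def growth_day(date=dt.date(2021, 4, 15)):
    cells = np.array([[0.0, 0.0], [100.0, 0.0], [0.0, 100.0]])
    return DailyGrowthDay(fire_id="F", date=date, area_ha=3.0, cells=cells,
                          cell_size=100.0)


def test_aggregate_means_and_fwi_median():
    fine = {v: np.array([10.0, 20.0, 30.0]) for v in
            ("ffmc", "dmc", "dc", "isi", "bui", "fwi")}
    fine["ffmc"] = np.array([88.0, 90.0, 88.0])
    row = aggregate_pair(growth_day(), fine)
    assert row["fwi"] == 20.0          # median of {10, 20, 30}
    assert row["ffmc"] == pytest.approx(266.0 / 3)
    assert row["season"] == "MAM"      # mid-April is spring
    # aggregates stay inside the range of the fine values
    for v in ("dmc", "dc", "isi", "bui", "fwi"):
        assert 10.0 <= row[v] <= 30.0


def test_fwi_median_even_count_uses_midpoint():
    fine = {v: np.array([10.0, 20.0]) for v in
            ("ffmc", "dmc", "dc", "isi", "bui", "fwi")}
    row = aggregate_pair(growth_day(), fine)
    assert row["fwi"] == 15.0
    assert row["ffmc"] == 15.0


def test_winter_months_have_no_season_label():
    assert season_of_month(12) is None
    assert season_of_month(1) is None
    assert season_of_month(2) is None
    assert season_of_month(3) == "MAM"
    assert season_of_month(9) == "SON"


def test_pair_growth_end_to_end(small_dataset):
    """A mapped synthetic fire pairs to values close to its generation truth."""
    from spreadday.growth import Hotspot, map_daily_growth
    from spreadday.synthetic import elevation_surface, generate_weather_grid
    p = small_dataset.perimeters[0]
    sub = small_dataset.hotspots[small_dataset.hotspots["fire_id"] == p.fire_id]
    hs = [Hotspot(x=r.x, y=r.y, date=r.date, sensor=r.sensor)
          for r in sub.itertuples()]
    days = map_daily_growth(p, hs, cell_size=100.0)
    grid = generate_weather_grid(small_dataset.config, small_dataset.fwi,
                                 p.geometry.bounds, sorted({d.date for d in days}))
    paired = pair_growth(days, grid, elevation_surface,
                         ecozone=p.ecozone, year=p.year)
    truth = small_dataset.growth[small_dataset.growth["fire_id"] == p.fire_id]
    merged = paired.merge(truth, on="date", suffixes=("", "_truth"))
    assert len(merged) == len(paired) > 0
    # the synthetic grid perturbs the base series by ~1-2 FFMC units at most
    assert np.abs(merged["ffmc"] - merged["ffmc_truth"]).max() < 3.0
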