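"""Daily growth delineation: oracle equivalence, conservation, tie rules."""

import datetime as dt

import numpy as np
import pytest
from shapely.geometry import Point, Polygon

from spreadday.growth import (
    FirePerimeter,
    GrowthMappingError,
    Hotspot,
    growth_table,
    map_daily_growth,
)


def square_fire(side_m=3000.0, fire_id="T1", year=2010):
    geom = Polygon([(0, 0), (side_m, 0), (side_m, side_m), (0, side_m)])
    return FirePerimeter(fire_id=fire_id, year=year, geometry=geom, ecozone="BP")


def brute_force_dates(cells, hotspots):
    """Per-cell nearest-hotspot date, ties to the earlier date."""
    out = np.empty(len(cells), dtype=np.int64)
    for i, (x, y) in enumerate(cells):
        d = [np.hypot(x - h.x, y - h.y) for h in hotspots]
        dmin = min(d)
        out[i] = min(h.date.toordinal() for h, dd in zip(hotspots, d)
                     if dd <= dmin * (1 + 1e-9) + 1e-9)
    return out


def test_single_date_yields_single_growth_day():
    fire = square_fire()
    hs = [Hotspot(500, 500, dt.date(2010, 7, 1)),
          Hotspot(2500, 2500, dt.date(2010, 7, 1))]
    days = map_daily_growth(fire, hs, cell_size=100.0)
    assert len(days) == 1
    assert days[0].date == dt.date(2010, 7, 1)
    assert days[0].area_ha == pytest.approx(fire.area_ha, rel=0.05)


def test_two_hotspots_split_by_nearest_distance():
    fire = square_fire()
    hs = [Hotspot(0, 1500, dt.date(2010, 7, 1)),
          Hotspot(3000, 1500, dt.date(2010, 7, 3))]
    days = map_daily_growth(fire, hs, cell_size=100.0)
    cells = np.vstack([d.cells for d in days])
    got = np.concatenate([np.full(len(d.cells), d.date.toordinal()) for d in days])
    expected = brute_force_dates(cells, hs)
    assert (got == expected).all()
    # only hotspot dates appear
    assert {d.date for d in days} <= {h.date for h in hs}


def test_random_fires_match_brute_force(small_dataset):
    """Nearest-hotspot assignment equals per-cell brute force on random fires."""
    checked = 0
    for p in small_dataset.perimeters[:5]:
        sub = small_dataset.hotspots[small_dataset.hotspots["fire_id"] == p.fire_id]
        hs = [Hotspot(x=r.x, y=r.y, date=r.date, sensor=r.sensor)
              for r in sub.itertuples()]
        days = map_daily_growth(p, hs, cell_size=120.0)
        cells = np.vstack([d.cells for d in days])
        got = np.concatenate(
            [np.full(len(d.cells), d.date.toordinal()) for d in days])
        order = np.lexsort((cells[:, 1], cells[:, 0]))
        expected = brute_force_dates(cells[order], hs)
        assert (got[order] == expected).all()
        checked += 1
    assert checked == 5


def test_area_conservation_within_boundary_tolerance(small_dataset):
    for p in small_dataset.perimeters[:5]:
        sub = small_dataset.hotspots[small_dataset.hotspots["fire_id"] == p.fire_id]
        hs = [Hotspot(x=r.x, y=r.y, date=r.date) for r in sub.itertuples()]
        cell = 100.0
        days = map_daily_growth(p, hs, cell_size=cell)
        mapped = sum(d.area_ha for d in days)
        n_boundary = p.geometry.exterior.length / cell + 4
        tol_ha = n_boundary * cell**2 / 1e4
        assert abs(mapped - p.area_ha) <= tol_ha


def test_hotspot_outside_tolerance_is_ignored():
    fire = square_fire()
    far = Hotspot(9000, 9000, dt.date(2010, 7, 9))  # ~8.5 km outside
    near = Hotspot(1500, 1500, dt.date(2010, 7, 1))
    days = map_daily_growth(fire, [near, far], cell_size=100.0)
    assert {d.date for d in days} == {dt.date(2010, 7, 1)}
    with pytest.raises(GrowthMappingError, match="no usable hotspots"):
        map_daily_growth(fire, [far], cell_size=100.0)


def test_hotspot_within_sensor_tolerance_is_kept():
    fire = square_fire()
    # 400 m outside: beyond VIIRS half-footprint, inside MODIS half-footprint
    edge_modis = Hotspot(3400, 1500, dt.date(2010, 7, 2), sensor="MODIS")
    edge_viirs = Hotspot(3400, 1500, dt.date(2010, 7, 2), sensor="VIIRS")
    inside = Hotspot(100, 1500, dt.date(2010, 7, 1))
    days = map_daily_growth(fire, [inside, edge_modis], cell_size=200.0)
    assert {d.date for d in days} == {dt.date(2010, 7, 1), dt.date(2010, 7, 2)}
    days = map_daily_growth(fire, [inside, edge_viirs], cell_size=200.0)
    assert {d.date for d in days} == {dt.date(2010, 7, 1)}


def test_equidistant_tie_goes_to_earlier_date():
    fire = square_fire()
    # both hotspots equidistant from every cell on the vertical midline
    hs = [Hotspot(1000, 1500, dt.date(2010, 7, 5)),
          Hotspot(2000, 1500, dt.date(2010, 7, 2))]
    # cell size 200 puts a column of cell centres exactly on the midline x=1500
    days = map_daily_growth(fire, hs, cell_size=200.0)
    by_date = {d.date: d for d in days}
    midline = np.isclose(np.vstack([d.cells for d in days])[:, 0], 1500.0)
    assert midline.any()
    early = by_date[dt.date(2010, 7, 2)].cells
    assert np.isclose(early[:, 0], 1500.0).sum() == midline.sum()


def test_true_dates_recovered_on_well_observed_fires():
    """>= 90% of cells get their true burn date with dense, unjittered hotspots."""
    from spreadday.synthetic import SyntheticConfig, generate_dataset
    cfg = SyntheticConfig(seed=21, n_years=3, n_fires_per_year=4,
                          hotspot_density=16.0, area_median_ha=400.0,
                          area_sigma=0.4, growth_days_mean=3.0)
    ds = generate_dataset(cfg)
    good = total = 0
    for p in ds.perimeters:
        truth = ds.growth[ds.growth["fire_id"] == p.fire_id].sort_values("date")
        radii = np.sqrt(np.cumsum(truth["area"].to_numpy()) * 1e4 / np.pi)
        cx, cy = p.geometry.centroid.x, p.geometry.centroid.y
        sub = ds.hotspots[ds.hotspots["fire_id"] == p.fire_id]
        hs = [Hotspot(x=r.x, y=r.y, date=r.date) for r in sub.itertuples()]
        days = map_daily_growth(p, hs, cell_size=60.0)
        dates = list(truth["date"])
        for d in days:
            rr = np.hypot(d.cells[:, 0] - cx, d.cells[:, 1] - cy)
            annulus = np.clip(np.searchsorted(radii, rr), 0, len(dates) - 1)
            true_ord = np.array([dates[a].toordinal() for a in annulus])
            good += int((true_ord == d.date.toordinal()).sum())
            total += len(d.cells)
    assert good / total >= 0.90


def test_smoothed_interpolation_stays_within_date_range():
    fire = square_fire()
    hs = [Hotspot(300, 300, dt.date(2010, 7, 1)),
          Hotspot(1500, 1500, dt.date(2010, 7, 4)),
          Hotspot(2700, 2700, dt.date(2010, 7, 9))]
    days = map_daily_growth(fire, hs, cell_size=100.0, method="idw")
    dates = sorted(d.date for d in days)
    assert dates[0] >= dt.date(2010, 7, 1) and dates[-1] <= dt.date(2010, 7, 9)
    # the smoothed surface interpolates: more than the three input dates appear
    assert len(dates) >= 3


def test_growth_table_carries_fire_metadata():
    fire = square_fire()
    hs = [Hotspot(1500, 1500, dt.date(2010, 7, 1))]
    df = growth_table(map_daily_growth(fire, hs, cell_size=200.0), fire)
    assert set(df.columns) == {"fire_id", "date", "area", "year", "ecozone"}
    assert (df["ecozone"] == "BP").all()


def test_undersized_fire_rejected():
    geom = Point(0, 0).buffer(300.0)  # ~28 ha
    fire = FirePerimeter(fire_id="small", year=2010, geometry=geom)
    with pytest.raises(ValueError, match="50 ha"):
        map_daily_growth(fire, [Hotspot(0, 0, dt.date(2010, 7, 1))], 50.0)
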