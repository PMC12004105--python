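"""Threshold estimation: curve oracles, smoother accuracy, resampling."""

import numpy as np
import pandas as pd
import pytest

from spreadday.reference_tables import ecozone_thresholds
from spreadday.thresholds import (
    EstimationError,
    ResampleConfig,
    area_weighted_quantile,
    cumulative_curve,
    estimate_all,
    resample_thresholds,
    summarize_ecozone_table,
    threshold_at_half,
)

from .conftest import make_paired


def brute_cumulative(values, areas):
    """Independent oracle: sorted cumulative area fraction with merged ties."""
    order = np.argsort(values, kind="stable")
    v = np.asarray(values, dtype=float)[order]
    a = np.asarray(areas, dtype=float)[order]
    knots, cum = [], []
    running = 0.0
    for i in range(len(v)):
        running += a[i]
        if i + 1 == len(v) or v[i + 1] != v[i]:
            knots.append(v[i])
            cum.append(running)
    return np.asarray(knots), np.asarray(cum) / running


def test_cumulative_curve_single_and_double_mass():
    v, c = cumulative_curve(make_paired([90.0], [100.0]), "ffmc")
    assert v.tolist() == [90.0] and c.tolist() == [1.0]
    v, c = cumulative_curve(make_paired([80.0, 90.0], [1.0, 1.0]), "ffmc")
    assert v.tolist() == [80.0, 90.0]
    assert c.tolist() == [0.5, 1.0]


def test_cumulative_curve_matches_brute_force_oracle():
    rng = np.random.default_rng(10)
    values = rng.normal(60, 15, 1000).round(1)  # rounding forces ties
    areas = rng.lognormal(3, 1, 1000)
    v, c = cumulative_curve(make_paired(values, areas), "ffmc")
    bv, bc = brute_cumulative(values, areas)
    assert v == pytest.approx(bv)
    assert c == pytest.approx(bc, abs=1e-12)
    assert np.all(np.diff(c) >= 0) and c[-1] == 1.0


def test_zero_total_area_is_an_error():
    with pytest.raises(EstimationError):
        cumulative_curve(make_paired([1.0, 2.0], [0.0, 0.0]), "ffmc")


def test_threshold_degenerate_and_two_point_cases():
    assert threshold_at_half(make_paired([90.0] * 5, [10.0] * 5), "ffmc") == 90.0
    two = make_paired([80.0, 90.0], [1.0, 1.0])
    t = threshold_at_half(two, "ffmc")
    assert 80.0 <= t <= 90.0
    # the area-weighted interpolation convention places it at the midpoint
    assert t == pytest.approx(85.0)


def test_weighted_quantile_conventions():
    assert area_weighted_quantile(np.array([80.0, 90.0]),
                                  np.array([1.0, 1.0])) == pytest.approx(85.0)
    assert area_weighted_quantile(np.array([90.0]), np.array([5.0])) == 90.0
    # heavier mass pulls the midpoint position toward its value
    q = area_weighted_quantile(np.array([80.0, 90.0]), np.array([3.0, 1.0]))
    assert q < 85.0


def test_smoothed_threshold_tracks_weighted_median(paired_rows):
    """Spline threshold agrees with the area-weighted median oracle (<=2% range)."""
    for var in ("ffmc", "dmc", "isi", "fwi"):
        t = threshold_at_half(paired_rows, var)
        oracle = area_weighted_quantile(paired_rows[var].to_numpy(),
                                        paired_rows["area"].to_numpy())
        rng_span = paired_rows[var].max() - paired_rows[var].min()
        assert abs(t - oracle) <= 0.02 * rng_span, var


def test_parameter_recovery_on_synthetic_truth():
    from spreadday.synthetic import SyntheticConfig, generate_dataset
    cfg = SyntheticConfig(seed=17, n_years=21, n_fires_per_year=70,
                          true_threshold={"ffmc": 89.0})
    g = generate_dataset(cfg).growth
    assert len(g) >= 5000
    assert threshold_at_half(g, "ffmc") == pytest.approx(89.0, abs=0.5)


def test_resampling_is_deterministic_under_fixed_seed(paired_rows):
    cfg = ResampleConfig(n_reps=20, years_per_rep=4, seed=9)
    a = resample_thresholds(paired_rows, cfg, "ffmc")
    b = resample_thresholds(paired_rows, cfg, "ffmc")
    assert a == b
    assert a.sd > 0.0
    c = resample_thresholds(paired_rows, cfg, "ffmc", season="JJA")
    assert c != a  # separate RNG stream per stratum/season cell


def test_identical_years_give_zero_sd():
    """If every year holds the same rows, year resampling has no variance."""
    base_v = np.linspace(70, 95, 40)
    base_a = np.full(40, 10.0)
    frames = [make_paired(base_v, base_a, years=np.full(40, y))
              for y in range(2001, 2011)]
    rows = pd.concat(frames, ignore_index=True)
    est = resample_thresholds(rows, ResampleConfig(n_reps=25, years_per_rep=4,
                                                   seed=2), "ffmc")
    assert est.sd == pytest.approx(0.0, abs=1e-12)


def test_subset_consistency_single_full_replicate(paired_rows):
    years = sorted(paired_rows["year"].unique())
    cfg = ResampleConfig(n_reps=1, years_per_rep=len(years), seed=0)
    est = resample_thresholds(paired_rows, cfg, "ffmc")
    assert est.mean == pytest.approx(threshold_at_half(paired_rows, "ffmc"))
    assert est.sd == 0.0


def test_insufficient_years_flags_unreliable():
    rows = make_paired(np.linspace(70, 95, 50), np.full(50, 1.0),
                       years=np.full(50, 2001))
    est = resample_thresholds(rows, ResampleConfig(years_per_rep=10, seed=1),
                              "ffmc")
    assert est.n_reps_used == 1 and not est.reliable


def test_estimate_all_produces_strata(paired_rows):
    cfg = ResampleConfig(n_reps=5, years_per_rep=3, seed=4)
    table = estimate_all(paired_rows, cfg, variables=("ffmc",))
    assert "national" in set(table["stratum"])
    assert "annual" in set(table["season"])
    nat = table[(table["stratum"] == "national") & (table["season"] == "annual")]
    assert len(nat) == 1 and nat.iloc[0]["sd"] >= 0


def test_ecozone_footer_reproduces_published_summary():
    """Column means of the 11 published ecozone rows give the printed footer."""
    summary = summarize_ecozone_table(ecozone_thresholds())
    by_var = summary.set_index("variable")
    assert by_var.loc["ffmc", "mean"] == 89.1
    assert by_var.loc["dc", "mean"] == 265.1
    assert by_var.loc["ffmc", "sd"] == 0.6
    assert (by_var["n_ecozones"] == 11).all()


def test_single_ecozone_summary_is_identity():
    one = pd.DataFrame([{"variable": "ffmc", "stratum": "BP", "season": "annual",
                         "mean": 90.1, "sd": 0.4}])
    s = summarize_ecozone_table(one, variables=("ffmc",))
    assert s.iloc[0]["mean"] == 90.1 and s.iloc[0]["sd"] == 0.4
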