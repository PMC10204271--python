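"""Site selection, studentized bootstrap, run-length rule, shell profiles."""

import numpy as np
import pandas as pd
import pytest

from dyntract.roi_stats import (
    FlatMapGeometry,
    bonferroni_comparisons,
    detect_significant_runs,
    distance_shell_profile,
    select_analysis_sites,
    studentized_bootstrap,
)
from dyntract.spectral import ALPHA, EpochGrid, PercentChangeMap


def _table(rows):
    return pd.DataFrame(rows, columns=["site_id", "roi", "hemisphere", "excluded"])


def test_roi_with_three_clean_sites_is_dropped():
    rows = [(f"s{i}", "occ", "L", False) for i in range(3)]
    rows += [(f"t{i}", "fus", "L", False) for i in range(4)]
    _, retained = select_analysis_sites(_table(rows))
    assert retained == [("fus", "L")]


def test_excluded_sites_never_enter_statistics():
    rows = [(f"s{i}", "occ", "L", i == 0) for i in range(5)]
    included, retained = select_analysis_sites(_table(rows))
    assert "s0" not in set(included["site_id"])
    assert retained == [("occ", "L")]  # 4 clean sites remain


def test_all_clean_is_identity():
    rows = [(f"s{i}", "occ", "L", False) for i in range(4)]
    included, retained = select_analysis_sites(_table(rows))
    assert len(included) == 4 and retained == [("occ", "L")]


def test_hand_counted_fixture():
    rows = (
        [(f"a{i}", "occ", "L", i < 2) for i in range(6)]       # 4 clean -> kept
        + [(f"b{i}", "occ", "R", i < 3) for i in range(6)]     # 3 clean -> dropped
        + [(f"c{i}", "pIFG", "L", False) for i in range(5)]    # 5 clean -> kept
    )
    _, retained = select_analysis_sites(_table(rows))
    assert sorted(retained) == [("occ", "L"), ("pIFG", "L")]


def test_empty_table_raises():
    with pytest.raises(ValueError):
        select_analysis_sites(_table([]))


# ---------------------------------------------------------------------------
# bootstrap

def test_degenerate_values_give_point_interval():
    m, lo, hi = studentized_bootstrap(np.full(5, 7.0), 0.95, 1000, seed=0)
    assert (m, lo, hi) == (7.0, 7.0, 7.0)


def test_interval_contains_sample_mean():
    rng = np.random.default_rng(4)
    for _ in range(5):
        v = rng.normal(size=12)
        m, lo, hi = studentized_bootstrap(v, 0.95, 2000, seed=rng)
        assert lo <= m <= hi
        assert m == pytest.approx(v.mean())


def test_deterministic_under_fixed_seed():
    v = np.random.default_rng(8).normal(size=(10, 5))
    a = studentized_bootstrap(v, 0.99, 2000, seed=42)
    b = studentized_bootstrap(v, 0.99, 2000, seed=42)
    for x, y in zip(a, b):
        np.testing.assert_array_equal(x, y)


def test_too_few_values_or_resamples_raise():
    with pytest.raises(ValueError):
        studentized_bootstrap(np.array([1.0]), 0.95, 2000)
    with pytest.raises(ValueError):
        studentized_bootstrap(np.ones(5), 0.95, 10)


def test_wider_level_shrinks_significance_mask():
    """99% significance masks contain the 99.99% masks (monotone in level)."""
    rng = np.random.default_rng(11)
    v = rng.normal(loc=1.0, scale=1.0, size=(8, 40))
    _, lo99, hi99 = studentized_bootstrap(v, 0.99, 5000, seed=1)
    _, lo9999, hi9999 = studentized_bootstrap(v, 0.9999, 5000, seed=1)
    centers = np.arange(40.0)
    m99 = detect_significant_runs(lo99, hi99, centers, min_run=3)
    m9999 = detect_significant_runs(lo9999, hi9999, centers, min_run=3)
    assert np.all(m99.aug_mask | ~m9999.aug_mask)  # 9999 ⊆ 99
    assert np.all(m99.att_mask | ~m9999.att_mask)


# ---------------------------------------------------------------------------
# run-length rule

def _bounds(sig_bins, n=20, value=1.0):
    lo = np.full(n, -1.0)
    hi = np.full(n, 2.0)
    lo[sig_bins] = value
    return lo, hi


def test_exactly_eight_bins_is_one_run():
    lo, hi = _bounds(slice(5, 13))
    res = detect_significant_runs(lo, hi, np.arange(20) * 25.0)
    assert res.aug_mask.sum() == 8
    assert res.onset_ms == 5 * 25.0
    assert res.onset_aug_ms == 5 * 25.0 and res.onset_att_ms is None


def test_seven_bins_is_not_significant():
    lo, hi = _bounds(slice(5, 12))
    res = detect_significant_runs(lo, hi, np.arange(20) * 25.0)
    assert not res.aug_mask.any()
    assert res.onset_ms is None


def test_straddling_bounds_give_empty_masks():
    lo = np.full(20, -1.0)
    hi = np.full(20, 1.0)
    res = detect_significant_runs(lo, hi, np.arange(20) * 25.0)
    assert not res.aug_mask.any() and not res.att_mask.any()
    assert res.onset_ms is None


def test_attenuation_mirror():
    lo = np.full(20, -2.0)
    hi = np.full(20, 1.0)
    hi[4:14] = -0.5
    res = detect_significant_runs(lo, hi, np.arange(20) * 25.0)
    assert res.att_mask.sum() == 10 and res.onset_att_ms == 100.0


def test_bonferroni_equivalence_500_comparisons():
    assert bonferroni_comparisons(0.9999, 0.05) == pytest.approx(500.0)


# ---------------------------------------------------------------------------
# distance shells

def _pct_map(site_values: dict[str, float], n_bins=None):
    grid = EpochGrid.for_band(ALPHA)
    n = grid.centers.size
    sites = list(site_values)
    values = np.stack([np.full(n, site_values[s]) for s in sites])
    return PercentChangeMap("alpha", "closure_onset", sites, grid, values, 8)


def _electrodes(positions: dict[str, tuple[float, float]]):
    return pd.DataFrame(
        [
            {"site_id": s, "roi": "occ", "hemisphere": "L", "excluded": False,
             "flat_x_mm": x, "flat_y_mm": y}
            for s, (x, y) in positions.items()
        ]
    )


def test_single_ventral_electrode_populates_only_first_shell():
    pm = _pct_map({"e1": 10.0})
    geom = FlatMapGeometry(np.array([[0.0, -5.0], [0.0, -25.0], [0.0, 15.0]]))
    prof = distance_shell_profile(
        pm, _electrodes({"e1": (0.0, -5.0)}), geom, n_resamples=1000, seed=0
    )
    cov = prof[prof["covered"]]
    assert set(cov["shell"]) == {"Ventral_0-10mm"}
    assert cov["value"].unique().tolist() == [10.0]


def test_two_electrodes_disjoint_shells_middle_missing():
    pm = _pct_map({"e1": 10.0, "e2": 30.0})
    geom = FlatMapGeometry(np.array([[0.0, -5.0], [0.0, -15.0], [0.0, -25.0]]))
    prof = distance_shell_profile(
        pm, _electrodes({"e1": (0.0, -4.0), "e2": (0.0, -26.0)}), geom,
        n_resamples=1000, seed=0,
    )
    by_shell = prof.groupby("shell").first()
    assert by_shell.loc["Ventral_0-10mm", "value"] == pytest.approx(10.0)
    assert by_shell.loc["Ventral_20-30mm", "value"] == pytest.approx(30.0)
    assert not by_shell.loc["Ventral_10-20mm", "covered"]
    assert np.isnan(by_shell.loc["Ventral_10-20mm", "value"])


def test_mesh_point_between_two_electrodes_takes_their_mean():
    pm = _pct_map({"e1": 10.0, "e2": 30.0})
    geom = FlatMapGeometry(np.array([[0.0, -10.0]]))
    prof = distance_shell_profile(
        pm, _electrodes({"e1": (-8.0, -10.0), "e2": (8.0, -10.0)}), geom,
        n_resamples=1000, seed=0,
    )
    assert prof["value"].unique().tolist() == [pytest.approx(20.0)]


def test_no_flat_coordinates_raises():
    pm = _pct_map({"e1": 10.0})
    elec = _electrodes({"e1": (0.0, -5.0)}).drop(columns=["flat_x_mm", "flat_y_mm"])
    elec["flat_x_mm"] = np.nan
    elec["flat_y_mm"] = np.nan
    with pytest.raises(ValueError):
        distance_shell_profile(pm, elec, FlatMapGeometry.regular())
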