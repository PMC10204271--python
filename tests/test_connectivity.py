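"""Chance model, co-modulation search, streamline filtering, dynamic edges."""

import numpy as np
import pandas as pd
import pytest

from conftest import brute_force_comodulation, epochs_as_set, montage
from dyntract.connectivity import (
    BoxMask,
    ChanceModel,
    StreamlineSet,
    build_dynamic_edges,
    chance_probability,
    classify_streamline,
    filter_streamlines,
    find_comodulation,
    pair_adjacency,
)
from dyntract.synth import default_roi_centroids, synthesize_streamlines


# ---------------------------------------------------------------------------
# chance model

def test_chance_limits():
    assert chance_probability(ChanceModel(52, 89, 8, 0.0)) == 0.0
    assert chance_probability(ChanceModel(52, 89, 8, 1.0)) == pytest.approx(
        26 * 51 * 82
    )


def test_chance_monotonicity():
    base = chance_probability(ChanceModel(52, 89, 8, 0.25))
    assert chance_probability(ChanceModel(52, 89, 8, 0.30)) > base
    assert chance_probability(ChanceModel(60, 89, 8, 0.25)) > base
    assert chance_probability(ChanceModel(52, 120, 8, 0.25)) > base
    assert chance_probability(ChanceModel(52, 89, 10, 0.25)) < base


def test_chance_invalid_inputs_raise():
    with pytest.raises(ValueError):
        ChanceModel(52, 89, 8, 1.5)
    with pytest.raises(ValueError):
        ChanceModel(1, 89, 8, 0.5)
    with pytest.raises(ValueError):
        ChanceModel(52, 5, 8, 0.5)


# ---------------------------------------------------------------------------
# co-modulation

CENTERS = -200.0 + 25.0 * np.arange(89)


def _mask(idx):
    m = np.zeros(89, dtype=bool)
    m[idx] = True
    return m


def test_disjoint_significance_gives_no_epochs():
    aug = {"A": _mask(slice(0, 20)), "B": _mask(slice(30, 50))}
    att = {"A": np.zeros(89, bool), "B": np.zeros(89, bool)}
    assert find_comodulation(aug, att, CENTERS, "alpha") == []


def test_exact_eight_bin_overlap_is_one_epoch():
    aug = {"A": _mask(slice(0, 18)), "B": _mask(slice(10, 40))}
    att = {"A": np.zeros(89, bool), "B": np.zeros(89, bool)}
    eps = find_comodulation(aug, att, CENTERS, "alpha")
    assert len(eps) == 1
    e = eps[0]
    assert (e.start_ms, e.end_ms, e.n_bins) == (CENTERS[10], CENTERS[17], 8)
    assert e.polarity == "co-augmentation"


def test_seven_bin_overlap_is_rejected():
    aug = {"A": _mask(slice(0, 17)), "B": _mask(slice(10, 40))}
    att = {"A": np.zeros(89, bool), "B": np.zeros(89, bool)}
    assert find_comodulation(aug, att, CENTERS, "alpha") == []


def test_matches_brute_force_on_random_masks():
    """20 regions x 89 bins, seeded: identical to the explicit triple loop."""
    rng = np.random.default_rng(99)
    rois = [f"r{i}" for i in range(20)]
    aug = {r: rng.random(89) < 0.3 for r in rois}
    att = {r: rng.random(89) < 0.2 for r in rois}
    fast = find_comodulation(aug, att, CENTERS, "alpha")
    slow = brute_force_comodulation(aug, att, CENTERS, "alpha")
    assert epochs_as_set(fast) == epochs_as_set(slow)


# ---------------------------------------------------------------------------
# streamline filtering

def _straight(p0, p1, n=11):
    u = np.linspace(0, 1, n)[:, None]
    return np.asarray(p0) + u * (np.asarray(p1) - np.asarray(p0))


def _sset(streamlines, qa=None, **kw):
    if qa is None:
        qa = [np.full(len(s), 0.10) for s in streamlines]
    return StreamlineSet([np.asarray(s, float) for s in streamlines], qa, **kw)


def test_straight_100mm_good_qa_is_kept():
    kept, verdicts = filter_streamlines(_sset([_straight((0, 0, 0), (100, 0, 0))]))
    assert len(kept) == 1 and verdicts["kept"].all()


def test_80_degree_bend_rejected_as_turning_angle():
    a = np.radians(80)
    bend = np.array([[0, 0, 0], [30, 0, 0], [30 + 30 * np.cos(a), 30 * np.sin(a), 0]])
    _, verdicts = filter_streamlines(_sset([bend]))
    assert verdicts.loc[0, "reason"] == "turning angle"


def test_70_degree_bend_is_allowed():
    a = np.radians(69.9)
    bend = np.array([[0, 0, 0], [30, 0, 0], [30 + 30 * np.cos(a), 30 * np.sin(a), 0]])
    _, verdicts = filter_streamlines(_sset([bend]))
    assert verdicts.loc[0, "kept"]


@pytest.mark.parametrize("p1,reason", [((5, 0, 0), "length"), ((300, 0, 0), "length")])
def test_length_outside_10_to_250mm_rejected(p1, reason):
    _, verdicts = filter_streamlines(_sset([_straight((0, 0, 0), p1)]))
    assert verdicts.loc[0, "reason"] == reason


def test_low_qa_vertex_rejected():
    s = _straight((0, 0, 0), (100, 0, 0))
    qa = np.full(len(s), 0.10)
    qa[5] = 0.02
    _, verdicts = filter_streamlines(_sset([s], qa=[qa]))
    assert verdicts.loc[0, "reason"] == "qa"


def test_mask_violations_rejected():
    s = _straight((-50, 0, 0), (50, 0, 0))
    inside = filter_streamlines(
        _sset([s], exclusion_masks=[BoxMask("thalamus", (-10, -10, -10), (10, 10, 10))])
    )[1]
    assert inside.loc[0, "reason"] == "inside thalamus"
    outside = filter_streamlines(
        _sset([s], parenchyma=BoxMask("parenchyma", (-20, -20, -20), (20, 20, 20)))
    )[1]
    assert outside.loc[0, "reason"] == "outside parenchyma"


def test_degenerate_segment_rejected_with_reason():
    s = np.array([[0.0, 0, 0], [0.0, 0, 0], [50.0, 0, 0]])
    _, verdicts = filter_streamlines(_sset([s]))
    assert verdicts.loc[0, "reason"] == "degenerate"


def test_filter_is_idempotent_on_generator_fixture():
    sset, _ = synthesize_streamlines(default_roi_centroids(), seed=4)
    once, v1 = filter_streamlines(sset)
    twice, v2 = filter_streamlines(once)
    assert len(twice) == len(once)
    assert v2["kept"].all()
    for a, b in zip(once.streamlines, twice.streamlines):
        np.testing.assert_array_equal(a, b)


def test_filter_matches_generator_labels():
    sset, labels = synthesize_streamlines(default_roi_centroids(), seed=4)
    _, verdicts = filter_streamlines(sset)
    assert verdicts["kept"].tolist() == labels["valid"].tolist()
    bad = labels[~labels["valid"]]
    assert verdicts.loc[bad.index, "reason"].tolist() == bad["reason"].tolist()


# ---------------------------------------------------------------------------
# adjacency + edges

CENTROIDS = {"A": np.array([0.0, 0, 0]), "B": np.array([80.0, 0, 0]),
             "C": np.array([0.0, 80, 0])}


def test_single_streamline_connects_its_pair():
    sset = _sset([_straight(CENTROIDS["A"], CENTROIDS["B"])])
    assert pair_adjacency(sset, CENTROIDS) == {("A", "B"): 1}


def test_within_roi_streamline_gives_no_pair():
    sset = _sset([_straight(CENTROIDS["A"], CENTROIDS["A"] + (2.0, 0, 0), n=5)])
    assert pair_adjacency(sset, CENTROIDS) == {}


def test_unassignable_endpoint_is_ignored():
    sset = _sset([_straight((40.0, 40, 0), CENTROIDS["B"])])
    assert pair_adjacency(sset, CENTROIDS) == {}


def test_adjacency_matches_generator_labels():
    centroids = default_roi_centroids()
    sset, labels = synthesize_streamlines(centroids, seed=4)
    legit, _ = filter_streamlines(sset)
    adj = pair_adjacency(legit, centroids)
    expected = {
        tuple(sorted(c.split("-"))) for c in labels.loc[labels["valid"], "connects"]
    }
    assert set(adj) == expected
    assert all(n == 1 for n in adj.values())


def test_adjacency_needs_two_rois():
    with pytest.raises(ValueError):
        pair_adjacency(_sset([_straight((0, 0, 0), (50, 0, 0))]), {"A": np.zeros(3)})


def _epoch(a, b, polarity="co-augmentation", start=0.0, end=175.0):
    from dyntract.connectivity import ComodulationEpoch

    return ComodulationEpoch(a, b, "alpha", polarity, start, end, 8)


def test_comodulating_pair_without_streamline_gives_no_edge():
    edges, dropped = build_dynamic_edges([_epoch("A", "C")], {("A", "B"): 1})
    assert edges.empty and dropped == 1


def test_adjacent_comodulating_pair_gives_strengthened_edge():
    edges, dropped = build_dynamic_edges([_epoch("A", "B")], {("A", "B"): 2})
    assert dropped == 0 and len(edges) == 1
    row = edges.iloc[0]
    assert row["polarity"] == "strengthened" and row["n_streamlines"] == 2


def test_mixed_fixture_row_count_matches_hand_count():
    epochs = [
        _epoch("A", "B"),
        _epoch("A", "B", polarity="co-attenuation", start=500.0, end=700.0),
        _epoch("A", "C"),  # no streamline -> dropped
    ]
    edges, dropped = build_dynamic_edges(epochs, {("A", "B"): 1, ("B", "C"): 1})
    assert len(edges) == 2 and dropped == 1
    assert set(edges["polarity"]) == {"strengthened", "weakened"}
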