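"""Kabsch superposition, structurally weighted RMSD, and leader clustering."""

import numpy as np
import pytest

from conftest import make_ca_ensemble
from idpkit.secstruct import SecStructAssignment
from idpkit.swrmsd import (
    cluster_ensemble,
    kabsch_superpose,
    rmsd_timeseries,
    structure_score,
    swrmsd,
)


def _random_rotation(rng):
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q


def test_superposing_a_rotated_copy_gives_zero_rmsd():
    rng = np.random.default_rng(2)
    x = rng.normal(size=(12, 3))
    r = _random_rotation(rng)
    y = x @ r.T + np.array([3.0, -1.0, 2.0])
    res = kabsch_superpose(x, y)
    assert res.rmsd == pytest.approx(0.0, abs=1e-9)
    np.testing.assert_allclose(res.apply(x), y, atol=1e-9)
    np.testing.assert_allclose(res.rotation, r, atol=1e-9)


def test_rotation_is_proper_even_for_mirror_images():
    rng = np.random.default_rng(9)
    x = rng.normal(size=(8, 3))
    y = x.copy()
    y[:, 0] *= -1  # reflection: not reachable by rotation
    res = kabsch_superpose(x, y)
    assert np.linalg.det(res.rotation) == pytest.approx(1.0, abs=1e-9)
    assert res.rmsd > 0.1


def test_rmsd_agrees_with_explicit_superposed_deviation():
    rng = np.random.default_rng(4)
    x = rng.normal(size=(15, 3))
    y = x + rng.normal(scale=0.3, size=(15, 3))
    res = kabsch_superpose(x, y)
    explicit = np.sqrt(np.mean(np.sum((res.apply(x) - y) ** 2, axis=1)))
    assert res.rmsd == pytest.approx(explicit, rel=1e-9)


def test_structure_score_table_is_exhaustive():
    # 0 for identical states, 1 for coil vs folded, 4 for helix vs extended
    expected = {
        ("C", "C"): 0, ("H", "H"): 0, ("E", "E"): 0,
        ("C", "H"): 1, ("H", "C"): 1, ("C", "E"): 1, ("E", "C"): 1,
        ("H", "E"): 4, ("E", "H"): 4,
    }
    for (a, b), score in expected.items():
        assert structure_score(a, b) == score


def test_structure_score_sums_over_residues():
    # per-residue: C/C=0, C/H=1, H/H=0, H/E=4
    assert structure_score("CCHH", "CHHE") == 5


def test_swrmsd_is_rmsd_times_mismatch_score():
    rng = np.random.default_rng(6)
    x = rng.normal(size=(4, 3))
    y = x + rng.normal(scale=0.5, size=(4, 3))
    rmsd = kabsch_superpose(x, y).rmsd
    assert swrmsd(x, y, "CCHH", "CHHE") == pytest.approx(5 * rmsd, rel=1e-9)
    # identical states: the weight is 0, so the distance is exactly 0
    assert swrmsd(x, y, "CCHH", "CCHH") == 0.0


def test_clustering_identical_frames_yields_one_cluster():
    coords = np.tile(np.random.default_rng(0).normal(size=(6, 3)), (10, 1, 1))
    e = make_ca_ensemble(coords)
    ss = SecStructAssignment(np.full((10, 6), "C"))
    res = cluster_ensemble(e, ss, threshold=1.0)
    assert res.n_clusters == 1
    assert res.occupancies[0] == 1.0


def test_clustering_separates_two_distinct_states():
    rng = np.random.default_rng(8)
    a = rng.normal(size=(6, 3))
    b = a * 3.0 + 5.0  # different shape, cannot superpose onto a
    frames = np.array([a, b, a, a, b])
    e = make_ca_ensemble(frames)
    ss = SecStructAssignment(np.array(
        [list("HHHHHH"), list("EEEEEE"), list("HHHHHH"),
         list("HHHHHH"), list("EEEEEE")]))
    res = cluster_ensemble(e, ss, threshold=0.5)
    assert res.n_clusters == 2
    # leader rule: the first frame founds cluster 0
    np.testing.assert_array_equal(res.labels, [0, 1, 0, 0, 1])
    np.testing.assert_allclose(res.occupancies, [0.6, 0.4])
    assert res.representatives[0] in (0, 2, 3)
    assert res.representatives[1] in (1, 4)
    np.testing.assert_array_equal(res.sorted_by_occupancy(), [0, 1])


def test_same_structure_frames_are_zero_distance_by_design():
    # the weighting is deliberately not a metric: frames with identical
    # secondary structure have SWRMSD 0 regardless of geometry
    rng = np.random.default_rng(3)
    a = rng.normal(size=(6, 3))
    b = a * 2.5
    assert swrmsd(a, b, "CCCCCC", "CCCCCC") == 0.0
    assert swrmsd(a, b, "CCCCCC", "HHHHHH") > 0.0


def test_frames_join_the_earliest_founded_cluster():
    rng = np.random.default_rng(3)
    a = rng.normal(size=(6, 3))
    b = a * 2.5  # geometrically distinct from a
    frames = np.stack([a, b, b])
    e = make_ca_ensemble(frames)
    ss = SecStructAssignment(np.array(
        [list("CCCCCC"), list("HHHHHH"), list("CCCCCC")]))
    # frame 1 founds a second cluster (distance 6 * rmsd(a, b) to frame 0);
    # frame 2 is at distance 0 from BOTH leaders (same structure as frame 0,
    # same geometry as frame 1) and must join the earliest-founded cluster
    d01 = swrmsd(a, b, "CCCCCC", "HHHHHH")
    res = cluster_ensemble(e, ss, threshold=0.5 * d01)
    np.testing.assert_array_equal(res.labels, [0, 1, 0])


def test_rmsd_timeseries_matches_pairwise_kabsch():
    rng = np.random.default_rng(5)
    coords = rng.normal(size=(7, 9, 3))
    e = make_ca_ensemble(coords)
    series = rmsd_timeseries(e, reference_index=2)
    expected = [kabsch_superpose(coords[f], coords[2]).rmsd for f in range(7)]
    np.testing.assert_allclose(series, expected, atol=1e-6)
    assert series[2] == pytest.approx(0.0, abs=1e-6)
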