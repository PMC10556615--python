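"""Contact-fraction maps, strength profiles, and NMR comparison."""

import numpy as np
import pandas as pd
import pytest

from idpkit import synth
from idpkit.contacts import (
    contact_fraction_map,
    mask_weak,
    profile_vs_nmr,
    residue_strengths,
    weighted_profile,
)


def _two_chain_toy(n_frames=20, seed=0):
    rng = np.random.default_rng(seed)
    e, realized = synth.complex_interface(
        n_res_a=6, n_res_b=4,
        schedule={(2, 1): 0.8, (5, 3): 0.4, (2, 4): 1.0},
        n_frames=n_frames, seed=seed,
    )
    return e, realized


def test_contact_map_matches_planted_bookkeeping():
    e, realized = _two_chain_toy(n_frames=50, seed=1)
    cmap = contact_fraction_map(e, "A", "B", cutoff=12.0)
    np.testing.assert_allclose(cmap.pair_fractions, realized, atol=1e-12)


def test_contact_map_matches_double_loop_brute_force():
    e, _ = _two_chain_toy(n_frames=25, seed=2)
    cmap = contact_fraction_map(e, "A", "B", cutoff=12.0)
    ca = e.atom_coords("CA", chain="A")
    cb = e.atom_coords("CA", chain="B")
    brute = np.zeros((ca.shape[1], cb.shape[1]))
    for f in range(e.n_frames):
        for i in range(ca.shape[1]):
            for j in range(cb.shape[1]):
                d = np.linalg.norm(ca[f, i] - cb[f, j])
                brute[i, j] += d < 12.0
    brute /= e.n_frames
    np.testing.assert_allclose(cmap.pair_fractions, brute, atol=1e-12)


def test_heavy_atom_representation_agrees_on_single_atom_residues():
    e, _ = _two_chain_toy(n_frames=10, seed=3)
    ca_map = contact_fraction_map(e, "A", "B", cutoff=12.0, representation="CA")
    heavy = contact_fraction_map(e, "A", "B", cutoff=12.0, representation="heavy")
    np.testing.assert_allclose(ca_map.pair_fractions, heavy.pair_fractions)


def test_contact_map_validation():
    e, _ = _two_chain_toy(n_frames=2)
    with pytest.raises(ValueError):
        contact_fraction_map(e, "A", "B", cutoff=-1.0)
    with pytest.raises(ValueError):
        contact_fraction_map(e, "A", "B", representation="nonsense")


def test_transpose_swaps_axes():
    e, _ = _two_chain_toy(n_frames=5)
    cmap = contact_fraction_map(e, "A", "B")
    t = cmap.transpose()
    np.testing.assert_array_equal(t.pair_fractions, cmap.pair_fractions.T)
    np.testing.assert_array_equal(t.residues_a, cmap.residues_b)


def test_residue_strengths_max_and_sum_modes():
    e, realized = _two_chain_toy(n_frames=40, seed=4)
    cmap = contact_fraction_map(e, "A", "B")
    np.testing.assert_allclose(residue_strengths(cmap), realized.max(axis=1))
    np.testing.assert_allclose(residue_strengths(cmap, mode="sum"),
                               realized.sum(axis=1))
    np.testing.assert_allclose(residue_strengths(cmap, axis="b"),
                               realized.max(axis=0))
    with pytest.raises(ValueError):
        residue_strengths(cmap, mode="median")


def test_weighted_profile_normalisation_and_zero_case():
    p1 = np.array([0.2, 0.8, 0.0])
    p2 = np.array([0.0, 0.4, 0.4])
    prof = weighted_profile([p1, p2], [0.75, 0.25])
    mean = 0.75 * p1 + 0.25 * p2
    np.testing.assert_allclose(prof.strengths, mean / mean.max())
    assert prof.strengths.max() == pytest.approx(1.0)
    zero = weighted_profile([np.zeros(3)], [1.0])
    np.testing.assert_array_equal(zero.strengths, 0.0)
    with pytest.raises(ValueError):
        weighted_profile([p1, p2], [1.0])
    with pytest.raises(ValueError):
        weighted_profile([p1, np.zeros(4)], [0.5, 0.5])


def test_mask_weak_leaves_underlying_profile_untouched():
    prof = weighted_profile([np.array([0.01, 0.5, 1.0])], [1.0])
    masked = mask_weak(prof, threshold=0.05)
    assert np.isnan(masked[0]) and masked[2] == 1.0
    assert prof.strengths[0] > 0  # original untouched


def test_profile_vs_nmr_recovers_perfect_rank_agreement():
    prof = weighted_profile([np.array([0.1, 0.3, 0.5, 0.7, 0.9, 1.0])], [1.0])
    # stronger simulated contact = larger intensity loss (more negative)
    changes = pd.Series([-5.0, -20.0, -40.0, -60.0, -80.0, -100.0],
                        index=prof.residues)
    out = profile_vs_nmr(prof, changes)
    assert out["spearman_rho"] == pytest.approx(1.0)
    assert out["n_residues"] == 6


def test_profile_vs_nmr_excludes_missing_residues_pairwise():
    prof = weighted_profile([np.linspace(0.1, 1.0, 8)], [1.0])
    changes = pd.Series([-10.0, np.nan, -30.0, -40.0, -50.0, -60.0, -70.0],
                        index=np.arange(1, 8))  # residue 8 absent, 2 is NaN
    out = profile_vs_nmr(prof, changes)
    assert out["n_residues"] == 6
    with pytest.raises(ValueError, match="overlap"):
        profile_vs_nmr(prof, changes.iloc[:4])
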