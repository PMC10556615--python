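"""Synthetic generators: determinism, invariants, and planted ground truth."""

import numpy as np
import pytest

from idpkit import synth
from idpkit.polymer import end_to_end
from idpkit.synth import (
    build_backbone,
    complex_interface,
    ideal_chain,
    planted_nmr_tables,
    saw_pivot,
    two_conformer_ensemble,
)


def test_generators_are_seed_deterministic():
    for gen in (
        lambda s: ideal_chain(50, 1.0, 5, seed=s).coords,
        lambda s: saw_pivot(20, 5, seed=s).coords,
        lambda s: two_conformer_ensemble(n_res=20, n_frames=10, seed=s)[0].coords,
    ):
        np.testing.assert_array_equal(gen(123), gen(123))
        assert not np.array_equal(gen(123), gen(124))


def test_ideal_chain_bond_lengths_are_exact():
    e = ideal_chain(2, bond_length=1.7, n_samples=1, seed=0)
    steps = np.diff(e.coords[0], axis=0)
    np.testing.assert_allclose(np.linalg.norm(steps, axis=1), 1.7, rtol=1e-12)


def test_ideal_chain_mean_square_end_to_end_matches_closed_form():
    n, samples = 200, 3000
    e = ideal_chain(n, 1.0, samples, seed=7)
    ree2 = end_to_end(e.coords) ** 2
    se = ree2.std(ddof=1) / np.sqrt(samples)
    assert abs(ree2.mean() - n) < 3 * se


def test_ideal_chain_input_validation():
    with pytest.raises(ValueError):
        ideal_chain(1, 1.0, 5)
    with pytest.raises(ValueError):
        ideal_chain(10, 1.0, 0)


def test_saw_walks_never_revisit_a_lattice_site():
    e = saw_pivot(30, n_samples=40, seed=5)
    for frame in e.coords:
        sites = {tuple(np.rint(p).astype(int)) for p in frame}
        assert len(sites) == frame.shape[0]


def test_saw_steps_stay_on_the_lattice():
    e = saw_pivot(25, n_samples=10, seed=6)
    steps = np.diff(e.coords, axis=1)
    np.testing.assert_allclose(np.abs(steps).sum(axis=2), 1.0, atol=1e-9)


def test_saw_input_validation():
    with pytest.raises(ValueError):
        saw_pivot(5, 10)
    with pytest.raises(ValueError):
        saw_pivot(20, 0)


def test_two_conformer_label_counts_match_planted_occupancies():
    occ = (0.5, 0.4, 0.1)
    n = 2000
    _, labels = two_conformer_ensemble(n_res=20, occupancies=occ,
                                       n_frames=n, seed=9)
    for k, p in enumerate(occ):
        sd = np.sqrt(n * p * (1 - p))
        assert abs(np.sum(labels == k) - n * p) < 3 * sd


def test_two_conformer_zero_noise_repeats_templates_exactly():
    e, labels = two_conformer_ensemble(n_res=20, occupancies=(0.5, 0.5, 0.0),
                                       noise_rms=0.0, n_frames=30, seed=10)
    for k in (0, 1):
        frames = e.coords[labels == k]
        assert len(frames) > 1
        np.testing.assert_array_equal(frames, np.broadcast_to(
            frames[0], frames.shape))


def test_two_conformer_validation():
    with pytest.raises(ValueError):
        two_conformer_ensemble(n_res=10)
    with pytest.raises(ValueError):
        two_conformer_ensemble(occupancies=(0.5, 0.4, 0.4))


def test_interface_schedule_edge_cases():
    e, realized = complex_interface(4, 3, {}, n_frames=5, seed=0)
    np.testing.assert_array_equal(realized, 0.0)
    e2, realized2 = complex_interface(4, 3, {(2, 1): 1.0}, n_frames=5, seed=0)
    assert realized2[1, 0] == 1.0


def test_interface_infeasible_schedules_name_the_pair():
    with pytest.raises(ValueError, match=r"\(2, 1\)"):
        complex_interface(4, 3, {(1, 1): 0.5, (2, 1): 0.5}, n_frames=2)
    with pytest.raises(ValueError, match="more than two"):
        complex_interface(4, 4, {(1, 1): 0.5, (1, 2): 0.5, (1, 3): 0.5},
                          n_frames=2)
    with pytest.raises(ValueError):
        complex_interface(4, 3, {(9, 1): 0.5}, n_frames=2)
    with pytest.raises(ValueError):
        complex_interface(4, 3, {(1, 1): 1.5}, n_frames=2)


def test_backbone_bond_lengths_and_dihedrals_are_honoured():
    pp = np.array([[-60.0, -45.0]] * 8)
    e = build_backbone(pp)
    c = e.coords[0]
    # atoms come in N, CA, C, O quadruples
    n_xyz = c[0::4]
    ca_xyz = c[1::4]
    c_xyz = c[2::4]
    np.testing.assert_allclose(np.linalg.norm(ca_xyz - n_xyz, axis=1),
                               1.46, atol=1e-9)
    np.testing.assert_allclose(np.linalg.norm(c_xyz - ca_xyz, axis=1),
                               1.52, atol=1e-9)
    for i in range(1, 7):
        phi = synth._dihedral(c_xyz[i - 1], n_xyz[i], ca_xyz[i], c_xyz[i])
        psi = synth._dihedral(n_xyz[i], ca_xyz[i], c_xyz[i], n_xyz[i + 1])
        assert phi == pytest.approx(-60.0, abs=1e-6)
        assert psi == pytest.approx(-45.0, abs=1e-6)


def test_backbone_validation():
    with pytest.raises(ValueError):
        build_backbone(np.zeros((2, 2)))
    with pytest.raises(ValueError):
        build_backbone(np.zeros((5, 2)), sequence="AAA")


def test_planted_nmr_ratio_validation():
    with pytest.raises(ValueError):
        planted_nmr_tables(0.0, 5)
    with pytest.raises(ValueError):
        planted_nmr_tables(100.0, 5)
    with pytest.raises(ValueError):
        planted_nmr_tables(50.0, 5, pattern=np.zeros(3))
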