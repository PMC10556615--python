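"""Shared fixtures: small synthetic ensembles built from the generators."""

import numpy as np
import pytest

from idpkit import synth
from idpkit.ensemble import Ensemble, Topology


@pytest.fixture(scope="session")
def helix_backbone() -> Ensemble:
    """30-residue backbone with two helical segments (single frame)."""
    return synth.build_backbone(synth.helix_rich_phi_psi(30))


@pytest.fixture(scope="session")
def hairpin_backbone() -> Ensemble:
    """30-residue antiparallel beta-hairpin backbone (single frame)."""
    return synth.build_backbone(synth.hairpin_phi_psi(30))


@pytest.fixture(scope="session")
def small_mixture():
    """Small two-conformer mixture with its planted labels."""
    return synth.two_conformer_ensemble(
        n_res=24, occupancies=(0.5, 0.4, 0.1), noise_rms=0.5,
        n_frames=120, seed=11,
    )


def make_ca_ensemble(coords: np.ndarray, chain: str = "A") -> Ensemble:
    """Wrap (F, N, 3) or (N, 3) coordinates as a CA-only glycine chain."""
    coords = np.asarray(coords, dtype=float)
    if coords.ndim == 2:
        coords = coords[None]
    n = coords.shape[1]
    top = Topology(
        chain_ids=np.full(n, chain),
        res_numbers=np.arange(1, n + 1),
        res_names=np.full(n, "GLY"),
        res_codes=np.full(n, "G"),
        atom_res_index=np.arange(n),
        atom_names=np.full(n, "CA"),
        elements=np.full(n, "C"),
    )
    return Ensemble(top, coords)
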