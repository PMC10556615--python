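"""Inter-chain contact analysis for bound-complex ensembles.

A residue pair (one residue from each chain) is "in contact" in a frame when
its representative distance is below a cutoff (default 12 Angstrom, a
coarse-grained interface criterion); the contact fraction is the share of
frames in contact.  Per-residue marginal strengths condense the map to a
binding-interface profile, which — after occupancy weighting over
conformational clusters and max-normalisation — can be compared directly
against NMR titration intensity-loss profiles via a rank correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .ensemble import Ensemble

__all__ = [
    "ContactMap",
    "ResidueStrengthProfile",
    "contact_fraction_map",
    "residue_strengths",
    "weighted_profile",
    "mask_weak",
    "profile_vs_nmr",
]

DEFAULT_CUTOFF = 12.0  # Angstrom


@dataclass
class ContactMap:
    """Residue-pair contact fractions between two chains."""

    pair_fractions: np.ndarray  # (Ra, Rb) fractions in [0, 1]
    residues_a: np.ndarray      # residue numbers of chain A rows
    residues_b: np.ndarray      # residue numbers of chain B columns
    cutoff: float               # Angstrom
    representation: str         # atom set used for distances

    def __post_init__(self):
        if np.any(self.pair_fractions < 0) or np.any(self.pair_fractions > 1):
            raise ValueError("contact fractions must lie in [0, 1]")

    def transpose(self) -> "ContactMap":
        return ContactMap(self.pair_fractions.T, self.residues_b,
                          self.residues_a, self.cutoff, self.representation)


@dataclass
class ResidueStrengthProfile:
    """Per-residue contact strengths normalised to the strongest residue."""

    strengths: np.ndarray   # in [0, 1]; max is 1 when any contact exists
    residues: np.ndarray    # residue numbers
    weighting: str          # description of how clusters were combined

    def __post_init__(self):
        if np.any(self.strengths < 0) or np.any(self.strengths > 1 + 1e-12):
            raise ValueError("strengths must lie in [0, 1]")


def contact_fraction_map(ensemble: Ensemble, chain_a: str, chain_b: str,
                         cutoff: float = DEFAULT_CUTOFF,
                         representation: str = "CA") -> ContactMap:
    """Contact fractions at ``cutoff`` between all residue pairs of two chains.

    ``representation`` is "CA" (alpha-carbon distances, the default matching
    a coarse-grained 12 A criterion) or "heavy" (minimum distance over all
    non-hydrogen atoms of each residue).
    """
    if not cutoff > 0:
        raise ValueError("cutoff must be positive")
    top = ensemble.topology
    res_a = top.residue_indices(chain=chain_a)
    res_b = top.residue_indices(chain=chain_b)
    if representation == "CA":
        ca = ensemble.atom_coords("CA", chain=chain_a)   # (F, Ra, 3)
        cb = ensemble.atom_coords("CA", chain=chain_b)   # (F, Rb, 3)
        d = np.linalg.norm(ca[:, :, None, :] - cb[:, None, :, :], axis=3)
        frac = (d < cutoff).mean(axis=0)
    elif representation == "heavy":
        frac = _heavy_atom_fractions(ensemble, res_a, res_b, cutoff)
    else:
        raise ValueError(f"unknown representation {representation!r}")
    return ContactMap(
        pair_fractions=frac,
        residues_a=top.res_numbers[res_a],
        residues_b=top.res_numbers[res_b],
        cutoff=float(cutoff),
        representation=representation,
    )


def _heavy_atom_fractions(ensemble, res_a, res_b, cutoff):
    top = ensemble.topology
    heavy = top.elements != "H"
    groups_a = [np.flatnonzero((top.atom_res_index == r) & heavy) for r in res_a]
    groups_b = [np.flatnonzero((top.atom_res_index == r) & heavy) for r in res_b]
    frac = np.zeros((len(res_a), len(res_b)))
    for f in range(ensemble.n_frames):
        xyz = ensemble.coords[f]
        for i, ga in enumerate(groups_a):
            for j, gb in enumerate(groups_b):
                d = np.linalg.norm(xyz[ga][:, None] - xyz[gb][None], axis=2)
                frac[i, j] += d.min() < cutoff
    return frac / ensemble.n_frames


def residue_strengths(cmap: ContactMap, axis: str = "a",
                      mode: str = "max") -> np.ndarray:
    """Raw per-residue contact strength along one chain of a contact map.

    The default is the maximum contact fraction over partner residues (a
    bounded scalar per residue, so a single strongest residue sets the
    normalisation); ``mode="sum"`` accumulates over partners instead, for
    sensitivity analysis.
    """
    m = cmap.pair_fractions if axis == "a" else cmap.pair_fractions.T
    if axis not in ("a", "b"):
        raise ValueError("axis must be 'a' or 'b'")
    if mode == "max":
        return m.max(axis=1)
    if mode == "sum":
        return m.sum(axis=1)
    raise ValueError(f"unknown mode {mode!r}")


def weighted_profile(profiles, occupancies, residues=None) -> ResidueStrengthProfile:
    """Occupancy-weighted average of cluster strength profiles, max-normalised.

    ``occupancies`` are renormalised to sum to one over the supplied
    clusters, so only their ratios matter.  An all-zero input stays all
    zero rather than dividing by zero.
    """
    profiles = [np.asarray(p, dtype=float) for p in profiles]
    occ = np.asarray(occupancies, dtype=float)
    if len(profiles) != len(occ):
        raise ValueError("one occupancy per profile required")
    if np.any(occ <= 0):
        raise ValueError("occupancies must be positive")
    lengths = {len(p) for p in profiles}
    if len(lengths) != 1:
        raise ValueError("profiles cover different residue ranges")
    occ = occ / occ.sum()
    mean = sum(w * p for w, p in zip(occ, profiles))
    peak = mean.max()
    if peak > 0:
        mean = mean / peak
    if residues is None:
        residues = np.arange(1, len(mean) + 1)
    return ResidueStrengthProfile(
        strengths=mean,
        residues=np.asarray(residues),
        weighting=f"occupancy-weighted over {len(profiles)} clusters, max-normalised",
    )


def mask_weak(profile: ResidueStrengthProfile, threshold: float = 0.05) -> np.ndarray:
    """Strengths with values below ``threshold`` replaced by NaN.

    This is a reporting mask for interface regions too weak to follow; the
    underlying strengths are left untouched.
    """
    out = profile.strengths.astype(float).copy()
    out[out < threshold] = np.nan
    return out


def profile_vs_nmr(profile: ResidueStrengthProfile,
                   intensity_changes: pd.Series) -> dict:
    """Rank-correlate simulated contact strengths with NMR intensity losses.

    ``intensity_changes`` is a per-residue series of percentage intensity
    changes on titration (negative = signal loss), indexed by residue
    number.  Residues absent from either side (prolines, overlapped peaks)
    are excluded pairwise.  Returns the Spearman correlation between
    strength and -(change), its p-value, the residue count used and the
    aligned table.
    """
    sim = pd.Series(profile.strengths, index=profile.residues, name="strength")
    obs = pd.Series(intensity_changes, name="intensity_change").dropna()
    table = pd.concat([sim, obs], axis=1, join="inner").dropna()
    if len(table) < 5:
        raise ValueError(f"only {len(table)} overlapping residues; need >= 5")
    rho, pval = stats.spearmanr(table["strength"], -table["intensity_change"])
    return {
        "spearman_rho": float(rho),
        "p_value": float(pval),
        "n_residues": int(len(table)),
        "table": table,
    }
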