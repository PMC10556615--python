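"""Per-residue secondary-structure propensities and disorder summaries.

The propensity of a residue for state X in {H, E, C} is the fraction of
ensemble frames in which it is assigned X.  The summary statistics quantify
how disordered a profile is: the fraction of residues that never commit to a
fold (max folded propensity below a threshold), the fraction that are almost
always coil, the fraction with a strong preference for some fold, and the
run lengths of contiguous high-propensity segments.  A multiplicative
reweighting of global helix/extended/other fractions is provided to correct
for known secondary-structure biases of simulation force fields.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .secstruct import SecStructAssignment

__all__ = [
    "PropensityProfile",
    "compute_propensity",
    "disorder_summary",
    "reweight_fractions",
]


@dataclass
class PropensityProfile:
    """Per-residue fractions of helix, extended and coil over an ensemble."""

    p_h: np.ndarray
    p_e: np.ndarray
    p_c: np.ndarray
    n_frames: int

    def __post_init__(self):
        for p in (self.p_h, self.p_e, self.p_c):
            if np.any(p < 0) or np.any(p > 1):
                raise ValueError("propensities must lie in [0, 1]")
        if not np.allclose(self.p_h + self.p_e + self.p_c, 1.0, atol=1e-9):
            raise ValueError("propensities must sum to 1 per residue")

    @property
    def n_residues(self) -> int:
        return len(self.p_h)


def compute_propensity(assignment: SecStructAssignment) -> PropensityProfile:
    """Fraction of frames each residue spends in H, E and C."""
    states = assignment.states
    if states.shape[0] < 1:
        raise ValueError("empty assignment")
    n = states.shape[0]
    return PropensityProfile(
        p_h=(states == "H").mean(axis=0),
        p_e=(states == "E").mean(axis=0),
        p_c=(states == "C").mean(axis=0),
        n_frames=n,
    )


def disorder_summary(profile: PropensityProfile, fold_threshold: float = 0.2,
                     coil_threshold: float = 0.8,
                     high_threshold: float = 0.8) -> dict:
    """Disorder statistics of a propensity profile.

    Returns a dict with:

    - ``frac_unfolded``: fraction of residues whose largest folded propensity
      (max of p_H, p_E) is below ``fold_threshold`` — residues with no
      specific fold preference;
    - ``frac_coil``: fraction of residues with p_C above ``coil_threshold``;
    - ``frac_high_propensity``: fraction of residues with some folded
      propensity above ``high_threshold``;
    - ``high_run_lengths``: lengths of contiguous runs of such residues,
      the "segment" reading of high-propensity regions.
    """
    for t in (fold_threshold, coil_threshold, high_threshold):
        if not 0 < t < 1:
            raise ValueError("thresholds must lie strictly inside (0, 1)")
    folded = np.maximum(profile.p_h, profile.p_e)
    high = folded > high_threshold
    runs = []
    count = 0
    for flag in high:
        if flag:
            count += 1
        elif count:
            runs.append(count)
            count = 0
    if count:
        runs.append(count)
    return {
        "frac_unfolded": float((folded < fold_threshold).mean()),
        "frac_coil": float((profile.p_c > coil_threshold).mean()),
        "frac_high_propensity": float(high.mean()),
        "high_run_lengths": runs,
    }


def reweight_fractions(fractions, factors):
    """Multiplicatively reweight (helix, extended, other) fractions.

    corrected_X is proportional to factor_X * fraction_X, renormalised to
    sum to one.  Identity factors leave the input unchanged.  The factors
    are configuration — they encode an externally calibrated bias of the
    simulation force field toward or against each state.
    """
    fractions = np.asarray(fractions, dtype=float)
    factors = np.asarray(factors, dtype=float)
    if fractions.shape != factors.shape:
        raise ValueError("fractions and factors must align")
    if not np.isclose(fractions.sum(), 1.0, atol=1e-9):
        raise ValueError("input fractions must sum to 1")
    if np.any(factors <= 0):
        raise ValueError("correction factors must be positive")
    w = factors * fractions
    return w / w.sum()
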