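"""Per-frame, per-residue 3-state secondary structure from backbone geometry.

The assignment follows the Kabsch-Sander scheme: an electrostatic model of
the backbone amide-carbonyl hydrogen bond,

    E = 0.084 * 332 * (1/r_ON + 1/r_CH - 1/r_OH - 1/r_CN)  [kcal/mol],

with a bond called when E < -0.5 kcal/mol; helices from runs of (i, i+n)
turns (n = 3, 4, 5 all reduced to 'H'), strands from parallel/antiparallel
bridge topology (isolated bridges included, reduced to 'E'), and coil ('C')
otherwise.  The three-letter alphabet {H, E, C} is exactly the one the
structurally weighted RMSD score in :mod:`idpkit.swrmsd` is defined on.

Amide hydrogens missing from the input are reconstructed on the peptide
plane, so models stripped of protons (as most simulation snapshots are)
assign identically to files carrying explicit amide protons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ensemble import Ensemble

__all__ = [
    "HBOND_PREFACTOR",
    "HBOND_CUTOFF",
    "SecStructAssignment",
    "AssignmentError",
    "hbond_energy",
    "reconstruct_amide_h",
    "assign",
    "assign_frame",
    "reduce_to_three_state",
]

# 0.084 e^2 partial charges * 332 kcal*A/mol Coulomb constant
HBOND_PREFACTOR = 0.084 * 332.0  # kcal*A/mol = 27.888
HBOND_CUTOFF = -0.5              # kcal/mol; E below this is a hydrogen bond
N_H_BOND_LENGTH = 1.01           # A, reconstructed amide proton

EIGHT_TO_THREE = {
    "H": "H", "G": "H", "I": "H",
    "E": "E", "B": "E",
    "T": "C", "S": "C", "C": "C", "-": "C", " ": "C", "~": "C",
}


class AssignmentError(ValueError):
    """The system cannot be assigned (too small or malformed)."""


@dataclass
class SecStructAssignment:
    """frames x residues matrix of states over the alphabet {H, E, C}."""

    states: np.ndarray  # (F, R) of single characters
    source: str = "kabsch-sander-3state"

    def __post_init__(self):
        self.states = np.asarray(self.states, dtype="U1")
        bad = set(np.unique(self.states)) - {"H", "E", "C"}
        if bad:
            raise AssignmentError(f"states outside alphabet {{H,E,C}}: {bad}")

    @property
    def n_frames(self) -> int:
        return self.states.shape[0]

    @property
    def n_residues(self) -> int:
        return self.states.shape[1]

    def frame_string(self, frame: int) -> str:
        return "".join(self.states[frame])


def reduce_to_three_state(state: str) -> str:
    """Map an 8-state (DSSP-style) letter onto {H, E, C}; total mapping."""
    return EIGHT_TO_THREE.get(state, "C")


def hbond_energy(r_on, r_ch, r_oh, r_cn):
    """Kabsch-Sander hydrogen-bond energy in kcal/mol.

    Parameters are the O..N, C..H, O..H and C..N distances (Angstrom) between
    the acceptor carbonyl (C=O) and donor amide (N-H) groups.  Distances at
    or below 0.5 A are rejected as steric clashes.
    """
    r_on, r_ch, r_oh, r_cn = (np.asarray(r, dtype=float)
                              for r in (r_on, r_ch, r_oh, r_cn))
    for r in (r_on, r_ch, r_oh, r_cn):
        if np.any(r <= 0.5):
            raise ValueError("distance <= 0.5 A: atoms clash or input invalid")
    e = HBOND_PREFACTOR * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn)
    return e if e.shape else float(e)


def reconstruct_amide_h(n: np.ndarray, ca: np.ndarray, c_prev: np.ndarray) -> np.ndarray:
    """Place the amide proton 1.01 A from N on the C(prev)-N-CA plane.

    The proton sits on the external bisector of the C(prev)-N-CA angle,
    i.e. trans to both heavy-atom bonds, which is the planar peptide
    geometry.  Works on single positions or arrays of positions.
    """
    n = np.asarray(n, dtype=float)
    u1 = n - np.asarray(c_prev, dtype=float)
    u2 = n - np.asarray(ca, dtype=float)
    u1 = u1 / np.linalg.norm(u1, axis=-1, keepdims=True)
    u2 = u2 / np.linalg.norm(u2, axis=-1, keepdims=True)
    bis = u1 + u2
    bis = bis / np.linalg.norm(bis, axis=-1, keepdims=True)
    return n + N_H_BOND_LENGTH * bis


def _backbone_arrays(ensemble: Ensemble):
    """Per-residue backbone atom indices (or -1) and chain bookkeeping."""
    top = ensemble.topology
    n_res = top.n_residues
    idx = {name: np.full(n_res, -1, dtype=int) for name in ("N", "CA", "C", "O", "H")}
    for a in range(top.n_atoms):
        name = top.atom_names[a]
        if name in idx and idx[name][top.atom_res_index[a]] == -1:
            idx[name][top.atom_res_index[a]] = a
    complete = (idx["N"] >= 0) & (idx["CA"] >= 0) & (idx["C"] >= 0) & (idx["O"] >= 0)
    # previous residue in the same chain (positional adjacency)
    prev = np.arange(n_res) - 1
    same_chain = np.zeros(n_res, dtype=bool)
    same_chain[1:] = top.chain_ids[1:] == top.chain_ids[:-1]
    prev[~same_chain] = -1
    return idx, complete, prev


def _frame_geometry(coords, idx, complete, prev, res_names):
    """Backbone positions for one frame; H reconstructed where absent."""
    n_res = len(complete)
    pos = {}
    for name in ("N", "CA", "C", "O"):
        p = np.full((n_res, 3), np.nan)
        ok = idx[name] >= 0
        p[ok] = coords[idx[name][ok]]
        pos[name] = p
    h = np.full((n_res, 3), np.nan)
    has_h = idx["H"] >= 0
    h[has_h] = coords[idx["H"][has_h]]
    # donors: need N and CA, a preceding C in the same chain, and not proline
    donor = complete & (prev >= 0) & (res_names != "PRO")
    donor &= complete[np.clip(prev, 0, None)] | (prev < 0)
    need_h = donor & ~has_h
    for i in np.flatnonzero(need_h):
        h[i] = reconstruct_amide_h(pos["N"][i], pos["CA"][i], pos["C"][prev[i]])
    donor &= np.all(np.isfinite(h), axis=1)
    return pos, h, donor


def _hbond_matrix(pos, h, donor, complete):
    """Boolean matrix hb[a, d]: C=O of residue a accepts the N-H of d."""
    n_res = len(donor)
    c, o = pos["C"], pos["O"]
    nn = pos["N"]
    acceptor = complete

    def dist(x, y):
        return np.linalg.norm(x[:, None, :] - y[None, :, :], axis=2)

    with np.errstate(invalid="ignore", divide="ignore"):
        r_on = dist(o, nn)
        r_ch = dist(c, h)
        r_oh = dist(o, h)
        r_cn = dist(c, nn)
        e = HBOND_PREFACTOR * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn)
    hb = e < HBOND_CUTOFF
    hb &= acceptor[:, None] & donor[None, :]
    np.fill_diagonal(hb, False)
    return hb


def _contiguous(prev, i, j):
    """Whether residues i..j are positionally consecutive in one chain."""
    return all(prev[k] == k - 1 for k in range(i + 1, j + 1))


def assign_frame(coords: np.ndarray, topology_arrays) -> np.ndarray:
    """Assign {H, E, C} states for one frame (see module docstring)."""
    idx, complete, prev, res_names = topology_arrays
    n_res = len(complete)
    if n_res < 3:
        raise AssignmentError("secondary structure needs at least 3 residues")
    pos, h, donor = _frame_geometry(coords, idx, complete, prev, res_names)
    hb = _hbond_matrix(pos, h, donor, complete)

    states = np.full(n_res, "C", dtype="U1")

    # strands: parallel / antiparallel bridges between residues >= 3 apart
    in_bridge = np.zeros(n_res, dtype=bool)
    ii, jj = np.meshgrid(np.arange(n_res), np.arange(n_res), indexing="ij")
    sep = np.abs(ii - jj) >= 3

    def hbs(a, b):
        """hb with out-of-range indices treated as no bond."""
        a = np.asarray(a)
        b = np.asarray(b)
        ok = (a >= 0) & (a < n_res) & (b >= 0) & (b < n_res)
        out = np.zeros(a.shape, dtype=bool)
        out[ok] = hb[a[ok], b[ok]]
        return out

    para = (hbs(ii - 1, jj) & hbs(jj, ii + 1)) | (hbs(jj - 1, ii) & hbs(ii, jj + 1))
    anti = (hbs(ii, jj) & hbs(jj, ii)) | (hbs(ii - 1, jj + 1) & hbs(jj - 1, ii + 1))
    bridge = (para | anti) & sep
    in_bridge = bridge.any(axis=1)
    states[in_bridge] = "E"

    # helices: two consecutive (i, i+n) turns mark residues i..i+n-1
    for n_turn in (4, 3, 5):
        turn = np.zeros(n_res, dtype=bool)
        for i in range(n_res - n_turn):
            if hb[i, i + n_turn] and _contiguous(prev, i, i + n_turn):
                turn[i] = True
        for i in range(1, n_res - n_turn):
            if turn[i - 1] and turn[i]:
                states[i:i + n_turn] = "H"

    states[~complete] = "C"
    return states


def assign(ensemble: Ensemble) -> SecStructAssignment:
    """Assign secondary structure for every frame of an ensemble."""
    top = ensemble.topology
    if top.n_residues < 3:
        raise AssignmentError("secondary structure needs at least 3 residues")
    idx, complete, prev = _backbone_arrays(ensemble)
    arrays = (idx, complete, prev, top.res_names)
    states = np.empty((ensemble.n_frames, top.n_residues), dtype="U1")
    for f in range(ensemble.n_frames):
        states[f] = assign_frame(ensemble.coords[f], arrays)
    return SecStructAssignment(states)
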