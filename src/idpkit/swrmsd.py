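"""Kabsch superposition, structurally weighted RMSD, and ensemble clustering.

The structurally weighted RMSD (SWRMSD) between two frames is the optimal
superposition RMSD multiplied by a secondary-structure mismatch score summed
over residues: 0 where the two frames agree, 1 where one frame is coil and
the other folded, and 4 where one is helix and the other extended.  Frames
that differ in coordinates but share the same secondary structure therefore
score zero — SWRMSD is deliberately NOT a metric; it separates frames by
fold topology first and geometry second, which is what makes it effective at
splitting partially structured conformers of a disordered chain that plain
RMSD mixes together.

Clustering uses a deterministic leader scan: a frame joins the first
existing cluster whose leader is within the threshold in SWRMSD, otherwise
it founds a new cluster; medoid representatives minimise the summed SWRMSD
within each cluster.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ensemble import Ensemble
from .secstruct import SecStructAssignment

__all__ = [
    "SuperpositionResult",
    "ClusterResult",
    "kabsch_superpose",
    "structure_score",
    "swrmsd",
    "cluster_ensemble",
    "rmsd_timeseries",
]

# per-residue mismatch scores, indexed by encoded states (C=0, H=1, E=2)
_SCORE_TABLE = np.array([
    [0, 1, 1],   # C vs C, H, E
    [1, 0, 4],   # H vs C, H, E
    [1, 4, 0],   # E vs C, H, E
], dtype=np.int64)
_ENCODE = {"C": 0, "H": 1, "E": 2}


@dataclass
class SuperpositionResult:
    """Optimal rigid-body superposition of one frame onto another."""

    rotation: np.ndarray     # (3, 3) proper rotation (det = +1)
    translation: np.ndarray  # (3,) applied after rotation [A]
    rmsd: float              # minimised RMSD [A]

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


@dataclass
class ClusterResult:
    """Leader/medoid clustering of an ensemble under SWRMSD."""

    labels: np.ndarray          # (F,) cluster index per frame
    occupancies: np.ndarray     # (K,) frame fraction per cluster
    representatives: np.ndarray  # (K,) medoid frame index per cluster
    threshold: float            # SWRMSD threshold used [weighted A]

    def __post_init__(self):
        if not np.isclose(self.occupancies.sum(), 1.0, atol=1e-9):
            raise ValueError("cluster occupancies must sum to 1")

    @property
    def n_clusters(self) -> int:
        return len(self.occupancies)

    def sorted_by_occupancy(self) -> np.ndarray:
        """Cluster indices ordered from most to least occupied."""
        return np.argsort(-self.occupancies, kind="stable")


def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray) -> SuperpositionResult:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Both are (N, 3) with the same N >= 3.  The reflection branch of the SVD
    solution is corrected so the rotation is always proper (det = +1).
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape:
        raise ValueError("atom count mismatch between mobile and reference")
    if mobile.shape[0] < 3 or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("superposition needs >= 3 points of shape (N, 3)")
    mc = mobile.mean(axis=0)
    rc = reference.mean(axis=0)
    a = mobile - mc
    b = reference - rc
    h = a.T @ b
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    resid = (a ** 2).sum() + (b ** 2).sum() - 2.0 * (s[0] + s[1] + d * s[2])
    rmsd = float(np.sqrt(max(resid, 0.0) / mobile.shape[0]))
    return SuperpositionResult(rotation=rot, translation=rc - rot @ mc, rmsd=rmsd)


def _batch_rmsd(mobiles: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Kabsch RMSD of each (N,3) frame in ``mobiles`` (M,N,3) vs one reference."""
    a = mobiles - mobiles.mean(axis=1, keepdims=True)
    b = reference - reference.mean(axis=0)
    h = np.einsum("mni,nj->mij", a, b)
    s = np.linalg.svd(h, compute_uv=False)
    det = np.linalg.det(h)
    # proper-rotation correction flips the sign of the smallest singular value
    sign = np.where(det < 0, -1.0, 1.0)
    trace = s[:, 0] + s[:, 1] + sign * s[:, 2]
    resid = (a ** 2).sum(axis=(1, 2)) + (b ** 2).sum() - 2.0 * trace
    return np.sqrt(np.clip(resid, 0.0, None) / mobiles.shape[1])


def encode_states(states: np.ndarray) -> np.ndarray:
    states = np.asarray(states, dtype="U1")
    out = np.full(states.shape, -1, dtype=np.int64)
    for sym, code in _ENCODE.items():
        out[states == sym] = code
    if np.any(out < 0):
        bad = set(np.unique(states)) - set(_ENCODE)
        raise ValueError(f"unknown secondary-structure symbols: {bad}")
    return out


def structure_score(ss_a, ss_b) -> int:
    """Secondary-structure mismatch score summed over residues.

    Per residue: 0 if the states agree, 1 for coil vs folded (H or E),
    4 for helix vs extended.  Inputs are equal-length sequences over
    {H, E, C} (strings or arrays).
    """
    a = encode_states(np.array(list(ss_a)) if isinstance(ss_a, str) else ss_a)
    b = encode_states(np.array(list(ss_b)) if isinstance(ss_b, str) else ss_b)
    if a.shape != b.shape:
        raise ValueError("state sequences differ in length")
    return int(_SCORE_TABLE[a, b].sum())


def swrmsd(frame_a: np.ndarray, frame_b: np.ndarray, ss_a, ss_b) -> float:
    """Structurally weighted RMSD: superposition RMSD times mismatch score."""
    score = structure_score(ss_a, ss_b)
    if score == 0:
        return 0.0
    return kabsch_superpose(frame_a, frame_b).rmsd * score


def _pair_scores(encoded: np.ndarray, i: int, others: np.ndarray) -> np.ndarray:
    """Scores between frame i and a set of frames, vectorised over residues."""
    return _SCORE_TABLE[encoded[i][None, :], encoded[others]].sum(axis=1)


def cluster_ensemble(ensemble: Ensemble, assignment: SecStructAssignment,
                     threshold: float, chain: str | None = None,
                     atom_name: str = "CA") -> ClusterResult:
    """Leader/medoid clustering of an ensemble under SWRMSD.

    Frames are scanned in trajectory order; each joins the earliest-founded
    cluster whose leader frame is within ``threshold`` (weighted Angstrom)
    in SWRMSD, founding a new cluster otherwise.  Afterwards each cluster's
    representative is its medoid (minimum summed SWRMSD to clustermates).
    """
    if not threshold > 0:
        raise ValueError("threshold must be positive")
    if ensemble.n_frames < 2:
        raise ValueError("clustering needs at least 2 frames")
    coords = ensemble.atom_coords(atom_name, chain=chain)
    encoded = encode_states(assignment.states)
    if encoded.shape[0] != ensemble.n_frames:
        raise ValueError("assignment frame count does not match ensemble")
    n_frames = coords.shape[0]

    leaders: list[int] = [0]
    labels = np.full(n_frames, -1, dtype=int)
    labels[0] = 0
    leader_arr = np.array(leaders)
    for f in range(1, n_frames):
        leader_arr = np.asarray(leaders)
        scores = _pair_scores(encoded, f, leader_arr)
        dists = np.zeros(len(leaders))
        nz = scores > 0
        if np.any(nz):
            rms = np.array([
                _batch_rmsd(coords[f][None], coords[l])[0]
                for l in leader_arr[nz]
            ])
            dists[nz] = rms * scores[nz]
        within = np.flatnonzero(dists <= threshold)
        if within.size:
            labels[f] = int(within[0])   # earliest-founded cluster wins ties
        else:
            leaders.append(f)
            labels[f] = len(leaders) - 1

    n_clusters = len(leaders)
    occupancies = np.bincount(labels, minlength=n_clusters) / n_frames
    representatives = np.empty(n_clusters, dtype=int)
    for k in range(n_clusters):
        members = np.flatnonzero(labels == k)
        representatives[k] = members[_medoid(coords[members], encoded[members])]
    return ClusterResult(labels=labels, occupancies=occupancies,
                         representatives=representatives, threshold=float(threshold))


def _medoid(coords: np.ndarray, encoded: np.ndarray, chunk: int = 256) -> int:
    """Index (within the cluster) of the frame minimising summed SWRMSD."""
    n = coords.shape[0]
    if n == 1:
        return 0
    totals = np.zeros(n)
    for i in range(n):
        scores = _SCORE_TABLE[encoded[i][None, :], encoded].sum(axis=1)
        nz = np.flatnonzero(scores > 0)
        if nz.size:
            for start in range(0, nz.size, chunk):
                sel = nz[start:start + chunk]
                rms = _batch_rmsd(coords[sel], coords[i])
                totals[i] += float((rms * scores[sel]).sum())
    return int(np.argmin(totals))


def rmsd_timeseries(ensemble: Ensemble, reference_index: int = 0,
                    chain: str | None = None, atom_name: str = "CA") -> np.ndarray:
    """Superposed RMSD of every frame against one reference frame.

    Band structure in this series (well-separated flat bands rather than a
    single slowly drifting one) signals the coexistence of substantially
    different structures in the trajectory.
    """
    coords = ensemble.atom_coords(atom_name, chain=chain)
    if not 0 <= reference_index < coords.shape[0]:
        raise IndexError(f"reference frame {reference_index} out of range")
    out = np.empty(coords.shape[0])
    ref = coords[reference_index]
    for start in range(0, coords.shape[0], 1024):
        out[start:start + 1024] = _batch_rmsd(coords[start:start + 1024], ref)
    return out
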