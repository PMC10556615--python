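"""Synthetic ensembles and tables with planted ground truth.

Every pipeline stage in the package is testable without external downloads
through these generators:

- :func:`ideal_chain` — freely jointed chains, the random-coil reference
  with exact closed forms (<Ree^2> = n b^2, shape ratio -> 1/sqrt(6));
- :func:`saw_pivot` — cubic-lattice self-avoiding walks sampled with the
  pivot algorithm, the good-solvent reference (nu ~= 0.588, ratio ~= 0.406);
- :func:`two_conformer_ensemble` — protein-like mixtures of a helix-rich
  and a hairpin (strand-rich) conformer plus coil frames at planted
  occupancies, for clustering and propensity recovery;
- :func:`complex_interface` — two-chain trajectories with a planted
  per-pair contact schedule, for contact-map bookkeeping;
- :func:`planted_nmr_tables` — peak/shift tables with planted isomer ratios
  and secondary-shift patterns.

All generators are seed-deterministic and return their ground truth
alongside the data.  Protein-like conformers are built by forward
kinematics from backbone dihedrals with ideal bond geometry, so the
secondary-structure stage can label them without real structures.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .ensemble import Ensemble, Topology
from .nmr import load_random_coil_shifts

__all__ = [
    "ideal_chain",
    "saw_pivot",
    "build_backbone",
    "two_conformer_ensemble",
    "complex_interface",
    "planted_nmr_tables",
    "monomer_ensemble",
]

logger = logging.getLogger(__name__)

# ideal backbone geometry (Angstrom / degrees)
BOND_N_CA = 1.46
BOND_CA_C = 1.52
BOND_C_N = 1.33
BOND_C_O = 1.23
ANGLE_N_CA_C = 111.0
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.8
OMEGA = 180.0

HELIX_PHI_PSI = (-60.0, -45.0)
STRAND_PHI_PSI = (-139.0, 135.0)


def monomer_ensemble(coords: np.ndarray, chain: str = "A") -> Ensemble:
    """Wrap (F, N, 3) monomer positions as a CA-only ensemble.

    Each monomer becomes one glycine residue carrying a single CA atom, so
    the polymer diagnostics (which default to CA selections) apply
    unchanged to abstract chains.
    """
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


def ideal_chain(n_bonds: int, bond_length: float = 1.0, n_samples: int = 1,
                seed: int | None = None) -> Ensemble:
    """Freely jointed chains: n_bonds uniformly random unit-direction bonds.

    The model's laws are exact: <Ree^2> = n_bonds * b^2 and, for long
    chains, <Rg^2> -> n_bonds * b^2 / 6, so the shape ratio approaches
    1/sqrt(6) ~= 0.408.
    """
    if n_bonds < 2 or n_samples < 1:
        raise ValueError("need n_bonds >= 2 and n_samples >= 1")
    rng = np.random.default_rng(seed)
    steps = rng.normal(size=(n_samples, n_bonds, 3))
    steps /= np.linalg.norm(steps, axis=2, keepdims=True)
    coords = np.zeros((n_samples, n_bonds + 1, 3))
    np.cumsum(steps * bond_length, axis=1, out=coords[:, 1:])
    return monomer_ensemble(coords)


def _octahedral_group() -> np.ndarray:
    """The 47 non-identity signed permutation matrices of the cubic lattice."""
    mats = []
    from itertools import permutations, product
    for perm in permutations(range(3)):
        for signs in product((1, -1), repeat=3):
            m = np.zeros((3, 3), dtype=np.int64)
            for row, (col, s) in enumerate(zip(perm, signs)):
                m[row, col] = s
            if not np.array_equal(m, np.eye(3, dtype=np.int64)):
                mats.append(m)
    return np.array(mats)


def saw_pivot(n_steps: int, n_samples: int, n_equilibration_pivots: int = 10,
              seed: int | None = None, burn_in: int | None = None) -> Ensemble:
    """Cubic-lattice self-avoiding walks sampled by the pivot algorithm.

    Each move picks a random interior pivot site and a random non-identity
    octahedral symmetry, applies it to the shorter arm of the walk, and
    rejects on self-intersection.  One sample is emitted every
    ``n_equilibration_pivots`` attempted moves after a burn-in (default:
    max(1000, 2 * n_steps) attempted moves from the initial rod).  Rejected
    moves count as steps of the chain -- skipping them would sample the
    embedded jump chain, whose stationary distribution over-weights walks
    with high acceptance probability (verified against exhaustive
    enumeration at n = 10).  Global observables decorrelate within a few
    attempted pivots, so the default stride is conservative.
    """
    if n_steps < 10:
        raise ValueError("need n_steps >= 10")
    if n_samples < 1 or n_equilibration_pivots < 1:
        raise ValueError("need n_samples >= 1 and a positive sampling stride")
    rng = np.random.default_rng(seed)
    group = _octahedral_group()
    n = n_steps
    if burn_in is None:
        burn_in = max(1000, 2 * n)
    pos = np.zeros((n + 1, 3), dtype=np.int64)
    pos[:, 0] = np.arange(n + 1)
    base = 2 * n + 1
    shift = n

    def keys(p):
        return ((p[:, 0] + shift) * base + (p[:, 1] + shift)) * base + (p[:, 2] + shift)

    samples = np.empty((n_samples, n + 1, 3))
    accepted = 0
    attempts = 0
    emitted = 0
    next_sample = burn_in + n_equilibration_pivots
    while emitted < n_samples:
        attempts += 1
        k = int(rng.integers(1, n))
        g = group[int(rng.integers(len(group)))]
        if k <= n // 2:
            moved = slice(0, k)
            fixed = slice(k, n + 1)
        else:
            moved = slice(k + 1, n + 1)
            fixed = slice(0, k + 1)
        p = pos[k]
        new_part = (pos[moved] - p) @ g.T + p
        if not np.any(np.isin(keys(new_part), keys(pos[fixed]))):
            pos[moved] = new_part
            accepted += 1
        # rejected attempts advance the chain too (the state repeats);
        # sampling on attempts keeps the uniform stationary distribution
        if attempts >= next_sample:
            samples[emitted] = pos
            emitted += 1
            next_sample += n_equilibration_pivots
    logger.info(
        "pivot sampler: n=%d, %d samples, acceptance rate %.3f",
        n, n_samples, accepted / attempts,
    )
    return monomer_ensemble(samples)


def _dihedral(p0, p1, p2, p3):
    """Signed dihedral angle p0-p1-p2-p3 in degrees."""
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m = np.cross(n1, b1 / np.linalg.norm(b1))
    return float(np.degrees(np.arctan2(np.dot(m, n2), np.dot(n1, n2))))


def _place(a, b, c, bond, angle_deg, dihedral_deg):
    """Next atom from three predecessors and internal coordinates (NeRF)."""
    theta = np.radians(angle_deg)
    chi = -np.radians(dihedral_deg)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d = bond * np.array([-np.cos(theta),
                         np.sin(theta) * np.cos(chi),
                         np.sin(theta) * np.sin(chi)])
    return c + d[0] * bc + d[1] * m + d[2] * n


def build_backbone(phi_psi: np.ndarray, sequence: str | None = None,
                   chain: str = "A") -> Ensemble:
    """Build an N/CA/C/O backbone from per-residue (phi, psi) dihedrals.

    Ideal bond lengths and angles are used throughout, with trans peptide
    bonds; amide hydrogens are left out (the assignment stage reconstructs
    them).  phi of the first residue and psi of the last have no geometric
    effect beyond placing the terminal oxygen.
    """
    phi_psi = np.asarray(phi_psi, dtype=float)
    n_res = phi_psi.shape[0]
    if n_res < 3:
        raise ValueError("need at least 3 residues")
    if sequence is None:
        sequence = "A" * n_res
    if len(sequence) != n_res:
        raise ValueError("sequence length must match dihedral count")
    from .ensemble import ONE_TO_THREE
    n_pos = np.empty((n_res, 3))
    ca_pos = np.empty((n_res, 3))
    c_pos = np.empty((n_res, 3))
    o_pos = np.empty((n_res, 3))
    # first residue in a canonical frame
    n_pos[0] = (0.0, 0.0, 0.0)
    ca_pos[0] = (BOND_N_CA, 0.0, 0.0)
    theta = np.radians(ANGLE_N_CA_C)
    c_pos[0] = ca_pos[0] + BOND_CA_C * np.array([-np.cos(theta), np.sin(theta), 0.0])
    for i in range(1, n_res):
        psi_prev = phi_psi[i - 1, 1]
        n_pos[i] = _place(n_pos[i - 1], ca_pos[i - 1], c_pos[i - 1],
                          BOND_C_N, ANGLE_CA_C_N, psi_prev)
        ca_pos[i] = _place(ca_pos[i - 1], c_pos[i - 1], n_pos[i],
                           BOND_N_CA, ANGLE_C_N_CA, OMEGA)
        c_pos[i] = _place(c_pos[i - 1], n_pos[i], ca_pos[i],
                          BOND_CA_C, ANGLE_N_CA_C, phi_psi[i, 0])
    for i in range(n_res):
        psi = phi_psi[i, 1]
        o_pos[i] = _place(n_pos[i], ca_pos[i], c_pos[i],
                          BOND_C_O, ANGLE_CA_C_O, psi + 180.0)
    coords = np.empty((1, 4 * n_res, 3))
    names = np.empty(4 * n_res, dtype="U2")
    res_index = np.repeat(np.arange(n_res), 4)
    for i in range(n_res):
        coords[0, 4 * i + 0] = n_pos[i]
        coords[0, 4 * i + 1] = ca_pos[i]
        coords[0, 4 * i + 2] = c_pos[i]
        coords[0, 4 * i + 3] = o_pos[i]
        names[4 * i:4 * i + 4] = ("N", "CA", "C", "O")
    elements = np.array([n[0] for n in names])
    top = Topology(
        chain_ids=np.full(n_res, chain),
        res_numbers=np.arange(1, n_res + 1),
        res_names=np.array([ONE_TO_THREE[c] for c in sequence]),
        res_codes=np.array(list(sequence)),
        atom_res_index=res_index,
        atom_names=names,
        elements=elements,
    )
    return Ensemble(top, coords)


def _coil_phi_psi(n_res: int, rng) -> np.ndarray:
    """Dihedrals sampled uniformly from the broad beta basin (no helix)."""
    phi = rng.uniform(-160.0, -70.0, size=n_res)
    psi = rng.uniform(90.0, 170.0, size=n_res)
    return np.column_stack([phi, psi])


def helix_rich_phi_psi(n_res: int) -> np.ndarray:
    """Template dihedrals: two helical segments joined by extended linkers."""
    pp = np.tile([-80.0, 150.0], (n_res, 1))
    seg1 = slice(4, min(18, n_res - 2))
    seg2 = slice(min(23, n_res - 2), min(36, n_res - 2))
    pp[seg1] = HELIX_PHI_PSI
    pp[seg2] = HELIX_PHI_PSI
    return pp


def hairpin_phi_psi(n_res: int) -> np.ndarray:
    """Template dihedrals: an antiparallel beta hairpin.

    The strand and turn dihedrals were tuned once so that the two strands
    stay hydrogen-bonded in register over their full length under the ideal
    bond geometry used by :func:`build_backbone` (the twist of ideal strands
    otherwise frays the pairing after a few residues).
    """
    strand = (-127.1, 124.1)
    pp = np.tile([-70.0, 140.0], (n_res, 1))
    half = min(10, (n_res - 8) // 2)
    s1 = slice(4, 4 + half)
    turn_at = 4 + half
    s2 = slice(turn_at + 2, turn_at + 2 + half)
    pp[s1] = strand
    pp[turn_at] = (62.0, -63.3)
    pp[turn_at + 1] = (-151.3, 19.8)
    pp[s2] = strand
    return pp


def two_conformer_ensemble(n_res: int = 40,
                           occupancies: tuple[float, float, float] = (0.46, 0.45, 0.09),
                           noise_rms: float = 1.0, n_frames: int = 2000,
                           seed: int | None = None):
    """Mixture of a helix-rich and a strand-rich conformer plus coil frames.

    Frames are drawn from the three populations at the planted occupancies
    (conformer 1, conformer 2, coil), perturbed by isotropic Gaussian noise
    of per-atom rms ``noise_rms`` (Angstrom), and shuffled.  Returns
    ``(ensemble, labels)`` with labels 0/1/2 for conformer1/conformer2/coil,
    the ground truth for recovery tests.
    """
    if n_res < 20:
        raise ValueError("need n_res >= 20")
    occ = np.asarray(occupancies, dtype=float)
    if occ.shape != (3,) or np.any(occ < 0) or not np.isclose(occ.sum(), 1.0):
        raise ValueError("occupancies must be three non-negative values summing to 1")
    rng = np.random.default_rng(seed)
    conf1 = build_backbone(helix_rich_phi_psi(n_res))
    conf2 = build_backbone(hairpin_phi_psi(n_res))
    labels = rng.choice(3, size=n_frames, p=occ)
    n_atoms = conf1.coords.shape[1]
    coords = np.empty((n_frames, n_atoms, 3))
    sigma = noise_rms / np.sqrt(3.0)
    for f in range(n_frames):
        if labels[f] == 0:
            base = conf1.coords[0]
        elif labels[f] == 1:
            base = conf2.coords[0]
        else:
            base = build_backbone(_coil_phi_psi(n_res, rng)).coords[0]
        coords[f] = base + rng.normal(scale=sigma, size=(n_atoms, 3))
    return Ensemble(conf1.topology, coords), labels


def complex_interface(n_res_a: int, n_res_b: int, schedule: dict,
                      n_frames: int, seed: int | None = None,
                      cutoff: float = 12.0):
    """Two-chain trajectory with a planted per-pair contact schedule.

    ``schedule`` maps (residue_a, residue_b) pairs (1-based numbers) to
    contact fractions in [0, 1].  In each frame every scheduled pair is
    independently placed in contact (within ``cutoff``) with its planted
    probability, or held well apart otherwise; unscheduled residues never
    contact.  Geometric feasibility requires each chain-B residue to appear
    in at most one pair and each chain-A residue in at most two.  Returns
    ``(ensemble, realized)`` where ``realized`` is the (Ra, Rb) matrix of
    contact fractions actually generated, the bookkeeping oracle.
    """
    spacing = 3.0 * cutoff
    rng = np.random.default_rng(seed)
    pairs = {}
    b_seen = {}
    a_count = {}
    for (i, j), frac in schedule.items():
        if not (1 <= i <= n_res_a and 1 <= j <= n_res_b):
            raise ValueError(f"pair {(i, j)} outside the chains")
        if not 0.0 <= frac <= 1.0:
            raise ValueError(f"pair {(i, j)}: fraction {frac} outside [0, 1]")
        if j in b_seen:
            raise ValueError(
                f"infeasible schedule: chain-B residue {j} appears in both "
                f"{(b_seen[j], j)} and {(i, j)}"
            )
        a_count[i] = a_count.get(i, 0) + 1
        if a_count[i] > 2:
            raise ValueError(
                f"infeasible schedule: chain-A residue {i} has more than two "
                f"partners (adding pair {(i, j)})"
            )
        b_seen[j] = i
        pairs[(i, j)] = frac

    near, far, away = 0.6 * cutoff, 4.0 * cutoff, 100.0 * cutoff
    # z-stagger so two partners of the same A residue stay within the cutoff
    z_off = {}
    for i in a_count:
        partners = sorted(j for (a, j) in pairs if a == i)
        for rank, j in enumerate(partners):
            z_off[(i, j)] = (0.0 if rank == 0 else 0.5 * cutoff)

    n_atoms = n_res_a + n_res_b
    coords = np.empty((n_frames, n_atoms, 3))
    realized = np.zeros((n_res_a, n_res_b))
    ax = spacing * np.arange(n_res_a)
    for f in range(n_frames):
        xyz = np.zeros((n_atoms, 3))
        xyz[:n_res_a, 0] = ax
        xyz[n_res_a:, 0] = spacing * np.arange(n_res_b)
        xyz[n_res_a:, 1] = away
        for (i, j), frac in pairs.items():
            contact = rng.random() < frac
            y = near if contact else far
            xyz[n_res_a + j - 1] = (ax[i - 1], y, z_off[(i, j)])
            if contact:
                realized[i - 1, j - 1] += 1
        coords[f] = xyz
    realized /= n_frames

    top = Topology(
        chain_ids=np.array(["A"] * n_res_a + ["B"] * n_res_b),
        res_numbers=np.concatenate([np.arange(1, n_res_a + 1),
                                    np.arange(1, n_res_b + 1)]),
        res_names=np.full(n_atoms, "GLY"),
        res_codes=np.full(n_atoms, "G"),
        atom_res_index=np.arange(n_atoms),
        atom_names=np.full(n_atoms, "CA"),
        elements=np.full(n_atoms, "C"),
    )
    return Ensemble(top, coords), realized


def planted_nmr_tables(ratio_cis_percent: float, n_residues: int,
                       pattern=None, height_noise: float = 0.0,
                       shift_noise: float = 0.0, seed: int | None = None,
                       cis_pro_offset: float | None = None):
    """Peak and shift tables with a planted isomer ratio and shift pattern.

    Every residue gets a cis and a trans peak whose heights realise the
    planted cis percentage (with optional multiplicative noise), and Ca/Cb
    shifts equal to the random-coil reference plus/minus half the planted
    secondary-shift ``pattern`` (so the Ca-Cb differential equals the
    pattern exactly at zero noise).  If ``cis_pro_offset`` is given, a
    proline is appended whose cis Ca sits that many ppm upfield of trans.
    Returns ``(peak_table, shift_table)`` as data frames.
    """
    if not 0.0 < ratio_cis_percent < 100.0:
        raise ValueError("cis percentage must lie strictly between 0 and 100")
    rng = np.random.default_rng(seed)
    ref = load_random_coil_shifts()
    codes = [c for c in "ADEFIKLNQRSTVWY"]
    if pattern is None:
        pattern = np.zeros(n_residues)
    pattern = np.asarray(pattern, dtype=float)
    if pattern.shape != (n_residues,):
        raise ValueError("pattern length must equal n_residues")

    base_height = 1.0e6
    peak_rows = []
    shift_rows = []
    for r in range(1, n_residues + 1):
        code = codes[(r - 1) % len(codes)]
        h_cis = base_height * ratio_cis_percent / 100.0
        h_trans = base_height * (100.0 - ratio_cis_percent) / 100.0
        if height_noise > 0:
            h_cis *= max(1e-9, 1.0 + height_noise * rng.normal())
            h_trans *= max(1e-9, 1.0 + height_noise * rng.normal())
        peak_rows.append((r, code, "cis", h_cis))
        peak_rows.append((r, code, "trans", h_trans))
        ca = ref.loc[code, "ca"] + pattern[r - 1] / 2.0
        cb = ref.loc[code, "cb"] - pattern[r - 1] / 2.0
        if shift_noise > 0:
            ca += shift_noise * rng.normal()
            cb += shift_noise * rng.normal()
        shift_rows.append((r, code, "CA", ca, "none"))
        shift_rows.append((r, code, "CB", cb, "none"))
    if cis_pro_offset is not None:
        r = n_residues + 1
        trans_ca = ref.loc["P", "ca"]
        shift_rows.append((r, "P", "CA", trans_ca, "trans"))
        shift_rows.append((r, "P", "CA", trans_ca - cis_pro_offset, "cis"))
    peaks = pd.DataFrame(peak_rows, columns=["residue", "code", "isomer", "height"])
    shifts = pd.DataFrame(
        shift_rows, columns=["residue", "code", "atom", "shift", "isomer"]
    )
    return peaks, shifts
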