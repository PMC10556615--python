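"""Coordinate/topology data model and multi-model PDB input/output.

An :class:`Ensemble` is an ordered set of conformations ("frames") of one
molecular system: a shared :class:`Topology` (chains, residues, named atoms)
plus a ``frames x atoms x 3`` coordinate array in Angstrom.  Every analysis
stage in the package consumes this container, whether the frames come from a
molecular-dynamics trajectory, an NMR-style multi-model PDB file, or one of
the synthetic generators in :mod:`idpkit.synth`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import biotite.structure as struc
import biotite.structure.io.pdb as pdbio

__all__ = [
    "Topology",
    "Ensemble",
    "MalformedEnsembleError",
    "SelectionError",
    "read_multimodel_pdb",
    "write_multimodel_pdb",
]

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}


class MalformedEnsembleError(ValueError):
    """The input does not describe a consistent multi-frame ensemble."""


class SelectionError(ValueError):
    """A chain/residue selection matched nothing or is invalid."""


@dataclass(frozen=True)
class Topology:
    """Chains, residues and named atoms shared by all frames of an ensemble.

    Residues are stored in file order; atoms reference residues by positional
    index.  Residue numbering follows the input file (1-based in normal PDB
    practice); no renumbering is performed on read.
    """

    chain_ids: np.ndarray      # (R,) chain identifier per residue
    res_numbers: np.ndarray    # (R,) residue number per residue
    res_names: np.ndarray      # (R,) 3-letter residue name
    res_codes: np.ndarray      # (R,) 1-letter residue code ('X' if unknown)
    atom_res_index: np.ndarray  # (A,) residue index of each atom
    atom_names: np.ndarray     # (A,) atom name (e.g. 'N', 'CA', 'C', 'O')
    elements: np.ndarray       # (A,) element symbol per atom

    def __post_init__(self):
        for name in ("chain_ids", "res_numbers", "res_names", "res_codes",
                     "atom_res_index", "atom_names", "elements"):
            object.__setattr__(self, name, np.asarray(getattr(self, name)))
        if self.n_residues == 0 or self.n_atoms == 0:
            raise MalformedEnsembleError("topology has no residues or atoms")
        if self.atom_res_index.min() < 0 or self.atom_res_index.max() >= self.n_residues:
            raise MalformedEnsembleError("atom references an invalid residue")
        # residue numbers strictly increasing within each chain
        for cid in self.chains:
            nums = self.res_numbers[self.chain_ids == cid]
            if np.any(np.diff(nums) <= 0):
                raise MalformedEnsembleError(
                    f"residue numbers not strictly increasing in chain {cid!r}"
                )

    @property
    def n_residues(self) -> int:
        return len(self.res_numbers)

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    @property
    def chains(self) -> list:
        """Chain identifiers in order of first appearance."""
        _, idx = np.unique(self.chain_ids, return_index=True)
        return [self.chain_ids[i] for i in np.sort(idx)]

    def atom_index(self, res_index: int, atom_name: str) -> int | None:
        """Index of atom ``atom_name`` in residue ``res_index``, or None."""
        hits = np.flatnonzero(
            (self.atom_res_index == res_index) & (self.atom_names == atom_name)
        )
        return int(hits[0]) if hits.size else None

    def backbone_complete(self, res_index: int) -> bool:
        """Whether the residue carries all of N, CA, C and O."""
        names = set(self.atom_names[self.atom_res_index == res_index])
        return {"N", "CA", "C", "O"} <= names

    def residue_indices(self, chain: str | None = None,
                        residue_range: tuple[int, int] | None = None) -> np.ndarray:
        mask = np.ones(self.n_residues, dtype=bool)
        if chain is not None:
            if chain not in self.chains:
                raise SelectionError(f"unknown chain {chain!r}")
            mask &= self.chain_ids == chain
        if residue_range is not None:
            lo, hi = residue_range
            if lo > hi:
                raise SelectionError(f"empty residue range {lo}:{hi}")
            mask &= (self.res_numbers >= lo) & (self.res_numbers <= hi)
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            raise SelectionError(
                f"selection chain={chain!r} range={residue_range!r} matched no residue"
            )
        return idx

    def atom_indices(self, res_indices: np.ndarray | None = None,
                     atom_name: str | None = None) -> np.ndarray:
        """Atom indices restricted to given residues and/or one atom name."""
        mask = np.ones(self.n_atoms, dtype=bool)
        if res_indices is not None:
            mask &= np.isin(self.atom_res_index, res_indices)
        if atom_name is not None:
            mask &= self.atom_names == atom_name
        return np.flatnonzero(mask)

    def sequence(self, chain: str | None = None) -> str:
        """One-letter sequence of one chain (or the whole topology)."""
        idx = self.residue_indices(chain=chain)
        return "".join(self.res_codes[idx])


@dataclass
class Ensemble:
    """A conformational ensemble: one topology, ``n_frames`` coordinate sets."""

    topology: Topology
    coords: np.ndarray                 # (F, A, 3) in Angstrom
    frame_times: np.ndarray | None = None  # optional, ns

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise MalformedEnsembleError("coordinates must have shape (frames, atoms, 3)")
        if self.coords.shape[0] < 1:
            raise MalformedEnsembleError("ensemble must contain at least one frame")
        if self.coords.shape[1] != self.topology.n_atoms:
            raise MalformedEnsembleError(
                f"coordinate array has {self.coords.shape[1]} atoms, "
                f"topology has {self.topology.n_atoms}"
            )
        if not np.all(np.isfinite(self.coords)):
            raise MalformedEnsembleError("non-finite coordinates")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    def select(self, chain: str | None = None,
               residue_range: tuple[int, int] | None = None) -> "Ensemble":
        """Sub-ensemble restricted to one chain and/or residue-number range.

        The range is inclusive and expressed in the file's residue numbers.
        Atom order is preserved; the frame count is unchanged.
        """
        res_idx = self.topology.residue_indices(chain, residue_range)
        atom_idx = self.topology.atom_indices(res_indices=res_idx)
        remap = {int(old): new for new, old in enumerate(res_idx)}
        top = Topology(
            chain_ids=self.topology.chain_ids[res_idx],
            res_numbers=self.topology.res_numbers[res_idx],
            res_names=self.topology.res_names[res_idx],
            res_codes=self.topology.res_codes[res_idx],
            atom_res_index=np.array(
                [remap[int(i)] for i in self.topology.atom_res_index[atom_idx]]
            ),
            atom_names=self.topology.atom_names[atom_idx],
            elements=self.topology.elements[atom_idx],
        )
        return Ensemble(top, self.coords[:, atom_idx], self.frame_times)

    def atom_coords(self, atom_name: str, chain: str | None = None) -> np.ndarray:
        """Coordinates of one named atom per residue, shape (F, R_sel, 3)."""
        res_idx = self.topology.residue_indices(chain=chain)
        idx = self.topology.atom_indices(res_indices=res_idx, atom_name=atom_name)
        if idx.size == 0:
            raise SelectionError(f"no atoms named {atom_name!r} in selection")
        return self.coords[:, idx]


def _infer_element(atom_name: str) -> str:
    name = atom_name.strip()
    if not name:
        return ""
    if name[0].isdigit():
        name = name.lstrip("0123456789")
    return name[0].upper()


def read_multimodel_pdb(path) -> Ensemble:
    """Read a (multi-)MODEL PDB file into an :class:`Ensemble`.

    All models must contain the same atoms in the same order; a single
    structure without MODEL records yields a one-frame ensemble.  The first
    alternate location of each atom is kept; insertion codes are rejected.
    """
    try:
        pdb_file = pdbio.PDBFile.read(path)
    except OSError:
        raise
    except Exception as exc:  # malformed records
        raise MalformedEnsembleError(f"cannot parse PDB file {path}: {exc}") from exc
    try:
        n_models = pdb_file.get_model_count()
    except Exception as exc:
        raise MalformedEnsembleError(f"no coordinate models in {path}: {exc}") from exc
    if n_models == 0:
        raise MalformedEnsembleError(f"no coordinate models in {path}")
    for line in pdb_file.lines:
        if line.startswith(("ATOM", "HETATM")) and len(line) > 26 and line[26] != " ":
            raise MalformedEnsembleError(
                f"{path} contains insertion codes, which are not supported"
            )
    try:
        stack = pdb_file.get_structure(model=None, altloc="first")
    except Exception as exc:
        raise MalformedEnsembleError(
            f"inconsistent models in {path} (atom count/order mismatch): {exc}"
        ) from exc
    return _from_atom_array_stack(stack)


def _from_atom_array_stack(stack: struc.AtomArrayStack) -> Ensemble:
    starts = struc.get_residue_starts(stack)
    n_res = len(starts)
    chain_ids = stack.chain_id[starts]
    res_numbers = stack.res_id[starts]
    res_names = stack.res_name[starts]
    res_codes = np.array([THREE_TO_ONE.get(n, "X") for n in res_names])
    bounds = np.append(starts, stack.array_length())
    atom_res_index = np.repeat(np.arange(n_res), np.diff(bounds))
    elements = stack.element
    if np.all(elements == ""):
        elements = np.array([_infer_element(n) for n in stack.atom_name])
    top = Topology(
        chain_ids=chain_ids,
        res_numbers=res_numbers,
        res_names=res_names,
        res_codes=res_codes,
        atom_res_index=atom_res_index,
        atom_names=stack.atom_name,
        elements=elements,
    )
    return Ensemble(top, stack.coord)


def _to_atom_array_stack(ensemble: Ensemble) -> struc.AtomArrayStack:
    top = ensemble.topology
    stack = struc.AtomArrayStack(ensemble.n_frames, top.n_atoms)
    stack.coord = ensemble.coords
    stack.chain_id = top.chain_ids[top.atom_res_index].astype("U4")
    stack.res_id = top.res_numbers[top.atom_res_index]
    stack.res_name = top.res_names[top.atom_res_index].astype("U5")
    stack.atom_name = top.atom_names.astype("U6")
    stack.element = top.elements.astype("U2")
    stack.hetero = np.zeros(top.n_atoms, dtype=bool)
    return stack


def write_multimodel_pdb(ensemble: Ensemble, path) -> None:
    """Write an ensemble as a multi-MODEL PDB file (0.001 A precision)."""
    if not isinstance(ensemble, Ensemble):
        raise TypeError("expected an Ensemble")
    pdb_file = pdbio.PDBFile()
    pdb_file.set_structure(_to_atom_array_stack(ensemble))
    pdb_file.write(path)
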