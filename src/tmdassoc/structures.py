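"""Structure ensembles, atom selections, and multi-model PDB I/O.

A :class:`StructureEnsemble` is the in-memory container every structural
observable operates on: an (n_frames, n_atoms, 3) coordinate block in Å plus
one atom table (pandas DataFrame) shared by all frames.  Multi-model PDB
files (MODEL/ENDMDL records, as deposited for NMR ensembles such as the
integrin TMD structure 2K9J) map one model to one frame.

Residue numbering follows the file's author numbering (for integrin work,
the αIIbβ3 convention); selections use 1-based inclusive residue ranges.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import biotite.structure as struc
import biotite.structure.info as struc_info
import biotite.structure.io.pdb as pdb

from .exceptions import FormatError, SelectionError, ValidationError

__all__ = ["StructureEnsemble", "AtomSelection", "read_structure_ensemble",
           "write_structure_ensemble"]

_FALLBACK_MASS = 12.011

ATOM_COLUMNS = ["chain_id", "res_id", "res_name", "atom_name", "element", "mass"]


def _element_mass(element: str, atom_name: str) -> float:
    element = (element or "").strip()
    if not element:
        element = atom_name.strip()[:1]
    try:
        m = struc_info.mass(element.capitalize(), is_residue=False)
    except KeyError:
        m = None
    if m is None:
        warnings.warn(f"unknown element {element!r} for atom {atom_name!r}; "
                      f"assigning carbon mass {_FALLBACK_MASS}")
        return _FALLBACK_MASS
    return float(m)


@dataclass
class StructureEnsemble:
    """Frames × labelled atoms.

    Parameters
    ----------
    coords : ndarray, shape (n_frames, n_atoms, 3)
        Cartesian coordinates in Å.
    atoms : DataFrame
        Columns ``chain_id, res_id, res_name, atom_name, element, mass``;
        one row per atom, shared by all frames.
    """

    coords: np.ndarray
    atoms: pd.DataFrame

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValidationError("coords must have shape (n_frames, n_atoms, 3)")
        if self.coords.shape[0] < 1:
            raise ValidationError("ensemble needs at least one frame")
        if not np.all(np.isfinite(self.coords)):
            raise ValidationError("coordinates must be finite")
        missing = [c for c in ATOM_COLUMNS if c not in self.atoms.columns]
        if missing:
            raise ValidationError(f"atom table missing columns {missing}")
        if len(self.atoms) != self.coords.shape[1]:
            raise ValidationError("atom table length does not match coordinate block")
        self.atoms = self.atoms.reset_index(drop=True)

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    @property
    def masses(self) -> np.ndarray:
        return self.atoms["mass"].to_numpy(dtype=float)

    def select(self, selection: "AtomSelection") -> np.ndarray:
        """Resolve a selection to atom indices (raises if empty)."""
        return selection.resolve(self.atoms)

    def subset(self, indices) -> "StructureEnsemble":
        indices = np.asarray(indices)
        return StructureEnsemble(self.coords[:, indices, :],
                                 self.atoms.iloc[indices].reset_index(drop=True))

    def frame(self, index: int) -> "StructureEnsemble":
        return StructureEnsemble(self.coords[index:index + 1], self.atoms)

    def com(self, indices, frame: int | None = None) -> np.ndarray:
        """Mass-weighted center of mass of the given atoms, per frame
        (shape (n_frames, 3)) or for one frame (shape (3,))."""
        indices = np.asarray(indices)
        if indices.size == 0:
            raise SelectionError("cannot take COM of an empty selection")
        m = self.masses[indices]
        xyz = self.coords[:, indices, :]
        com = (xyz * m[None, :, None]).sum(axis=1) / m.sum()
        return com[frame] if frame is not None else com

    # -- I/O ---------------------------------------------------------------

    @classmethod
    def from_pdb(cls, path) -> "StructureEnsemble":
        return read_structure_ensemble(path)

    def to_pdb(self, path) -> Path:
        return write_structure_ensemble(self, path)


@dataclass(frozen=True)
class AtomSelection:
    """Named selection: chain / residue-range(s) / atom-name filters.

    ``res_ids`` may be an explicit iterable of residue numbers or a
    ``(start, stop)`` inclusive pair; ``None`` means no filtering on that
    field.  Matching is by author residue numbers (1-based, inclusive).
    """

    chain: str | None = None
    res_ids: tuple | None = None
    atom_names: tuple | None = None
    res_names: tuple | None = None
    label: str = ""

    @staticmethod
    def range(chain: str | None, start: int, stop: int, atom_names=None) -> "AtomSelection":
        """Inclusive residue range, e.g. ``AtomSelection.range("A", 996, 1015, ("CA",))``."""
        return AtomSelection(chain=chain, res_ids=(("range", start, stop)),
                             atom_names=tuple(atom_names) if atom_names else None,
                             label=f"{chain or '*'}:{start}-{stop}")

    def mask(self, atoms: pd.DataFrame) -> np.ndarray:
        m = np.ones(len(atoms), dtype=bool)
        if self.chain is not None:
            m &= (atoms["chain_id"] == self.chain).to_numpy()
        if self.res_ids is not None:
            rid = atoms["res_id"].to_numpy()
            if isinstance(self.res_ids, tuple) and len(self.res_ids) == 3 and self.res_ids[0] == "range":
                _, start, stop = self.res_ids
                m &= (rid >= start) & (rid <= stop)
            else:
                m &= np.isin(rid, np.asarray(list(self.res_ids)))
        if self.atom_names is not None:
            m &= atoms["atom_name"].isin(self.atom_names).to_numpy()
        if self.res_names is not None:
            m &= atoms["res_name"].isin(self.res_names).to_numpy()
        return m

    def resolve(self, atoms: pd.DataFrame) -> np.ndarray:
        idx = np.flatnonzero(self.mask(atoms))
        if idx.size == 0:
            raise SelectionError(f"selection {self.label or self} matched no atoms")
        return idx


def read_structure_ensemble(path) -> StructureEnsemble:
    """Read a (multi-model) PDB file into a :class:`StructureEnsemble`.

    One MODEL per frame; a bare coordinate block counts as one frame.
    Masses come from the element column (fallback: first letter of the atom
    name; unknown elements get a carbon mass with a warning).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        pfile = pdb.PDBFile.read(str(path))
        stack = pfile.get_structure(model=None)
    except Exception as exc:
        raise FormatError(f"could not parse PDB file {path}: {exc}") from exc
    if stack.array_length() == 0:
        raise FormatError(f"PDB file {path} contains no atoms")
    coords = np.asarray(stack.coord, dtype=float)
    if coords.ndim == 2:  # single model
        coords = coords[None]
    masses = np.array([_element_mass(el, nm)
                       for el, nm in zip(stack.element, stack.atom_name)])
    atoms = pd.DataFrame({
        "chain_id": stack.chain_id,
        "res_id": stack.res_id.astype(int),
        "res_name": stack.res_name,
        "atom_name": stack.atom_name,
        "element": stack.element,
        "mass": masses,
    })
    return StructureEnsemble(coords, atoms)


def write_structure_ensemble(ensemble: StructureEnsemble, path) -> Path:
    """Write as multi-model PDB (MODEL/ENDMDL records)."""
    path = Path(path)
    n_frames, n_atoms = ensemble.n_frames, ensemble.n_atoms
    arr = struc.AtomArrayStack(n_frames, n_atoms)
    arr.coord = ensemble.coords.astype(np.float32)
    at = ensemble.atoms
    arr.chain_id = at["chain_id"].to_numpy(dtype="U4")
    arr.res_id = at["res_id"].to_numpy(dtype=int)
    arr.res_name = at["res_name"].to_numpy(dtype="U5")
    arr.atom_name = at["atom_name"].to_numpy(dtype="U6")
    arr.element = at["element"].to_numpy(dtype="U2")
    arr.hetero = np.zeros(n_atoms, dtype=bool)
    pfile = pdb.PDBFile()
    pfile.set_structure(arr)
    path.parent.mkdir(parents=True, exist_ok=True)
    pfile.write(str(path))
    return path
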