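"""Protein structure container and geometric primitives.

Structures are read from PDB files (via gemmi) into a lightweight atomic
container indexed by ``(residue_index, atom_name)``.  All distance
computations used downstream — Cα–Cα separations for contact tests and
H–H separations for NOE simulation — live here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import gemmi

__all__ = [
    "Atom",
    "ProteinStructure",
    "read_structure",
    "write_structure",
    "place_amide_hydrogens",
    "ca_distance",
    "h_distance",
]

#: the 20 standard amino acids, 3-letter -> 1-letter
THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

#: N–H bond length used when placing missing amide hydrogens, Å
AMIDE_NH_LENGTH = 1.01


@dataclass
class Atom:
    """One atom: 1-based residue index, PDB-style names, position in Å."""

    residue_index: int
    residue_name: str
    atom_name: str
    element: str
    position: np.ndarray

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,):
            raise ValueError("atom position must be a 3-vector")
        if not np.all(np.isfinite(self.position)):
            raise ValueError(
                f"non-finite coordinates for atom {self.residue_index}/{self.atom_name}"
            )

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() == "H"


class ProteinStructure:
    """A single-chain, single-model protein structure.

    Atoms are indexed by ``(residue_index, atom_name)``; both must be unique
    within one model.  Every residue must carry a CA atom, which anchors all
    residue-level distance computations.
    """

    def __init__(self, atoms: Iterable[Atom], model_id: int = 1):
        self.model_id = int(model_id)
        self.atoms: list[Atom] = list(atoms)
        self._index: dict[tuple[int, str], Atom] = {}
        for atom in self.atoms:
            key = (atom.residue_index, atom.atom_name)
            if key in self._index:
                raise ValueError(
                    f"duplicate atom {key} in model {self.model_id}"
                )
            self._index[key] = atom
        self.residue_indices: list[int] = sorted(
            {a.residue_index for a in self.atoms}
        )
        self.residue_names: dict[int, str] = {}
        for atom in self.atoms:
            self.residue_names.setdefault(atom.residue_index, atom.residue_name)
        missing_ca = [i for i in self.residue_indices if (i, "CA") not in self._index]
        if missing_ca:
            raise ValueError(f"residues without CA atom: {missing_ca}")

    # ------------------------------------------------------------------ basic
    @property
    def n_resi(self) -> int:
        return len(self.residue_indices)

    @property
    def sequence(self) -> str:
        return "".join(
            THREE_TO_ONE.get(self.residue_names[i], "X")
            for i in self.residue_indices
        )

    def __len__(self) -> int:
        return len(self.atoms)

    def has_atom(self, residue_index: int, atom_name: str) -> bool:
        return (residue_index, atom_name) in self._index

    def atom(self, residue_index: int, atom_name: str) -> Atom:
        try:
            return self._index[(residue_index, atom_name)]
        except KeyError:
            raise KeyError(
                f"no atom {atom_name!r} in residue {residue_index}"
            ) from None

    def hydrogens(self) -> Iterator[Atom]:
        for atom in self.atoms:
            if atom.is_hydrogen:
                yield atom

    def ca_positions(self) -> np.ndarray:
        """Cα coordinates in residue-index order, shape (n_resi, 3)."""
        return np.array([self.atom(i, "CA").position for i in self.residue_indices])

    def copy(self) -> "ProteinStructure":
        return ProteinStructure(
            [Atom(a.residue_index, a.residue_name, a.atom_name, a.element,
                  a.position.copy()) for a in self.atoms],
            model_id=self.model_id,
        )


# ---------------------------------------------------------------------- I/O

def read_structure(
    path: str | Path,
    model_index: int = 1,
    chain_id: str | None = None,
) -> ProteinStructure:
    """Read one model of a PDB file into a :class:`ProteinStructure`.

    Parameters
    ----------
    path:
        PDB file; multi-model NMR ensembles are supported.
    model_index:
        1-based model number (position in the file, not the MODEL record value).
    chain_id:
        Chain to read; defaults to the first chain in the model.

    Only standard amino-acid residues are kept (solvent and ligands are
    dropped).  For alternate locations the highest-occupancy conformer is
    kept, ties broken by first occurrence.  ``HN`` is normalized to ``H``.
    Insertion codes are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    st = gemmi.read_pdb(str(path))
    if len(st) == 0:
        raise ValueError(f"no models found in {path}")
    if not (1 <= model_index <= len(st)):
        raise IndexError(
            f"model_index {model_index} out of range (file has {len(st)} models)"
        )
    model = st[model_index - 1]
    if chain_id is None:
        chain = model[0]
    else:
        chain = model.find_chain(chain_id)
        if chain is None:
            raise KeyError(f"chain {chain_id!r} not found")

    atoms: list[Atom] = []
    for res in chain:
        if res.name not in THREE_TO_ONE:
            continue
        if res.seqid.icode.strip():
            raise ValueError(
                f"insertion code {res.seqid.icode!r} at residue "
                f"{res.seqid.num} is not supported"
            )
        # altloc resolution: highest occupancy, first occurrence on ties
        by_name: dict[str, gemmi.Atom] = {}
        for atom in res:
            prev = by_name.get(atom.name)
            if prev is None or atom.occ > prev.occ:
                by_name[atom.name] = atom
        for name, atom in by_name.items():
            norm = "H" if name == "HN" else name
            pos = np.array([atom.pos.x, atom.pos.y, atom.pos.z])
            atoms.append(Atom(res.seqid.num, res.name, norm,
                              atom.element.name, pos))
    if not atoms:
        raise ValueError(f"no standard-residue atoms in {path}")
    return ProteinStructure(atoms, model_id=model_index)


def write_structure(structure: ProteinStructure, path: str | Path) -> None:
    """Write a structure as a single-model PDB file (ATOM records + END)."""
    lines = []
    serial = 1
    for atom in structure.atoms:
        name = atom.atom_name
        # PDB fixed-width atom-name convention: <4-char names with 1-letter
        # elements start in column 14
        if len(name) < 4 and len(atom.element) == 1:
            name_field = f" {name:<3s}"
        else:
            name_field = f"{name:<4s}"
        x, y, z = atom.position
        lines.append(
            f"ATOM  {serial:5d} {name_field} {atom.residue_name:<3s} A"
            f"{atom.residue_index:4d}    {x:8.3f}{y:8.3f}{z:8.3f}"
            f"{1.00:6.2f}{0.00:6.2f}          {atom.element:>2s}"
        )
        serial += 1
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------- hydrogen placement

def place_amide_hydrogens(structure: ProteinStructure) -> ProteinStructure:
    """Add missing backbone amide hydrogens with ideal planar geometry.

    For each residue that has no ``H`` on its backbone nitrogen, an H is
    placed 1.01 Å from N along the reverse of the bisector of the
    C(i−1)→N and CA→N bond directions (the standard trans-amide plane).
    Prolines and the N-terminal residue are skipped (no amide H / no
    preceding carbonyl), as are residues with missing or degenerate
    backbone geometry (with a warning).  Existing atoms are never moved.
    """
    out = structure.copy()
    new_atoms: list[Atom] = []
    indices = out.residue_indices
    for pos_in_chain, i in enumerate(indices):
        if out.has_atom(i, "H"):
            continue
        if out.residue_names[i] == "PRO" or pos_in_chain == 0:
            continue
        prev = indices[pos_in_chain - 1]
        if not (out.has_atom(i, "N") and out.has_atom(i, "CA")
                and out.has_atom(prev, "C")):
            warnings.warn(
                f"residue {i}: missing backbone heavy atoms, amide H not placed"
            )
            continue
        n = out.atom(i, "N").position
        ca = out.atom(i, "CA").position
        c_prev = out.atom(prev, "C").position
        u1 = c_prev - n
        u2 = ca - n
        nu1, nu2 = np.linalg.norm(u1), np.linalg.norm(u2)
        if nu1 < 1e-9 or nu2 < 1e-9:
            warnings.warn(f"residue {i}: degenerate backbone geometry, skipped")
            continue
        direction = -(u1 / nu1 + u2 / nu2)
        norm = np.linalg.norm(direction)
        if norm < 1e-6:  # collinear C(i-1), N, CA
            warnings.warn(f"residue {i}: collinear backbone geometry, skipped")
            continue
        h_pos = n + AMIDE_NH_LENGTH * direction / norm
        new_atoms.append(Atom(i, out.residue_names[i], "H", "H", h_pos))
    return ProteinStructure(out.atoms + new_atoms, model_id=out.model_id)


# ------------------------------------------------------------------ distances

def ca_distance(structure: ProteinStructure, i: int, j: int) -> float:
    """Euclidean Cα–Cα distance between residues *i* and *j* in Å."""
    try:
        a = structure.atom(i, "CA")
        b = structure.atom(j, "CA")
    except KeyError as exc:
        raise KeyError(f"missing CA atom: {exc}") from None
    return float(np.linalg.norm(a.position - b.position))


def h_distance(
    structure: ProteinStructure,
    a: tuple[int, str],
    b: tuple[int, str],
) -> float:
    """Euclidean distance between two hydrogen atoms in Å.

    Each of *a*, *b* is a ``(residue_index, atom_name)`` pair; both atoms
    must exist and be hydrogens.
    """
    atom_a = structure.atom(*a)
    atom_b = structure.atom(*b)
    for atom in (atom_a, atom_b):
        if not atom.is_hydrogen:
            raise ValueError(
                f"atom {atom.residue_index}/{atom.atom_name} is not a hydrogen"
            )
    return float(np.linalg.norm(atom_a.position - atom_b.position))
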