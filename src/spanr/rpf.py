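"""Recall, precision and F-measure over potential contacts.

These information-retrieval metrics compare two sets of amide-H / hydrogen
pairs: the "true" pairs, read off a proposed structure as every pair
closer than ``d_noe``, and the "identified" pairs, taken from the
potential contacts of the NOESY spectrum.  Recall is the fraction of true
pairs that the spectrum identifies; precision is the (optionally
distance-weighted) fraction of identified pairs that are true; the
F-measure combines the two as product over sum.
"""

from __future__ import annotations

from dataclasses import dataclass

from .contacts import ContactSet
from .structmodel import ProteinStructure, h_distance

__all__ = ["RpfParams", "RpfResult", "true_hh_pairs", "rpf_scores"]

#: an (anchor amide residue, partner residue, partner atom name) pair
HHPair = tuple[int, int, str]


@dataclass
class RpfParams:
    """d_noe : Å — H–H distance under which a pair counts as true (strict <).
    weight_mode : "uniform" or "inverse-sixth" precision weights.
    f_convention : "paper" gives F = RP/(R+P); "f1" the conventional
        2RP/(R+P)."""

    d_noe: float = 5.0
    weight_mode: str = "inverse-sixth"
    f_convention: str = "paper"

    def __post_init__(self):
        if self.d_noe <= 0:
            raise ValueError("d_noe must be positive")
        if self.weight_mode not in ("uniform", "inverse-sixth"):
            raise ValueError("weight_mode must be 'uniform' or 'inverse-sixth'")
        if self.f_convention not in ("paper", "f1"):
            raise ValueError("f_convention must be 'paper' or 'f1'")


@dataclass
class RpfResult:
    recall: float | None
    precision: float | None
    f_measure: float | None


def _f_measure(recall: float, precision: float, convention: str) -> float:
    if recall + precision == 0:
        return 0.0
    f = recall * precision / (recall + precision)
    return 2 * f if convention == "f1" else f


def true_hh_pairs(structure: ProteinStructure,
                  params: RpfParams | None = None) -> set[HHPair]:
    """All (backbone amide H, other hydrogen) pairs closer than ``d_noe``."""
    params = params or RpfParams()
    hydrogens = list(structure.hydrogens())
    if not hydrogens:
        raise ValueError("structure carries no hydrogens")
    pairs: set[HHPair] = set()
    for i in structure.residue_indices:
        if not structure.has_atom(i, "H"):
            continue
        for atom in hydrogens:
            if atom.residue_index == i and atom.atom_name == "H":
                continue
            d = h_distance(structure, (i, "H"),
                           (atom.residue_index, atom.atom_name))
            if d < params.d_noe:
                pairs.add((i, atom.residue_index, atom.atom_name))
    return pairs


def rpf_scores(contacts: ContactSet, structure: ProteinStructure,
               params: RpfParams | None = None) -> RpfResult:
    """Recall/precision/F of the spectrum's potential contacts vs *structure*.

    Identified pairs come from all potential contacts (not only long-range);
    the anchor amide paired with itself is excluded from both sets.  With an
    empty true set, recall (and F) are undefined.
    """
    params = params or RpfParams()
    true = true_hh_pairs(structure, params)
    identified: set[HHPair] = {
        (c.anchor_residue, c.partner_residue, c.partner_atom)
        for c in contacts.all_contacts()
        if not (c.partner_residue == c.anchor_residue and c.partner_atom == "H")
    }

    recall: float | None
    if not true:
        recall = None
    else:
        recall = len(identified & true) / len(true)

    def weight(pair: HHPair) -> float:
        if params.weight_mode == "uniform":
            return 1.0
        d = h_distance(structure, (pair[0], "H"), (pair[1], pair[2]))
        if d <= 0:
            return 1.0
        return min(1.0, (params.d_noe / d) ** 6)

    if not identified:
        precision = 0.0 if true else None
    else:
        total = sum(weight(p) for p in identified)
        hit = sum(weight(p) for p in identified & true)
        precision = hit / total if total > 0 else 0.0

    if recall is None or precision is None:
        f = None
    else:
        f = _f_measure(recall, precision, params.f_convention)
    return RpfResult(recall=recall, precision=precision, f_measure=f)
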