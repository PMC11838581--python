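"""Contact Score (CS) and Distance Score (DS).

CS rewards long-range interresidue contacts that are supported both by the
NOESY data (a potential contact with good shift agreement) and by the
proposed structure (Cα–Cα separation under ``eps_cs``).  Per residue pair
the best supporting weight is kept (capped at 1); the sum over long-range
pairs is normalized by the maximum possible number of such pairs, so
``0 ≤ CS ≤ 1`` by construction and high CS means good agreement.

DS is the fraction of long-range NOESY cross peaks that the proposed
structure cannot explain: each considered peak is reduced to its single
best candidate (smallest separation in the proposed structure); if even
that separation exceeds ``eps_d`` the peak is unexplained.  High DS means
poor agreement.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .contacts import ContactSet, long_range_view
from .structmodel import ProteinStructure, ca_distance, h_distance

__all__ = [
    "ScoringParams",
    "ContactScoreResult",
    "DistanceScoreResult",
    "max_long_range_pairs",
    "shift_weight",
    "contact_score",
    "distance_score",
    "product_map_export",
    "read_product_map",
]


@dataclass
class ScoringParams:
    """Thresholds for CS and DS.

    eps_cs : Å — Cα contact threshold for CS (grid-search optimum 12 Å).
    eps_d : Å — maximum Cα separation that can still explain a NOESY
        peak, for DS (grid-search optimum 10 Å).
    delta_measure : ppm — shift tolerance in the CS weight ramp.
    min_sep : minimum sequence separation for a long-range contact.
    contact_mode : "ca" measures Cα–Cα separations (default); "hh"
        measures amide-H-to-candidate-H separations instead.
    weight_mode : "linear" ramp or "gaussian" shift-agreement weight.
    """

    eps_cs: float = 12.0
    eps_d: float = 10.0
    delta_measure: float = 0.03
    min_sep: int = 5
    contact_mode: str = "ca"
    weight_mode: str = "linear"

    def __post_init__(self):
        if self.eps_cs <= 0 or self.eps_d <= 0 or self.delta_measure <= 0:
            raise ValueError("thresholds must be strictly positive")
        if self.contact_mode not in ("ca", "hh"):
            raise ValueError("contact_mode must be 'ca' or 'hh'")
        if self.weight_mode not in ("linear", "gaussian"):
            raise ValueError("weight_mode must be 'linear' or 'gaussian'")


@dataclass
class ContactScoreResult:
    cs: float
    product_map: np.ndarray  # symmetric n×n, per-pair scores in [0, 1]
    n_max_pairs: int


@dataclass
class DistanceScoreResult:
    ds: float | None  # None when no peak is considered (undefined)
    n_unexplained: int
    n_considered: int
    unexplained_peak_ids: list[int] = field(default_factory=list)


def max_long_range_pairs(n_resi: int, min_sep: int = 5) -> int:
    """Number of unordered residue pairs with sequence separation ≥ min_sep.

    For ``min_sep = 5`` this is ``(n² − 9n + 20)/2 = (n−4)(n−5)/2``; in
    general ``m(m+1)/2`` with ``m = n − min_sep``, clamped at 0.
    """
    if n_resi < 1:
        raise ValueError("n_resi must be >= 1")
    m = n_resi - min_sep
    return m * (m + 1) // 2 if m > 0 else 0


def shift_weight(delta_pc: float, delta_measure: float,
                 mode: str = "linear") -> float:
    """Shift-agreement weight in [0, 1]: 1 at δPC = 0, 0 at/after δmeasure
    (linear mode) or a Gaussian decay exp(−(δPC/δmeasure)²)."""
    if delta_measure <= 0:
        raise ValueError("delta_measure must be positive")
    if delta_pc < 0:
        raise ValueError("delta_pc must be non-negative")
    if mode == "linear":
        return max(0.0, 1.0 - delta_pc / delta_measure)
    if mode == "gaussian":
        return float(np.exp(-((delta_pc / delta_measure) ** 2)))
    raise ValueError(f"unknown weight mode {mode!r}")


def _pair_distance(structure: ProteinStructure, contact, mode: str) -> float:
    if mode == "ca":
        return ca_distance(structure, contact.anchor_residue,
                           contact.partner_residue)
    return h_distance(structure,
                      (contact.anchor_residue, "H"),
                      (contact.partner_residue, contact.partner_atom))


def _check_residues(contacts: ContactSet, structure: ProteinStructure) -> None:
    present = set(structure.residue_indices)
    missing = sorted({
        r for c in contacts.all_contacts()
        for r in (c.anchor_residue, c.partner_residue)
        if r not in present
    })
    if missing:
        raise KeyError(
            f"residues referenced by contacts but absent from the proposed "
            f"structure: {missing}"
        )


def contact_score(
    contacts: ContactSet,
    proposed: ProteinStructure,
    params: ScoringParams | None = None,
) -> ContactScoreResult:
    """Compute CS of *proposed* against the potential contacts.

    Every long-range potential contact whose residue pair is in spatial
    contact in the proposed structure (separation < ``eps_cs``) contributes
    a shift-agreement weight; per pair the maximum weight is kept and the
    capped per-pair scores are summed and normalized by
    :func:`max_long_range_pairs`.
    """
    params = params or ScoringParams()
    lv = long_range_view(contacts, params.min_sep)
    _check_residues(lv, proposed)
    n = max([contacts.n_resi] + [max(c.anchor_residue, c.partner_residue)
                                 for c in lv.all_contacts()] or [contacts.n_resi])
    pmap = np.zeros((n, n))
    for c in lv.all_contacts():
        d = _pair_distance(proposed, c, params.contact_mode)
        if d < params.eps_cs:
            w = min(1.0, shift_weight(c.delta_pc, params.delta_measure,
                                      params.weight_mode))
            i, j = c.anchor_residue - 1, c.partner_residue - 1
            if w > pmap[i, j]:
                pmap[i, j] = pmap[j, i] = w
    n_max = max_long_range_pairs(contacts.n_resi, params.min_sep)
    total = sum(
        pmap[i, j]
        for i in range(n) for j in range(i + params.min_sep, n)
    )
    cs = total / n_max if n_max > 0 else 0.0
    return ContactScoreResult(cs=float(cs), product_map=pmap, n_max_pairs=n_max)


def distance_score(
    contacts: ContactSet,
    proposed: ProteinStructure,
    params: ScoringParams | None = None,
) -> DistanceScoreResult:
    """Compute DS of *proposed* against the potential contacts.

    Considered peaks are those with at least one long-range candidate and
    no short-range candidate (a short-range explanation is always
    geometrically plausible and says nothing about the fold).  Each is
    reduced to the candidate minimizing the separation in the proposed
    structure; if that minimum exceeds ``eps_d`` the peak is unexplained.
    With zero considered peaks DS is undefined (``None``), never 0.
    """
    params = params or ScoringParams()
    lv = long_range_view(contacts, params.min_sep)
    _check_residues(lv, proposed)
    flags = lv.had_short_range or {}
    unexplained: list[int] = []
    n_considered = 0
    for peak_id, cands in lv.by_peak.items():
        if flags.get(peak_id, False):
            continue
        n_considered += 1
        best = min(_pair_distance(proposed, c, params.contact_mode)
                   for c in cands)
        if best > params.eps_d:
            unexplained.append(peak_id)
    if n_considered == 0:
        return DistanceScoreResult(ds=None, n_unexplained=0, n_considered=0)
    return DistanceScoreResult(
        ds=len(unexplained) / n_considered,
        n_unexplained=len(unexplained),
        n_considered=n_considered,
        unexplained_peak_ids=unexplained,
    )


def product_map_export(result: ContactScoreResult, path: str | Path) -> None:
    """Write the per-pair score matrix as a TSV (one row per residue)."""
    np.savetxt(path, result.product_map, delimiter="\t", fmt="%.6f")


def read_product_map(path: str | Path) -> np.ndarray:
    m = np.loadtxt(path, delimiter="\t", ndmin=2)
    return m
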