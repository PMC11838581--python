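"""Potential contacts: candidate assignments of NOESY peaks to hydrogens.

A potential contact pairs a NOESY cross peak (anchored to one residue's
amide) with every assigned hydrogen whose ¹H shift lies strictly within
``delta_shift`` ppm of the peak's indirect ¹H position.  These candidate
lists — not resolved assignments — are the shared substrate of the
contact score, the distance score and RPF.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from .shifts_io import PeakList, ShiftTable

__all__ = [
    "ToleranceParams",
    "PotentialContact",
    "ContactSet",
    "find_potential_contacts",
    "long_range_view",
    "sufficiency_check",
]


@dataclass
class ToleranceParams:
    """Shift-matching tolerances, all in ppm.

    delta_shift : ¹H window for candidate assignments (strict ``<``).
    hn_tol, n_tol : ¹H / ¹⁵N windows used to anchor an experimental peak
        to a residue when no anchor column is present.
    """

    delta_shift: float = 0.03
    hn_tol: float = 0.03
    n_tol: float = 0.3

    def __post_init__(self):
        if min(self.delta_shift, self.hn_tol, self.n_tol) <= 0:
            raise ValueError("tolerances must be strictly positive")


@dataclass(frozen=True)
class PotentialContact:
    peak_id: int
    anchor_residue: int
    partner_residue: int
    partner_atom: str
    delta_pc: float  # ppm, |peak δH − assigned δH|


@dataclass
class ContactSet:
    """Per-peak candidate lists plus bookkeeping for sufficiency/DS.

    ``had_short_range`` records, per retained peak, whether a short-range
    candidate existed before long-range filtering (filled by
    :func:`long_range_view`; ``None`` before filtering).
    """

    by_peak: dict[int, list[PotentialContact]]
    n_resi: int
    had_short_range: dict[int, bool] | None = None
    n_dropped_peaks: int = 0

    def all_contacts(self) -> list[PotentialContact]:
        return [c for lst in self.by_peak.values() for c in lst]

    def residues_covered(self) -> set[int]:
        covered: set[int] = set()
        for c in self.all_contacts():
            covered.add(c.anchor_residue)
            covered.add(c.partner_residue)
        return covered


def find_potential_contacts(
    peaks: PeakList,
    shifts: ShiftTable,
    tol: ToleranceParams | None = None,
    n_resi: int | None = None,
) -> ContactSet:
    """Build per-peak potential-contact lists.

    Each peak is anchored to a residue: its ``anchor_residue`` when known
    (simulated peaks), otherwise the unique assigned amide whose (δHN, δN)
    both match within ``(hn_tol, n_tol)``; peaks matching zero or several
    amides are dropped with a warning.  Candidates are all assigned
    hydrogens with ``|δH − δH_indirect| < delta_shift`` (strict).
    """
    tol = tol or ToleranceParams()
    if len(peaks) == 0:
        raise ValueError("empty peak list")
    if len(shifts) == 0:
        raise ValueError("empty shift table")
    if n_resi is None:
        n_resi = max(e.residue_index for e in shifts)
    amides = shifts.amide_pairs()
    hydrogens = shifts.hydrogens()

    by_peak: dict[int, list[PotentialContact]] = {}
    dropped = 0
    for peak_id, peak in enumerate(peaks):
        anchor = peak.anchor_residue
        if anchor is None:
            matches = [
                i for i, (hn, n) in amides.items()
                if abs(hn - peak.hn_shift) < tol.hn_tol
                and abs(n - peak.n_shift) < tol.n_tol
            ]
            if len(matches) != 1:
                dropped += 1
                continue
            anchor = matches[0]
        candidates = [
            PotentialContact(peak_id, anchor, e.residue_index, e.atom_name,
                             abs(e.shift - peak.h_indirect))
            for e in hydrogens
            if abs(e.shift - peak.h_indirect) < tol.delta_shift
        ]
        by_peak[peak_id] = candidates
    if dropped:
        warnings.warn(f"{dropped} peak(s) could not be anchored to a unique "
                      "amide and were dropped")
    return ContactSet(by_peak=by_peak, n_resi=n_resi, n_dropped_peaks=dropped)


def long_range_view(contacts: ContactSet, min_sep: int = 5) -> ContactSet:
    """Restrict to long-range candidates (sequence separation ≥ *min_sep*).

    Peaks left with no candidate disappear from the view.  Per retained
    peak, a flag records whether any short-range candidate existed before
    filtering (ORed with a pre-existing flag, so the operation is
    idempotent).
    """
    by_peak: dict[int, list[PotentialContact]] = {}
    flags: dict[int, bool] = {}
    prior = contacts.had_short_range or {}
    for peak_id, cands in contacts.by_peak.items():
        long_range = [c for c in cands
                      if abs(c.anchor_residue - c.partner_residue) >= min_sep]
        if not long_range:
            continue
        short = len(long_range) < len(cands)
        by_peak[peak_id] = long_range
        flags[peak_id] = bool(prior.get(peak_id, False) or short)
    return ContactSet(by_peak=by_peak, n_resi=contacts.n_resi,
                      had_short_range=flags,
                      n_dropped_peaks=contacts.n_dropped_peaks)


def sufficiency_check(contacts: ContactSet) -> tuple[bool, float]:
    """Data-sufficiency filter: at least half the residues must generate
    a potential contact (as anchor or partner).

    Returns ``(passed, coverage)``; coverage exactly 0.5 passes.
    """
    if contacts.n_resi == 0:
        raise ValueError("n_resi is zero")
    coverage = len(contacts.residues_covered()) / contacts.n_resi
    return coverage >= 0.5, coverage
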