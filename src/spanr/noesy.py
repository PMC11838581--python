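"""Simulation of a ¹⁵N-edited NOESY peak list from structure + shifts.

The simulator loops over backbone amide hydrogens as "base" hydrogens.
For every other assigned hydrogen it emits a cross peak with probability
``min(1, (r0/r)^6)`` — saturating at short range and decaying with the
NOE's r⁻⁶ intensity dependence — truncated beyond ``r_max``, the practical
observability limit.  Each base amide also always yields its diagonal peak.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structmodel import ProteinStructure
from .shifts_io import Peak, PeakList, ShiftTable

__all__ = ["NoesySimParams", "peak_probability", "simulate_noesy"]


@dataclass
class NoesySimParams:
    """Acceptance-probability parameters for the NOESY simulator.

    r0 : Å — distance at and below which a cross peak is certain.
    r_max : Å — hard cutoff; no peak beyond this separation.
    seed : RNG seed for the Bernoulli draws.
    jitter : ppm — optional Gaussian noise added to emitted shifts
        (0 by default; used only for robustness testing).
    """

    r0: float = 3.0
    r_max: float = 6.0
    seed: int = 0
    jitter: float = 0.0

    def __post_init__(self):
        if not (0 < self.r0 <= self.r_max):
            raise ValueError("require 0 < r0 <= r_max")
        if self.jitter < 0:
            raise ValueError("jitter must be non-negative")


def peak_probability(r: float, params: NoesySimParams) -> float:
    """Probability that a hydrogen pair at distance *r* (Å) yields a peak."""
    if r <= 0:
        raise ValueError("distance must be positive")
    if r > params.r_max:
        return 0.0
    return min(1.0, (params.r0 / r) ** 6)


def simulate_noesy(
    structure: ProteinStructure,
    shifts: ShiftTable,
    params: NoesySimParams | None = None,
) -> PeakList:
    """Simulate the ¹⁵N-edited NOESY peak list for *structure*.

    Base amides are residues whose structure has an ``H`` atom and whose
    shift table assigns both that ``H`` and the backbone ``N``.  For each
    base, every other assigned hydrogen present in the structure is tested
    with :func:`peak_probability`; accepted pairs emit a cross peak
    ``(δH_other, δN_base, δHN_base)`` anchored to the base residue.  The
    diagonal peak ``(δHN, δN, δHN)`` is always emitted.  Output is
    deterministic for a fixed seed.
    """
    params = params or NoesySimParams()
    rng = np.random.default_rng(params.seed)
    amides = shifts.amide_pairs()
    bases = [i for i in structure.residue_indices
             if i in amides and structure.has_atom(i, "H")]
    if not bases:
        raise ValueError("no base amides with assigned (HN, N) shifts")

    # all assigned hydrogens present in the structure, in deterministic order
    assigned_h = []
    for atom in structure.hydrogens():
        shift = shifts.get(atom.residue_index, atom.atom_name)
        if shift is not None:
            assigned_h.append((atom.residue_index, atom.atom_name, shift,
                               atom.position))
    assigned_h.sort(key=lambda t: (t[0], t[1]))

    def _jit() -> float:
        return float(rng.normal(0.0, params.jitter)) if params.jitter > 0 else 0.0

    peaks: list[Peak] = []
    for i in bases:
        hn_shift, n_shift = amides[i]
        base_pos = structure.atom(i, "H").position
        peaks.append(Peak(hn_shift + _jit(), n_shift + _jit(),
                          hn_shift + _jit(), anchor_residue=i))
        for (j, name, shift, pos) in assigned_h:
            if j == i and name == "H":
                continue
            r = float(np.linalg.norm(pos - base_pos))
            p = peak_probability(r, params)
            if p > 0 and rng.random() < p:
                peaks.append(Peak(shift + _jit(), n_shift + _jit(),
                                  hn_shift + _jit(), anchor_residue=i))
    return PeakList(peaks, source="simulated")
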