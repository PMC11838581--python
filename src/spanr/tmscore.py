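"""Rigid superposition (Kabsch) and the TM-score.

The TM-score measures length-normalized structural similarity between two
conformations of the same sequence,

    TM = max over superpositions of (1/L) Σ_i 1 / (1 + (d_i/d0)²),

with ``d0 = 1.24 (L − 15)^{1/3} − 1.8`` (floored at 0.5 Å) and L the
reference length.  The maximization follows the standard iterative
fragment search: seed superpositions on fragments of length L, L/2, L/4,
… (≥ 4 residues), then repeatedly re-superpose on the residues currently
within a distance cutoff until the selection stabilizes, keeping the best
score seen.  Scores above 0.5 conventionally indicate the same fold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .structmodel import ProteinStructure

__all__ = ["Superposition", "TMResult", "kabsch_superpose", "tm_score", "tm_d0"]


@dataclass
class Superposition:
    rotation: np.ndarray   # 3×3, proper (det = +1)
    translation: np.ndarray  # 3-vector, Å
    rmsd: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def kabsch_superpose(coords_a: np.ndarray, coords_b: np.ndarray) -> Superposition:
    """Least-squares rigid superposition of *coords_b* onto *coords_a*.

    Returns the proper rotation R and translation t minimizing
    ``|R·b + t − a|²`` (no reflection).  Degenerate (e.g. collinear) point
    sets still yield a valid rmsd but the rotation may be non-unique.
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValueError("coordinate arrays must have matching n×3 shapes")
    if a.shape[0] < 3:
        raise ValueError("need at least 3 points to superpose")
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    h = (b - cb).T @ (a - ca)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = ca - rot @ cb
    moved = b @ rot.T + trans
    rmsd = float(np.sqrt(np.mean(np.sum((moved - a) ** 2, axis=1))))
    return Superposition(rotation=rot, translation=trans, rmsd=rmsd)


@dataclass
class TMResult:
    tm: float
    aligned_length: int
    d0: float


def tm_d0(l_ref: int) -> float:
    """The TM-score distance scale d0 for a reference of *l_ref* residues."""
    return max(0.5, 1.24 * np.cbrt(l_ref - 15.0) - 1.8)


def _tm_sum(ref: np.ndarray, moved: np.ndarray, d0: float) -> tuple[float, np.ndarray]:
    d = np.linalg.norm(moved - ref, axis=1)
    return float(np.sum(1.0 / (1.0 + (d / d0) ** 2))), d


def tm_score(reference: ProteinStructure, model: ProteinStructure) -> TMResult:
    """TM-score of *model* against *reference* (same sequence length).

    Normalization uses the reference length.  Residues missing a CA in
    either structure are dropped pairwise with a warning.  No sequence
    alignment is attempted: residue indices must correspond.
    """
    if reference.n_resi != model.n_resi:
        raise ValueError(
            f"length mismatch: reference has {reference.n_resi} residues, "
            f"model has {model.n_resi}"
        )
    common = [i for i in reference.residue_indices
              if model.has_atom(i, "CA") and reference.has_atom(i, "CA")]
    if len(common) < len(reference.residue_indices):
        warnings.warn("residues missing CA were dropped pairwise")
    if len(common) < 4:
        raise ValueError("fewer than 4 residues with CA in common")
    ref = np.array([reference.atom(i, "CA").position for i in common])
    mod = np.array([model.atom(i, "CA").position for i in common])
    l_norm = reference.n_resi
    d0 = tm_d0(l_norm)
    n = len(common)

    fragment_lengths = []
    l = n
    while l >= 4:
        fragment_lengths.append(l)
        l //= 2

    best = 0.0
    for frag in fragment_lengths:
        stride = max(1, frag // 2)
        for start in range(0, n - frag + 1, stride):
            subset = np.arange(start, start + frag)
            for _ in range(20):
                sup = kabsch_superpose(ref[subset], mod[subset])
                score, d = _tm_sum(ref, sup.apply(mod), d0)
                best = max(best, score / l_norm)
                d_cut = max(d0, 3.0)
                new = np.flatnonzero(d < d_cut)
                while len(new) < 3:
                    d_cut += 0.5
                    new = np.flatnonzero(d < d_cut)
                if len(new) == len(subset) and np.array_equal(new, subset):
                    break
                subset = new
    return TMResult(tm=float(best), aligned_length=n, d0=float(d0))
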