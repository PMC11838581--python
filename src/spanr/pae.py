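"""AlphaFold predicted-aligned-error (PAE) matrices and their summaries.

The PAE is an n×n matrix of expected positional error (Å) of residue i
when the prediction is aligned on residue j — AlphaFold's own uncertainty
estimate.  Two public JSON dialects exist: nested lists under
``predicted_aligned_error`` and the older flat ``residue1``/``residue2``/
``distance`` triplet; both are accepted.  For classification the matrix is
reduced to two scalars: the mean off-diagonal PAE and the mean over
long-range pairs.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = ["PaeMatrix", "read_pae", "pae_features"]


@dataclass
class PaeMatrix:
    values: np.ndarray  # n×n, Å

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("PAE matrix must be square")
        if np.any(self.values < 0) or not np.all(np.isfinite(self.values)):
            raise ValueError("PAE entries must be finite and non-negative")

    @property
    def n(self) -> int:
        return self.values.shape[0]


def read_pae(path: str | Path) -> PaeMatrix:
    """Read an AlphaFold DB PAE JSON file (either public dialect)."""
    data = json.loads(Path(path).read_text())
    if isinstance(data, list):
        if not data:
            raise ValueError("empty PAE JSON")
        data = data[0]
    if "predicted_aligned_error" in data:
        rows = data["predicted_aligned_error"]
        lengths = {len(r) for r in rows}
        if len(lengths) != 1 or lengths != {len(rows)}:
            raise ValueError("ragged predicted_aligned_error matrix")
        return PaeMatrix(np.array(rows, dtype=float))
    if {"residue1", "residue2", "distance"} <= set(data):
        r1 = np.asarray(data["residue1"], dtype=int)
        r2 = np.asarray(data["residue2"], dtype=int)
        dist = np.asarray(data["distance"], dtype=float)
        if not (len(r1) == len(r2) == len(dist)):
            raise ValueError("flat-triplet arrays have unequal lengths")
        n = int(max(r1.max(), r2.max()))
        if len(dist) != n * n:
            raise ValueError("flat-triplet dialect does not cover a full matrix")
        m = np.zeros((n, n))
        m[r1 - 1, r2 - 1] = dist
        return PaeMatrix(m)
    raise ValueError("unrecognized PAE JSON layout")


def pae_features(pae: PaeMatrix, min_sep: int = 5) -> tuple[float, float]:
    """Summarize a PAE matrix as (mean_pae, long_range_mean_pae), in Å.

    The matrix is symmetrized first.  The global mean runs over all
    off-diagonal entries; the long-range mean over pairs with
    ``|i − j| ≥ min_sep`` (NaN when the chain is too short to have any).
    """
    m = (pae.values + pae.values.T) / 2.0
    n = pae.n
    idx = np.arange(n)
    sep = np.abs(idx[:, None] - idx[None, :])
    off = sep > 0
    mean_pae = float(m[off].mean()) if off.any() else float("nan")
    lr = sep >= min_sep
    long_range = float(m[lr].mean()) if lr.any() else float("nan")
    return mean_pae, long_range
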