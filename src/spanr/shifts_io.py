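"""Chemical-shift tables (NMR-STAR) and NOESY peak lists (TSV).

The shift reader consumes only the ``_Atom_chem_shift`` loop of an
NMR-STAR v3 file — the most reliably present and most easily parsed part
of a BMRB entry.  Peak lists use a minimal tab-separated format of this
package's own definition, documented in the README: one peak per row with
columns ``h_indirect`` (¹H of the NOE partner), ``n`` (¹⁵N of the anchor
amide), ``hn`` (¹H of the anchor amide) and an optional ``anchor_residue``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

__all__ = [
    "ShiftEntry",
    "ShiftTable",
    "Peak",
    "PeakList",
    "read_shift_table",
    "write_shift_table",
    "read_peaks",
    "write_peaks",
]


@dataclass(frozen=True)
class ShiftEntry:
    residue_index: int
    residue_name: str
    atom_name: str
    element: str
    shift: float  # ppm


class ShiftTable:
    """Assigned chemical shifts keyed by ``(residue_index, atom_name)``."""

    def __init__(self, entries: list[ShiftEntry] | None = None):
        self.entries: dict[tuple[int, str], ShiftEntry] = {}
        for e in entries or []:
            self.add(e, warn_duplicate=False)

    def add(self, entry: ShiftEntry, warn_duplicate: bool = True) -> None:
        if not math.isfinite(entry.shift):
            raise ValueError(f"non-finite shift for {entry}")
        if entry.atom_name.startswith("H") and entry.element.upper() != "H":
            raise ValueError(f"H-named atom with element {entry.element}: {entry}")
        key = (entry.residue_index, entry.atom_name)
        if key in self.entries and warn_duplicate:
            warnings.warn(f"duplicate shift assignment for {key}; keeping the last")
        self.entries[key] = entry

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[ShiftEntry]:
        return iter(self.entries.values())

    def get(self, residue_index: int, atom_name: str) -> float | None:
        e = self.entries.get((residue_index, atom_name))
        return None if e is None else e.shift

    def hydrogens(self) -> list[ShiftEntry]:
        return [e for e in self if e.element.upper() == "H"]

    def amide_pairs(self) -> dict[int, tuple[float, float]]:
        """Residues with both amide ``H`` and ``N`` assigned → (δHN, δN)."""
        out: dict[int, tuple[float, float]] = {}
        for (i, name), e in self.entries.items():
            if name != "H":
                continue
            n = self.get(i, "N")
            if n is not None:
                out[i] = (e.shift, n)
        return out


# ------------------------------------------------------------- NMR-STAR read

def _star_tokens(text: str) -> Iterator[str]:
    """Tokenize STAR content: whitespace-separated, minimal quote handling."""
    for line in text.splitlines():
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        i = 0
        while i < len(stripped):
            ch = stripped[i]
            if ch in "'\"":
                end = stripped.find(ch, i + 1)
                if end == -1:
                    end = len(stripped)
                yield stripped[i + 1:end]
                i = end + 1
            elif ch.isspace():
                i += 1
            else:
                j = i
                while j < len(stripped) and not stripped[j].isspace():
                    j += 1
                yield stripped[i:j]
                i = j


def read_shift_table(path: str | Path) -> ShiftTable:
    """Read assigned shifts from the ``_Atom_chem_shift`` loop of a STAR file.

    Residue indices are taken from the author sequence numbering column
    (``Auth_seq_ID``) when it is populated, falling back to ``Seq_ID`` /
    ``Comp_index_ID``.  Duplicate rows for the same atom keep the last value
    with a warning.
    """
    text = Path(path).read_text()
    tokens = list(_star_tokens(text))
    table = ShiftTable()
    k = 0
    found_loop = False
    while k < len(tokens):
        if tokens[k] != "loop_":
            k += 1
            continue
        k += 1
        tags: list[str] = []
        while k < len(tokens) and tokens[k].startswith("_"):
            tags.append(tokens[k])
            k += 1
        if not tags or not tags[0].startswith("_Atom_chem_shift."):
            continue
        found_loop = True
        cols = {t.split(".", 1)[1]: idx for idx, t in enumerate(tags)}
        values: list[str] = []
        while k < len(tokens) and tokens[k] != "stop_" and tokens[k] != "loop_":
            values.append(tokens[k])
            k += 1
        ncol = len(tags)
        if len(values) % ncol:
            raise ValueError(
                f"_Atom_chem_shift loop has {len(values)} values for {ncol} tags"
            )
        seq_col = None
        for candidate in ("Auth_seq_ID", "Seq_ID", "Comp_index_ID"):
            if candidate in cols:
                seq_col = cols[candidate]
                break
        if seq_col is None:
            raise ValueError("no sequence-index column in _Atom_chem_shift loop")
        for r in range(0, len(values), ncol):
            row = values[r:r + ncol]
            seq_val = row[seq_col]
            if seq_val in (".", "?") and "Seq_ID" in cols:
                seq_val = row[cols["Seq_ID"]]
            try:
                residue_index = int(seq_val)
            except ValueError:
                raise ValueError(f"non-integer residue index {seq_val!r}") from None
            try:
                shift = float(row[cols["Val"]])
            except (KeyError, ValueError):
                raise ValueError(
                    f"missing or non-numeric shift value in row {row}"
                ) from None
            atom_name = row[cols["Atom_ID"]]
            atom_name = "H" if atom_name == "HN" else atom_name
            element = row[cols["Atom_type"]] if "Atom_type" in cols else (
                "H" if atom_name.startswith("H") else atom_name[0]
            )
            residue_name = row[cols["Comp_ID"]] if "Comp_ID" in cols else "UNK"
            table.add(ShiftEntry(residue_index, residue_name, atom_name,
                                 element, shift))
    if not found_loop:
        raise ValueError(f"no _Atom_chem_shift loop found in {path}")
    return table


def write_shift_table(table: ShiftTable, path: str | Path,
                      entry_id: str = "synthetic") -> None:
    """Write a minimal NMR-STAR file containing one assigned-shift loop."""
    lines = [
        f"data_{entry_id}",
        "",
        "save_assigned_chemical_shifts",
        "   _Assigned_chem_shift_list.Sf_category  assigned_chemical_shifts",
        "   loop_",
        "      _Atom_chem_shift.ID",
        "      _Atom_chem_shift.Auth_seq_ID",
        "      _Atom_chem_shift.Comp_ID",
        "      _Atom_chem_shift.Atom_ID",
        "      _Atom_chem_shift.Atom_type",
        "      _Atom_chem_shift.Val",
    ]
    for n, e in enumerate(sorted(table, key=lambda e: (e.residue_index, e.atom_name)), 1):
        lines.append(
            f"      {n} {e.residue_index} {e.residue_name} {e.atom_name} "
            f"{e.element} {e.shift:.4f}"
        )
    lines += ["   stop_", "save_", ""]
    Path(path).write_text("\n".join(lines))


# ------------------------------------------------------------------- peaks

@dataclass(frozen=True)
class Peak:
    """One 3D ¹⁵N-edited NOESY cross peak, identified by three shifts (ppm)."""

    h_indirect: float
    n_shift: float
    hn_shift: float
    anchor_residue: int | None = None

    def __post_init__(self):
        for v in (self.h_indirect, self.n_shift, self.hn_shift):
            if not math.isfinite(v):
                raise ValueError("peak shifts must be finite")


@dataclass
class PeakList:
    peaks: list[Peak] = field(default_factory=list)
    source: str = "simulated"  # simulated | experimental

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self) -> Iterator[Peak]:
        return iter(self.peaks)


PEAK_HEADER = "# h_indirect\tn\thn\tanchor_residue"


def write_peaks(peaks: PeakList, path: str | Path) -> None:
    lines = [PEAK_HEADER]
    for p in peaks:
        anchor = "" if p.anchor_residue is None else str(p.anchor_residue)
        lines.append(f"{p.h_indirect:.4f}\t{p.n_shift:.4f}\t{p.hn_shift:.4f}\t{anchor}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_peaks(path: str | Path, source: str = "experimental") -> PeakList:
    peaks: list[Peak] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t") if "\t" in line else line.split()
        if len(fields) not in (3, 4):
            raise ValueError(f"line {lineno}: expected 3 or 4 columns, got {len(fields)}")
        try:
            h, n, hn = (float(v) for v in fields[:3])
        except ValueError:
            raise ValueError(f"line {lineno}: non-numeric shift value") from None
        anchor: int | None = None
        if len(fields) == 4 and fields[3] != "":
            anchor = int(fields[3])
        peaks.append(Peak(h, n, hn, anchor))
    if not peaks:
        warnings.warn(f"empty peak list read from {path}")
    return PeakList(peaks, source=source)
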