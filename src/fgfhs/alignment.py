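"""Alignment-side mutation design: conservation classes and the basic-residue
support rule.

The design procedure scans a multiple sequence alignment of FGF paralogs for
columns where the target protein (FGF1) carries a non-basic residue while at
least ``min_support`` other paralogs carry lysine or arginine — positions
where the paralog family "votes" for a basic residue that FGF1 lacks, and
hence candidate sites for electrostatic heparan-sulfate affinity gains.

Columns are additionally classified the way alignment figures shade them:
``identical_conserved`` when one residue repeats at least three times,
``class_conserved`` when three residues that are not all identical share one
physicochemical class, and ``unconserved`` otherwise. Gaps never count.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO

GAP_CHARS = frozenset("-.")

#: Residues treated as basic by the support rule. Histidine is deliberately
#: excluded: the rule names lysine and arginine only.
BASIC_RESIDUES = frozenset("KR")

#: Standard four-class physicochemical partition used for the grey
#: (class-conserved) shading; configurable per call.
AA_CLASSES: dict[str, frozenset[str]] = {
    "positive": frozenset("KRH"),
    "negative": frozenset("DE"),
    "polar": frozenset("STNQCYW"),
    "nonpolar": frozenset("AVLIMFPG"),
}


@dataclass(frozen=True)
class Alignment:
    """A gapped protein multiple sequence alignment."""

    ids: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("alignment is empty")
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in length")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("alignment ids must be unique")
        width = len(self.rows[0])
        if any(len(r) != width for r in self.rows):
            raise ValueError("alignment rows differ in length")

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])

    def row(self, row_id: str) -> str:
        try:
            return self.rows[self.ids.index(row_id)]
        except ValueError:
            raise KeyError(f"no alignment row with id {row_id!r}") from None

    def column(self, j: int) -> tuple[str, ...]:
        return tuple(r[j] for r in self.rows)

    def ungapped(self, row_id: str) -> str:
        return "".join(c for c in self.row(row_id) if c not in GAP_CHARS)

    def column_to_ungapped_index(self, row_id: str, j: int) -> int:
        """0-based index in the ungapped target of alignment column ``j``.

        Raises ``ValueError`` when the target row is gapped at ``j``.
        """
        row = self.row(row_id)
        if row[j] in GAP_CHARS:
            raise ValueError(f"row {row_id!r} is gapped at column {j}")
        return sum(1 for c in row[:j] if c not in GAP_CHARS)


def read_alignment(path: "str | Path") -> Alignment:
    """Read an aligned FASTA file."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return Alignment(tuple(r.id for r in records),
                     tuple(str(r.seq).upper() for r in records))


def write_alignment(alignment: Alignment, path: "str | Path") -> None:
    with open(path, "w") as fh:
        for rid, row in zip(alignment.ids, alignment.rows):
            fh.write(f">{rid}\n{row}\n")


@dataclass(frozen=True)
class ColumnClass:
    """Conservation call for one alignment column."""

    column: int  # 0-based
    conservation: str  # identical_conserved | class_conserved | unconserved
    basic_support: int  # count of K/R among non-target rows (0 if no target)
    target_residue: str | None = None
    residues: tuple[str, ...] = field(default_factory=tuple)


def _classify_residues(residues: Iterable[str],
                       classes: dict[str, frozenset[str]]) -> str:
    counts = Counter(r for r in residues if r not in GAP_CHARS)
    if not counts:
        return "unconserved"
    if max(counts.values()) >= 3:
        return "identical_conserved"
    for members in classes.values():
        in_class = [r for r in counts.elements() if r in members]
        if len(in_class) >= 3 and len(set(in_class)) > 1:
            return "class_conserved"
    return "unconserved"


def classify_columns(alignment: Alignment,
                     classes: dict[str, frozenset[str]] | None = None,
                     target_id: str | None = None) -> list[ColumnClass]:
    """Assign a conservation class to every alignment column.

    When ``target_id`` is given, ``basic_support`` counts K/R among the
    other rows and ``target_residue`` records the target's residue.
    """
    classes = classes if classes is not None else AA_CLASSES
    target_idx = alignment.ids.index(target_id) if target_id is not None else None
    out: list[ColumnClass] = []
    for j in range(alignment.n_columns):
        col = alignment.column(j)
        support = sum(1 for i, c in enumerate(col)
                      if i != target_idx and c in BASIC_RESIDUES)
        out.append(ColumnClass(
            column=j,
            conservation=_classify_residues(col, classes),
            basic_support=support if target_idx is not None else
            sum(1 for c in col if c in BASIC_RESIDUES),
            target_residue=col[target_idx] if target_idx is not None else None,
            residues=col,
        ))
    return out


def find_candidate_columns(alignment: Alignment, target_id: str,
                           min_support: int = 3) -> list[ColumnClass]:
    """Columns satisfying the basic-residue support rule.

    A column qualifies when the target row holds a residue that is neither
    basic nor a gap and at least ``min_support`` of the other rows carry K
    or R. The target's own residue never counts toward the support tally,
    and gaps in other rows simply contribute nothing (the absolute
    threshold is kept).
    """
    if target_id not in alignment.ids:
        raise KeyError(f"no alignment row with id {target_id!r}")
    if min_support < 1:
        raise ValueError("min_support must be >= 1")
    kept = []
    for cc in classify_columns(alignment, target_id=target_id):
        t = cc.target_residue
        if t in GAP_CHARS or t in BASIC_RESIDUES:
            continue
        if cc.basic_support >= min_support:
            kept.append(cc)
    return kept
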