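"""Kano-model requirement classification from questionnaire frequencies.

The Kano model sorts product attributes into six categories from paired
functional/dysfunctional questionnaire answers: must-be/basic (M), one-
dimensional/expected (O), attractive (A), indifferent (I), questionable (Q)
and reverse (R).  Given a table of per-attribute response frequencies over
those categories, each attribute is assigned its modal category; ties break
by the conventional priority M > O > A > I > R > Q (a requirement is never
downgraded past a category that would demand it).  The classification is
invariant under rescaling a row, so counts and percentages behave alike.

A transcribed frequency table from a wheelchair user-needs survey ships as a
packaged fixture (``load_wheelchair_survey``) with the surveyors' published
per-attribute evaluations for cross-checking.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

#: Kano response categories, in the table's column order.
CATEGORIES = ("M", "O", "A", "I", "Q", "R")

#: Tie-break priority, strongest requirement first.
PRIORITY = ("M", "O", "A", "I", "R", "Q")


@dataclass(frozen=True)
class KanoRow:
    attribute: str
    counts: tuple[int, ...]  # aligned with CATEGORIES
    printed_result: str | None = None


@dataclass(frozen=True)
class KanoTable:
    """Attribute x category frequency table, optionally with published results."""

    rows: tuple[KanoRow, ...]

    @classmethod
    def from_csv(cls, path: str | Path) -> "KanoTable":
        """Read ``attribute,M,O,A,I,Q,R[,printed_result]`` CSV."""
        df = pd.read_csv(path)
        required = ["attribute", *CATEGORIES]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"CSV is missing columns {missing}")
        rows = []
        for _, r in df.iterrows():
            printed = r.get("printed_result")
            rows.append(
                KanoRow(
                    attribute=str(r["attribute"]),
                    counts=tuple(int(r[c]) for c in CATEGORIES),
                    printed_result=None if pd.isna(printed) else str(printed),
                )
            )
        return cls(tuple(rows))


def classify_attribute(counts) -> str:
    """Modal Kano category for one attribute's response counts.

    ``counts`` is a mapping category -> count or a 6-sequence in M,O,A,I,Q,R
    order.  Ties resolve by the documented priority; all-zero counts are
    rejected.
    """
    if isinstance(counts, dict):
        vals = {c: int(counts.get(c, 0)) for c in CATEGORIES}
    else:
        seq = list(counts)
        if len(seq) != len(CATEGORIES):
            raise ValueError(f"expected {len(CATEGORIES)} counts, got {len(seq)}")
        vals = dict(zip(CATEGORIES, (int(v) for v in seq)))
    if any(v < 0 for v in vals.values()):
        raise ValueError("counts must be nonnegative")
    if all(v == 0 for v in vals.values()):
        raise ValueError("all-zero counts cannot be classified")
    best = max(vals.values())
    for cat in PRIORITY:
        if vals[cat] == best:
            return cat
    raise AssertionError("unreachable")


def classify_table(table: KanoTable) -> tuple[list[str], int | None]:
    """Per-row modal categories, plus agreement count with published results.

    The agreement count is ``None`` when no row carries a published result.
    """
    categories = [classify_attribute(row.counts) for row in table.rows]
    printed = [row.printed_result for row in table.rows]
    if all(p is None for p in printed):
        return categories, None
    agreement = sum(
        1 for got, want in zip(categories, printed) if want is not None and got == want
    )
    return categories, agreement


def load_wheelchair_survey() -> KanoTable:
    """The packaged wheelchair user-needs Kano frequency table (15 attributes)."""
    ref = resources.files("ssvepchair.data") / "kano_wheelchair_survey.csv"
    with resources.as_file(ref) as path:
        return KanoTable.from_csv(path)
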