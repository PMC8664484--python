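"""Assembly metrics, before/after census comparison, and parts-vs-totals
validation of annotation census tables.

The census comparison follows the release-notes convention: the
difference row is new minus old, so a shrinking assembly prints a
negative total-length difference alongside a positive effective-length
difference when placeholder Ns are replaced by real sequence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gapcensus import CensusTable


@dataclass
class MetricsRecord:
    n_sequences: int
    total_bp: int
    effective_bp: int
    n50_bp: int
    max_length_bp: int
    gap_counts: dict[str, int]


def n50(lengths: list[int]) -> int:
    """Length of the smallest member of the minimal set of largest
    sequences jointly covering at least half the total."""
    if not lengths or min(lengths) <= 0:
        raise ValueError("lengths must be positive and non-empty")
    ordered = sorted(lengths, reverse=True)
    half = sum(ordered) / 2.0
    acc = 0
    for x in ordered:
        acc += x
        if acc >= half:
            return x
    raise AssertionError("unreachable")


def assembly_metrics(lengths: list[int], *, effective_bp: int | None = None,
                     gap_counts: dict[str, int] | None = None
                     ) -> MetricsRecord:
    total = sum(lengths)
    return MetricsRecord(
        n_sequences=len(lengths), total_bp=total,
        effective_bp=total if effective_bp is None else effective_bp,
        n50_bp=n50(lengths), max_length_bp=max(lengths),
        gap_counts=gap_counts or {})


# ---------------------------------------------------------- census comparison

def compare_censuses(old: CensusTable, new: CensusTable) -> pd.DataFrame:
    """Per-sequence and Total differences, new - old.

    Requires identical sequence sets. The returned frame has the census
    columns plus a ``Difference`` row equal to the Total-row difference.
    """
    if set(old.frame.index) != set(new.frame.index):
        raise ValueError("censuses cover different sequence sets")
    diff = new.frame - old.frame.loc[new.frame.index]
    total = diff.sum(axis=0).rename("Difference")
    return pd.concat([diff, total.to_frame().T])


def difference_row(old: CensusTable, new: CensusTable) -> pd.Series:
    return compare_censuses(old, new).loc["Difference"]


# ------------------------------------------------------------ table validation

@dataclass(frozen=True)
class PartOf:
    """Declares that ``total`` should equal the sum of ``parts``."""
    total: str
    parts: tuple[str, ...]
    tolerance: float = 0.0


@dataclass(frozen=True)
class Violation:
    total: str
    expected: float
    observed: float

    def __str__(self) -> str:
        return (f"{self.total}: declared {self.observed}, parts sum to "
                f"{self.expected}")


class TableSchemaError(KeyError):
    pass


def validate_totals(values: dict[str, float],
                    relations: list[PartOf]) -> list[Violation]:
    """Check every declared total against the sum of its parts.

    Returns an empty list iff all relations hold within their tolerances
    (percentage columns typically use a printed-rounding tolerance such
    as 0.01; integer columns use 0). Unknown labels raise
    :class:`TableSchemaError`.
    """
    violations = []
    for rel in relations:
        unknown = [lbl for lbl in (rel.total, *rel.parts) if lbl not in values]
        if unknown:
            raise TableSchemaError(f"unknown label(s) {unknown} in relation "
                                   f"for {rel.total}")
        expected = float(np.sum([values[p] for p in rel.parts]))
        observed = float(values[rel.total])
        if abs(expected - observed) > rel.tolerance + 1e-9:
            violations.append(Violation(rel.total, expected, observed))
    return violations


def frame_to_values(df: pd.DataFrame, index_col: str | None = None
                    ) -> dict[str, float]:
    """Flatten a table to '<row>/<column>' labels for validate_totals."""
    if index_col is not None:
        df = df.set_index(index_col)
    values = {}
    for row in df.index:
        for col in df.columns:
            v = df.loc[row, col]
            if pd.notna(v) and np.isreal(v):
                values[f"{row}/{col}"] = float(v)
    return values
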