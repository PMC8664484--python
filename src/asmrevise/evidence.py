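"""HC/LC/REP gene-model grading from BLAST-tabular evidence, and the
BUSCO-style completeness summary.

Predicted proteins are graded against best hits in three databases:
UniMag (curated Magnoliophyta proteins), UniPoa (Poaceae proteins), and
PTREP (hypothetical transposon proteins). The decision rules:

* **HC** — a complete protein with a significant UniMag hit whose subject
  *and* query coverage exceed the threshold; or a complete protein with no
  UniMag hit at all but a significant UniPoa hit and no significant PTREP
  hit.
* **LC** — an incomplete protein with a significant UniMag or UniPoa hit
  and no significant PTREP hit; or a complete protein with no hit in any
  of the three databases.
* **REP** — a complete protein absent from UniMag but with a significant
  PTREP hit (evaluated before the complete-no-hit LC fallback).
* **unclassified** — every evidence shape the rules above leave silent
  (e.g. a complete protein whose only UniMag hit fails the coverage
  threshold); never silently promoted to HC/LC.

Hit significance requires E-value below ``evalue_max`` and the
database-appropriate coverage strictly above ``coverage_min``: subject
coverage for the protein databases, query coverage for the transposon
database. The stated E-value cutoff "10e-10" is read as 1e-10 by default;
the literal reading 1e-9 is available as :data:`LITERAL_10E10`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

PROTEIN_DBS = ("UniMag", "UniPoa")
TE_DB = "PTREP"
DATABASES = PROTEIN_DBS + (TE_DB,)

LABELS = ("HC", "LC", "REP", "unclassified")


@dataclass(frozen=True)
class Hit:
    """Best hit of one protein against one database."""
    evalue: float
    query_coverage: float    # percent, 0-100
    subject_coverage: float  # percent, 0-100

    def __post_init__(self):
        if not (0 <= self.query_coverage <= 100
                and 0 <= self.subject_coverage <= 100):
            raise ValueError("coverages must be in [0, 100]")
        if self.evalue < 0:
            raise ValueError("evalue must be >= 0")


@dataclass
class EvidenceRecord:
    protein_id: str
    complete: bool
    hits: dict[str, Hit] = field(default_factory=dict)  # db -> best hit


@dataclass(frozen=True)
class Thresholds:
    evalue_max: float = 1e-10
    coverage_min: float = 95.0


#: the literal reading of "10e-10"
LITERAL_10E10 = Thresholds(evalue_max=1e-9)


@dataclass(frozen=True)
class Grade:
    label: str
    rule_id: str


class EvidenceFormatError(ValueError):
    pass


def significant_hit(hit: Hit, db: str,
                    thresholds: Thresholds = Thresholds()) -> bool:
    """Significance of a best hit: E-value strictly below the cutoff and
    the database-appropriate coverage strictly above the minimum (subject
    coverage for protein databases, query coverage for PTREP)."""
    if db not in DATABASES:
        raise ValueError(f"unknown database {db!r}")
    cov = hit.query_coverage if db == TE_DB else hit.subject_coverage
    if cov is None:
        raise EvidenceFormatError(f"missing coverage for {db} hit")
    return hit.evalue < thresholds.evalue_max and cov > thresholds.coverage_min


def grade_protein(rec: EvidenceRecord,
                  thresholds: Thresholds = Thresholds()) -> Grade:
    """Grade one protein by the HC/LC/REP decision table."""
    sig = {db: (db in rec.hits and
                significant_hit(rec.hits[db], db, thresholds))
           for db in DATABASES}
    present = {db: db in rec.hits for db in DATABASES}
    unimag_full = (present["UniMag"]
                   and significant_hit(rec.hits["UniMag"], "UniMag", thresholds)
                   and rec.hits["UniMag"].query_coverage > thresholds.coverage_min)
    if rec.complete:
        if unimag_full:
            return Grade("HC", "hc_unimag")
        if not present["UniMag"] and sig[TE_DB]:
            return Grade("REP", "rep_ptrep")
        if not present["UniMag"] and sig["UniPoa"] and not sig[TE_DB]:
            return Grade("HC", "hc_unipoa")
        if not any(present.values()):
            return Grade("LC", "lc_complete_nohit")
        return Grade("unclassified", "silent_complete")
    if (sig["UniMag"] or sig["UniPoa"]) and not sig[TE_DB]:
        return Grade("LC", "lc_incomplete_hit")
    return Grade("unclassified", "silent_incomplete")


def grade_set(records: list[EvidenceRecord],
              thresholds: Thresholds = Thresholds()) -> pd.Series:
    """Counts per label; the counts partition the input."""
    counts = {label: 0 for label in LABELS}
    for rec in records:
        counts[grade_protein(rec, thresholds).label] += 1
    return pd.Series(counts)


# -------------------------------------------------------------- BUSCO summary

def busco_summary(total: int, complete_single: int, complete_dup: int,
                  fragmented: int, missing: int) -> dict[str, float]:
    """Completeness summary; coverage % = 100 (total - missing) / total,
    reported to one decimal."""
    parts = complete_single + complete_dup + fragmented + missing
    if parts != total:
        raise ValueError(
            f"categories sum to {parts}, expected total {total}")
    pct = lambda x: round(100.0 * x / total, 1)
    return {
        "coverage_pct": pct(total - missing),
        "complete_single_pct": pct(complete_single),
        "complete_duplicated_pct": pct(complete_dup),
        "fragmented_pct": pct(fragmented),
        "missing_pct": pct(missing),
    }


# ------------------------------------------------------------------ table I/O

BLAST_COLUMNS = ["qseqid", "sseqid", "pident", "length", "mismatch",
                 "gapopen", "qstart", "qend", "sstart", "send", "evalue",
                 "bitscore", "qcovs", "scovs"]


def read_blast_table(path: str | Path) -> pd.DataFrame:
    """outfmt-6-style TSV with appended qcovs/scovs columns."""
    df = pd.read_csv(path, sep="\t", names=BLAST_COLUMNS, comment="#")
    missing = df[["qcovs", "scovs"]].isna().any(axis=1)
    if missing.any():
        raise EvidenceFormatError(
            f"{path}: row {int(missing.idxmax())} lacks coverage columns")
    return df


def best_hits(df: pd.DataFrame) -> dict[str, Hit]:
    """Best hit per query: lowest E-value, then highest bitscore."""
    df = df.sort_values(["qseqid", "evalue", "bitscore"],
                        ascending=[True, True, False])
    best = df.groupby("qseqid", sort=False).first()
    return {q: Hit(row["evalue"], row["qcovs"], row["scovs"])
            for q, row in best.iterrows()}


def load_evidence(completeness_tsv: str | Path,
                  blast_tables: dict[str, str | Path]) -> list[EvidenceRecord]:
    """Assemble evidence records from a completeness TSV
    (protein_id<TAB>complete as 0/1) and per-database BLAST tables."""
    comp = pd.read_csv(completeness_tsv, sep="\t",
                       names=["protein_id", "complete"], comment="#")
    hits_by_db = {db: best_hits(read_blast_table(p))
                  for db, p in blast_tables.items()}
    records = []
    for _, row in comp.iterrows():
        pid = str(row["protein_id"])
        hits = {db: h[pid] for db, h in hits_by_db.items() if pid in h}
        records.append(EvidenceRecord(pid, bool(int(row["complete"])), hits))
    return records


def grades_to_frame(records: list[EvidenceRecord],
                    thresholds: Thresholds = Thresholds()) -> pd.DataFrame:
    rows = []
    for rec in records:
        g = grade_protein(rec, thresholds)
        rows.append({"protein_id": rec.protein_id, "label": g.label,
                     "rule_id": g.rule_id})
    return pd.DataFrame(rows)
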