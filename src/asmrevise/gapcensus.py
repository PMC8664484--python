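"""N-gap discovery, placeholder classification, and per-chromosome census.

Draft Triticeae assemblies encode three kinds of joins as N-runs of fixed
conventional size: 10 N between short-read contigs, 100 N between hybrid
scaffolding components, and 1000 N between adjacent scaffolds and
super-scaffolds. Any other N-run length is treated as a *sized* gap whose
N count estimates the physical span. The census table reports, per
pseudomolecule, total length, summed gap length, effective length (length
without Ns), and gap count — the standard before/after bookkeeping for a
gap-closing release.

Coordinates are 0-based half-open internally; AGP output is 1-based
inclusive per the AGP v2.1 standard.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .assembly import Assembly, check_alphabet

PLACEHOLDER_LENGTHS = {10: "placeholder10", 100: "placeholder100", 1000: "placeholder1000"}

_N_RUN = re.compile(r"[Nn]+")


@dataclass(frozen=True)
class GapRecord:
    """One maximal N-run. ``end - start == length >= 1``."""

    seq_id: str
    start: int  # 0-based inclusive
    end: int    # 0-based exclusive
    klass: str  # placeholder10 | placeholder100 | placeholder1000 | sized

    @property
    def length(self) -> int:
        return self.end - self.start


def classify_gap(length: int) -> str:
    """Classify an N-run length: exact 10/100/1000 are placeholders, else sized."""
    if length < 1:
        raise ValueError(f"gap length must be >= 1, got {length}")
    return PLACEHOLDER_LENGTHS.get(length, "sized")


def find_n_runs(sequence: str, seq_id: str = "seq") -> list[GapRecord]:
    """Locate maximal runs of N (case-insensitive), sorted by position.

    Raises :class:`~asmrevise.assembly.SequenceFormatError` on characters
    outside {A, C, G, T, N}. Ambiguity codes other than N are not gaps and
    are rejected rather than silently skipped.
    """
    check_alphabet(sequence, seq_id)
    return [
        GapRecord(seq_id, m.start(), m.end(), classify_gap(m.end() - m.start()))
        for m in _N_RUN.finditer(sequence)
    ]


def assembly_gaps(assembly: Assembly) -> list[GapRecord]:
    """Gap registry for every sequence of an assembly."""
    out: list[GapRecord] = []
    for seq_id, seq in assembly.sequences.items():
        out.extend(find_n_runs(seq, seq_id))
    return out


# --------------------------------------------------------------------- census

@dataclass
class CensusTable:
    """Per-sequence totals plus a Total row (Aet-census style).

    ``frame`` has index seq_id and columns ``total_length``, ``gap_length``,
    ``effective_length``, ``gap_number``. The Total row is recomputed, never
    stored.
    """

    frame: pd.DataFrame

    COLUMNS = ["total_length", "gap_length", "effective_length", "gap_number"]

    def total_row(self) -> pd.Series:
        return self.frame.sum(axis=0).rename("Total")

    def with_total(self) -> pd.DataFrame:
        return pd.concat([self.frame, self.total_row().to_frame().T])

    def to_tsv(self, path: str | Path) -> None:
        self.with_total().rename_axis("seq_id").to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "CensusTable":
        df = pd.read_csv(path, sep="\t", index_col="seq_id")
        df = df[df.index != "Total"][cls.COLUMNS].astype("int64")
        return cls(df)

    @classmethod
    def from_rows(cls, rows: dict[str, tuple[int, int, int, int]]) -> "CensusTable":
        df = pd.DataFrame.from_dict(rows, orient="index", columns=cls.COLUMNS)
        return cls(df.astype("int64"))


def census(assembly: Assembly) -> CensusTable:
    """Compute the census from sequence content.

    effective_length = total_length - gap_length for every row by
    construction.
    """
    rows = {}
    for seq_id, seq in assembly.sequences.items():
        if not seq:
            raise ValueError(f"{seq_id}: empty sequence")
        gaps = find_n_runs(seq, seq_id)
        gap_bp = sum(g.length for g in gaps)
        rows[seq_id] = (len(seq), gap_bp, len(seq) - gap_bp, len(gaps))
    return CensusTable.from_rows(rows)


# ------------------------------------------------------------------ AGP v2.1

def write_agp(assembly: Assembly, path: str | Path, *,
              component_prefix: str = "comp") -> None:
    """Write the assembly structure as AGP v2.1 (component and gap lines).

    Components are the non-N stretches; gap lines carry the emitted N count.
    Placeholder gaps are written as scaffold gaps with ``map`` evidence,
    sized gaps with ``paired-ends`` evidence (nearest standard vocabulary).
    """
    lines = ["##agp-version\t2.1"]
    comp_no = 0
    for seq_id, seq in assembly.sequences.items():
        part = 0
        pos = 0
        gaps = find_n_runs(seq, seq_id)
        bounds = [(g.start, g.end, g.klass) for g in gaps]
        for start, end, klass in bounds + [(len(seq), len(seq), None)]:
            if pos < start:
                part += 1
                comp_no += 1
                lines.append("\t".join([
                    seq_id, str(pos + 1), str(start), str(part), "W",
                    f"{component_prefix}{comp_no:06d}", "1", str(start - pos), "+",
                ]))
            if klass is not None:
                part += 1
                evidence = "map" if klass.startswith("placeholder") else "paired-ends"
                lines.append("\t".join([
                    seq_id, str(start + 1), str(end), str(part), "N",
                    str(end - start), "scaffold", "yes", evidence,
                ]))
            pos = end
    Path(path).write_text("\n".join(lines) + "\n")


def read_agp(path: str | Path) -> pd.DataFrame:
    """Parse AGP v2.1 into a DataFrame with 0-based half-open coordinates."""
    rows = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        f = line.split("\t")
        row = {
            "object": f[0], "start": int(f[1]) - 1, "end": int(f[2]),
            "part": int(f[3]), "type": f[4],
        }
        if f[4] in ("N", "U"):
            row.update(gap_length=int(f[5]), gap_type=f[6], linkage=f[7],
                       evidence=f[8])
        else:
            row.update(component_id=f[5], component_start=int(f[6]) - 1,
                       component_end=int(f[7]), orientation=f[8])
        rows.append(row)
    return pd.DataFrame(rows)
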