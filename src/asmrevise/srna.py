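"""Small-RNA classification: size profiles, hc-siRNA attribution,
tRNA-derived-fragment (tRF) classes with nine positional bins, and
polycistronic pre-miRNA grouping.

Reads are adapter-trimmed to 18-34 nt upstream. hc-siRNAs are the 21-24 nt
reads mapping to annotated transposable elements, counted per TE
superfamily and length. tRFs are tRNA-aligned reads classified by origin
on the mature tRNA: 5-tRF from the first nucleotide, 3-tRF ending at the
3' end, i-tRF internal (5-tRF precedence when a read spans the full
molecule); the read's 5' start falls into one of nine equal bins,
``ceil(9 * start / trna_length)``, reflecting typical cleavage positions.
Pre-miRNA loci separated by strictly less than 3000 intervening
nucleotides are grouped as potentially polycistronic.
"""

from __future__ import annotations

import math
from collections import Counter, defaultdict
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from intervaltree import IntervalTree

MIN_LEN, MAX_LEN = 18, 34
HC_SIRNA_LENGTHS = range(21, 25)
POLYCISTRON_MAX_SEP = 3000
N_BINS = 9


@dataclass(frozen=True)
class SrnaAlignment:
    target_id: str
    target_class: str  # TE | tRNA | pre-miRNA | CDS | other
    start: int         # 0-based on the target / genome
    end: int
    strand: str


@dataclass(frozen=True)
class SrnaRead:
    read_id: str
    length: int
    sequence: str = ""
    alignment: SrnaAlignment | None = None

    def __post_init__(self):
        if not (MIN_LEN <= self.length <= MAX_LEN):
            raise ValueError(
                f"{self.read_id}: length {self.length} outside "
                f"[{MIN_LEN}, {MAX_LEN}]")


@dataclass(frozen=True)
class TrfCall:
    read_id: str
    trf_class: str  # 5-tRF | i-tRF | 3-tRF
    bin: int        # 1..9


# --------------------------------------------------------------- size profile

def size_profile(reads: list[SrnaRead]) -> pd.DataFrame:
    """Histograms over 18-34 nt: all reads and distinct sequences.

    Distinct counting uses the read sequence when available, otherwise the
    read id. Abundant few-sequence classes (21-nt miRNAs) peak in the
    total histogram only; diverse classes (24-nt hc-siRNAs) peak in both.
    """
    total = Counter(r.length for r in reads)
    distinct = Counter()
    seen = set()
    for r in reads:
        key = r.sequence or r.read_id
        if key not in seen:
            seen.add(key)
            distinct[r.length] += 1
    idx = range(MIN_LEN, MAX_LEN + 1)
    return pd.DataFrame({"total": [total.get(i, 0) for i in idx],
                         "distinct": [distinct.get(i, 0) for i in idx]},
                        index=pd.Index(idx, name="length"))


# ------------------------------------------------------------------ hc-siRNAs

def read_gff3_features(path: str | Path, feature_types: set[str] | None = None,
                       class_attr: str = "superfamily") -> pd.DataFrame:
    """Flat GFF3 feature table (seqid, start0, end, strand, category)."""
    rows = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        f = line.split("\t")
        if len(f) < 9:
            continue
        if feature_types and f[2] not in feature_types:
            continue
        attrs = dict(kv.split("=", 1) for kv in f[8].split(";") if "=" in kv)
        rows.append({"seqid": f[0], "type": f[2], "start": int(f[3]) - 1,
                     "end": int(f[4]), "strand": f[6],
                     "category": attrs.get(class_attr, attrs.get("ID", "NA"))})
    return pd.DataFrame(rows)


def classify_hc_sirna(reads: list[SrnaRead], te_features: pd.DataFrame
                      ) -> pd.DataFrame:
    """Counts of 21-24 nt reads overlapping TE features, per TE
    superfamily x read length. Order-invariant; reads off any TE or of
    other lengths are excluded."""
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for _, f in te_features.iterrows():
        if f["end"] > f["start"]:
            trees[f["seqid"]].addi(f["start"], f["end"], f["category"])
    counts: Counter = Counter()
    for r in reads:
        if r.length not in HC_SIRNA_LENGTHS or r.alignment is None:
            continue
        hits = trees[r.alignment.target_id].overlap(
            r.alignment.start, r.alignment.end)
        for cat in sorted({iv.data for iv in hits}):
            counts[(cat, r.length)] += 1
    if not counts:
        return pd.DataFrame(columns=["superfamily", "length", "count"])
    df = pd.DataFrame([(c, l, n) for (c, l), n in sorted(counts.items())],
                      columns=["superfamily", "length", "count"])
    return df


# ------------------------------------------------------------------------ tRF

class TrfCoordinateError(ValueError):
    pass


def trf_classify(read_id: str, start: int, end: int,
                 trna_length: int) -> TrfCall:
    """Classify a tRNA-aligned read (1-based inclusive on the mature tRNA).

    start == 1 -> 5-tRF; end == trna_length -> 3-tRF; otherwise i-tRF.
    5-tRF takes precedence for reads spanning both ends. The positional
    bin is ``ceil(9 * start / trna_length)``.
    """
    if not (1 <= start <= end <= trna_length):
        raise TrfCoordinateError(
            f"{read_id}: alignment [{start}, {end}] outside "
            f"[1, {trna_length}]")
    if start == 1:
        klass = "5-tRF"
    elif end == trna_length:
        klass = "3-tRF"
    else:
        klass = "i-tRF"
    bin_no = math.ceil(N_BINS * start / trna_length)
    return TrfCall(read_id, klass, bin_no)


def trf_classify_reads(reads: list[SrnaRead],
                       trna_lengths: dict[str, int]) -> list[TrfCall]:
    """Classify every tRNA-aligned read (exactly one class and bin each)."""
    calls = []
    for r in reads:
        a = r.alignment
        if a is None or a.target_class != "tRNA":
            continue
        calls.append(trf_classify(r.read_id, a.start + 1, a.end,
                                  trna_lengths[a.target_id]))
    return calls


# ---------------------------------------------------------------- polycistron

def polycistron_group(loci: list[tuple[str, int, int]]
                      ) -> list[list[tuple[str, int, int]]]:
    """Single-linkage clusters of same-sequence pre-miRNA loci separated by
    strictly fewer than 3000 intervening nucleotides (end-to-start).

    Returns a partition of the input loci; clusters of size >= 2 are the
    potential polycistrons (see :func:`polycistrons`).
    """
    by_seq: dict[str, list[tuple[str, int, int]]] = defaultdict(list)
    for locus in loci:
        by_seq[locus[0]].append(locus)
    clusters = []
    for seq_id in sorted(by_seq):
        group = sorted(by_seq[seq_id], key=lambda x: (x[1], x[2]))
        current = [group[0]]
        cur_end = group[0][2]
        for locus in group[1:]:
            if locus[1] - cur_end < POLYCISTRON_MAX_SEP:
                current.append(locus)
            else:
                clusters.append(current)
                current = [locus]
            cur_end = max(cur_end, locus[2])
        clusters.append(current)
    return clusters


def polycistrons(loci: list[tuple[str, int, int]]
                 ) -> list[list[tuple[str, int, int]]]:
    """Clusters of size >= 2: the potentially polycistronic pre-miRNAs."""
    return [c for c in polycistron_group(loci) if len(c) >= 2]


# ----------------------------------------------------------------- TSV loader

def read_alignment_tsv(path: str | Path) -> list[SrnaRead]:
    """BED-like TSV: read_id, target_id, target_class, start, end, strand,
    length[, sequence]."""
    reads = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        f = line.split("\t")
        seq = f[7] if len(f) > 7 else ""
        reads.append(SrnaRead(
            f[0], int(f[6]), seq,
            SrnaAlignment(f[1], f[2], int(f[3]), int(f[4]), f[5])))
    return reads
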