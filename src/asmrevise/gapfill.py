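"""Close N-gaps with aligned contig sequence, collapse flank-duplication
artifacts, and maintain a lift-over of all coordinates.

Gap closing replaces an N-run with the contig subsequence spanning it,
provided a single contig anchors both flanks collinearly; nothing outside
the N-run is modified, and a gap is closed entirely or left intact.
Duplication collapse targets the placeholder-gap artifact where erroneous
scaffolding of a tandem-repeat region duplicated the gap's flank: the gap
and one copy of the near-identical overlap are removed, shortening the
sequence while increasing its effective (non-N) length.

Contig placement is a desk-scale stand-in for whole-genome alignment:
unique exact k-mer anchors grouped by diagonal, split at N-runs, and
scored by ungapped identity. Externally computed placements (minimal
12-column PAF) are accepted as an alternative input.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .assembly import Assembly, revcomp
from . import gapcensus

_LUT = np.full(256, 4, dtype=np.uint8)
for i, b in enumerate(b"ACGT"):
    _LUT[b] = i
for i, b in enumerate(b"acgt"):
    _LUT[b] = i


def _codes(seq: str) -> np.ndarray:
    return _LUT[np.frombuffer(seq.encode(), dtype=np.uint8)]


def _kmer_codes(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """(int64 k-mer codes, validity mask) for every window start."""
    n = codes.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    acc = np.zeros(n, dtype=np.int64)
    for t in range(k):
        acc = acc * 4 + codes[t:t + n]
    bad = (codes >= 4).astype(np.int32)
    cs = np.concatenate(([0], np.cumsum(bad)))
    valid = (cs[k:] - cs[:-k]) == 0
    return acc, valid


# ----------------------------------------------------------------- placement

@dataclass
class Placement:
    """An ungapped contig-to-assembly alignment block.

    ``contig_start/end`` are on the original contig strand;
    ``oriented_start`` is the block start on the contig as oriented to
    match the assembly forward strand (equal to ``contig_start`` for '+').
    """

    contig_id: str
    seq_id: str
    contig_start: int
    contig_end: int
    asm_start: int
    asm_end: int
    orientation: str
    identity: float
    aligned_bp: int
    contig_length: int = 0

    @property
    def oriented_start(self) -> int:
        if self.orientation == "+":
            return self.contig_start
        return self.contig_length - self.contig_end

    @property
    def diagonal(self) -> int:
        return self.asm_start - self.oriented_start


class _AssemblyIndex:
    """Sorted unique-k-mer index over all assembly sequences."""

    def __init__(self, assembly: Assembly, k: int):
        self.k = k
        self.offsets: list[tuple[str, int, int]] = []
        parts, cur = [], 0
        sep = "N" * k
        for seq_id, seq in assembly.sequences.items():
            self.offsets.append((seq_id, cur, cur + len(seq)))
            parts.append(seq)
            parts.append(sep)
            cur += len(seq) + k
        joined = "".join(parts)
        codes, valid = _kmer_codes(_codes(joined), k)
        pos = np.nonzero(valid)[0]
        kc = codes[pos]
        order = np.argsort(kc, kind="stable")
        kc, pos = kc[order], pos[order]
        first = np.concatenate(([True], kc[1:] != kc[:-1]))
        last = np.concatenate((kc[1:] != kc[:-1], [True]))
        unique = first & last
        self.sorted_codes = kc[unique]
        self.positions = pos[unique]

    def lookup(self, query_codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(query index, global assembly position) of unique-k-mer matches."""
        idx = np.searchsorted(self.sorted_codes, query_codes)
        idx = np.minimum(idx, self.sorted_codes.size - 1)
        hit = self.sorted_codes.size > 0
        if not hit:
            return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
        ok = self.sorted_codes[idx] == query_codes
        return np.nonzero(ok)[0], self.positions[idx[ok]]

    def seq_of(self, gpos: int) -> tuple[str, int] | None:
        for seq_id, lo, hi in self.offsets:
            if lo <= gpos < hi:
                return seq_id, lo
        return None


def _count_mismatches(a: str, b: str) -> int:
    if a == b:
        return 0
    xa = np.frombuffer(a.encode(), dtype=np.uint8)
    xb = np.frombuffer(b.encode(), dtype=np.uint8)
    return int(np.sum(xa != xb))


def place_contigs(assembly: Assembly, contigs: dict[str, str],
                  anchor_k: int = 21, *, min_identity: float = 0.99,
                  min_block: int = 200, max_anchor_gap: int = 20_000
                  ) -> list[Placement]:
    """Place contigs on the assembly from unique exact k-mer anchors.

    Anchors sharing a diagonal are chained into ungapped blocks (split at
    assembly N-runs and at anchor gaps above ``max_anchor_gap``), and
    blocks with un-gapped identity below ``min_identity`` or shorter than
    ``min_block`` bp are discarded. Both orientations are considered.
    """
    if anchor_k < 15:
        raise ValueError("anchor_k must be >= 15")
    if not contigs:
        return []
    index = _AssemblyIndex(assembly, anchor_k)
    k = anchor_k
    placements: list[Placement] = []
    for contig_id in sorted(contigs):
        cseq = contigs[contig_id]
        clen = len(cseq)
        for orientation, oseq in (("+", cseq), ("-", revcomp(cseq))):
            ccodes, cvalid = _kmer_codes(_codes(oseq), k)
            vpos = np.nonzero(cvalid)[0]
            qi, gpos = index.lookup(ccodes[vpos])
            if qi.size == 0:
                continue
            cpos = vpos[qi]
            diag = gpos - cpos
            order = np.lexsort((cpos, diag))
            cpos, gpos, diag = cpos[order], gpos[order], diag[order]
            starts = np.nonzero(np.concatenate(
                ([True], (diag[1:] != diag[:-1]) |
                 (cpos[1:] - cpos[:-1] > max_anchor_gap))))[0]
            bounds = np.concatenate((starts, [diag.size]))
            for a, b in zip(bounds[:-1], bounds[1:]):
                loc = index.seq_of(int(gpos[a]))
                if loc is None:
                    continue
                seq_id, base = loc
                block_c = cpos[a:b]
                block_g = gpos[a:b] - base
                placements.extend(_emit_blocks(
                    assembly.sequences[seq_id], oseq, seq_id, contig_id,
                    orientation, clen, block_c, block_g, k,
                    min_identity, min_block))
    placements.sort(key=lambda p: (p.seq_id, p.asm_start, p.contig_id))
    return placements


def _extend_ungapped(aseq: str, oseq: str, o_start: int, o_end: int,
                     g_start: int, g_end: int, max_mismatch_run: int = 10
                     ) -> tuple[int, int, int, int]:
    """Extend an anchor block outward on its diagonal, through repeat
    regions that lack unique k-mers, stopping at N, a sequence end, or a
    run of ``max_mismatch_run`` consecutive mismatches (trimmed back to
    the last matching base)."""
    run, last = 0, 0
    while o_start - last - 1 >= 0 and g_start - last - 1 >= 0:
        a, b = aseq[g_start - last - 1], oseq[o_start - last - 1]
        if a == "N" or b == "N":
            break
        last += 1
        if a == b:
            o_start -= last
            g_start -= last
            run, last = 0, 0
        else:
            run += 1
            if run >= max_mismatch_run:
                break
    run, last = 0, 0
    la, lo = len(aseq), len(oseq)
    while g_end + last < la and o_end + last < lo:
        a, b = aseq[g_end + last], oseq[o_end + last]
        if a == "N" or b == "N":
            break
        last += 1
        if a == b:
            g_end += last
            o_end += last
            run, last = 0, 0
        else:
            run += 1
            if run >= max_mismatch_run:
                break
    return o_start, o_end, g_start, g_end


def _emit_blocks(aseq, oseq, seq_id, contig_id, orientation, clen,
                 block_c, block_g, k, min_identity, min_block):
    """Split a diagonal anchor run at assembly N-runs; score each block."""
    import re
    out = []
    lo, hi = int(block_g[0]), int(block_g[-1]) + k
    sub = aseq[lo:hi]
    if "N" in sub:
        splits = []
        start = 0
        for m in re.finditer("N+", sub):
            splits.append((start, m.start()))
            start = m.end()
        splits.append((start, len(sub)))
        groups = []
        for s, e in splits:
            mask = (block_g >= lo + s) & (block_g + k <= lo + e)
            if mask.any():
                groups.append((block_c[mask], block_g[mask]))
    else:
        groups = [(block_c, block_g)]
    for bc, bg in groups:
        o_start, o_end = int(bc[0]), int(bc[-1]) + k
        g_start, g_end = int(bg[0]), int(bg[-1]) + k
        o_start, o_end, g_start, g_end = _extend_ungapped(
            aseq, oseq, o_start, o_end, g_start, g_end)
        span = g_end - g_start
        if span < min_block:
            continue
        mism = _count_mismatches(aseq[g_start:g_end], oseq[o_start:o_end])
        identity = 1.0 - mism / span
        if identity < min_identity:
            continue
        if orientation == "+":
            c_start, c_end = o_start, o_end
        else:
            c_start, c_end = clen - o_end, clen - o_start
        out.append(Placement(contig_id, seq_id, c_start, c_end, g_start,
                             g_end, orientation, identity, span, clen))
    return out


def read_paf(path: str | Path, contig_lengths: dict[str, int] | None = None
             ) -> list[Placement]:
    """Minimal 12-column PAF reader producing :class:`Placement` records."""
    out = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        f = line.split("\t")
        matches, block = int(f[9]), int(f[10])
        out.append(Placement(
            contig_id=f[0], seq_id=f[5], contig_start=int(f[2]),
            contig_end=int(f[3]), asm_start=int(f[7]), asm_end=int(f[8]),
            orientation=f[4], identity=matches / block if block else 0.0,
            aligned_bp=block, contig_length=int(f[1])))
    return out


# ------------------------------------------------------------------ edit log

@dataclass
class Edit:
    kind: str          # 'fill' | 'collapse'
    seq_id: str
    old_start: int
    old_end: int
    new_length: int    # replacement length (0 for collapse)
    provenance: str = ""
    meta: dict = field(default_factory=dict)

    @property
    def delta(self) -> int:
        return self.new_length - (self.old_end - self.old_start)


@dataclass
class EditLog:
    """Ordered fills/collapses with a piecewise-affine monotone lift-over.

    ``sequences``, when set, names every sequence of the edited assembly;
    lift-over then rejects unknown sequence ids.
    """

    edits: list[Edit] = field(default_factory=list)
    sequences: set[str] | None = None

    def for_seq(self, seq_id: str) -> list[Edit]:
        return sorted((e for e in self.edits if e.seq_id == seq_id),
                      key=lambda e: e.old_start)

    def seq_ids(self) -> list[str]:
        return sorted({e.seq_id for e in self.edits})

    def extend(self, other: "EditLog") -> None:
        self.edits.extend(other.edits)

    def n_fills(self) -> int:
        return sum(1 for e in self.edits if e.kind == "fill")

    def n_collapses(self) -> int:
        return sum(1 for e in self.edits if e.kind == "collapse")

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame([{
            "kind": e.kind, "seq_id": e.seq_id, "old_start": e.old_start,
            "old_end": e.old_end, "new_length": e.new_length,
            "provenance": e.provenance} for e in self.edits])


class LiftoverError(KeyError):
    pass


def liftover(edit_log: EditLog, seq_id: str, position: int,
             direction: str = "old_to_new") -> int:
    """Map a coordinate across the edits of one sequence.

    Positions outside edited intervals map bijectively; inside a replaced
    N-run they map to the replacement start; inside a collapsed copy they
    map to the retained copy. ``direction`` is ``old_to_new`` or
    ``new_to_old``.
    """
    if edit_log.sequences is not None and seq_id not in edit_log.sequences:
        raise LiftoverError(f"unknown sequence id {seq_id!r}")
    if seq_id not in {e.seq_id for e in edit_log.edits}:
        return position
    edits = edit_log.for_seq(seq_id)
    if direction == "old_to_new":
        delta = 0
        for e in edits:
            if position < e.old_start:
                break
            if position < e.old_end:
                if e.kind == "fill":
                    return e.old_start + delta
                gap_start = e.meta.get("gap_start", e.old_end)
                if position < gap_start:
                    # inside the collapsed copy: same offset in retained copy
                    return e.old_start + delta + (position - e.old_start)
                return e.old_start + delta + (gap_start - e.old_start)
            delta += e.delta
        return position + delta
    elif direction == "new_to_old":
        delta = 0
        for e in edits:
            new_start = e.old_start + delta
            new_end = new_start + e.new_length
            if position < new_start:
                break
            if position < new_end:
                return e.old_start
            delta += e.delta
        return position - delta
    raise ValueError(f"unknown direction {direction!r}")


def lift_gff3(edit_log: EditLog, lines: list[str]) -> list[str]:
    """Rewrite GFF3 feature coordinates through the lift-over (1-based)."""
    out = []
    for line in lines:
        if not line or line.startswith("#"):
            out.append(line)
            continue
        f = line.split("\t")
        start = liftover(edit_log, f[0], int(f[3]) - 1) + 1
        end = liftover(edit_log, f[0], int(f[4]) - 1) + 1
        f[3], f[4] = str(start), str(end)
        out.append("\t".join(f))
    return out


# ---------------------------------------------------------------- gap filling

@dataclass
class FillParams:
    min_anchor_bp: int = 500
    max_edge_distance: int = 100
    min_identity: float = 0.99
    span_tolerance: float = 0.5   # relative, sized gaps only


class AmbiguousFillError(ValueError):
    """Two candidate contigs tie on every tie-break key."""


def _apply_edits_to_seq(seq: str, edits: list[Edit],
                        replacements: dict[int, str]) -> str:
    """Apply edits right-to-left so earlier coordinates stay valid."""
    for e in sorted(edits, key=lambda e: -e.old_start):
        rep = replacements.get(id(e), "")
        seq = seq[:e.old_start] + rep + seq[e.old_end:]
    return seq


def fill_gaps(assembly: Assembly, contigs: dict[str, str],
              placements: list[Placement],
              params: FillParams | None = None) -> tuple[Assembly, EditLog]:
    """Close gaps whose flanks are both anchored by one contig.

    A gap closes iff a single contig has an alignment block ending within
    ``max_edge_distance`` bp of the left gap edge and another starting
    within ``max_edge_distance`` of the right edge, both at least
    ``min_anchor_bp`` long, in the same orientation and collinear. The
    contig subsequence between the flank anchor points replaces the N-run.
    Placeholder gaps accept any implied span >= 1; sized gaps must agree
    with the recorded span within ``span_tolerance`` (relative). Multiple
    qualifying contigs are resolved by greatest total anchored bp, then
    greatest identity, then lexicographic contig id.
    """
    params = params or FillParams()
    log_sequences = set(assembly.seq_ids)
    by_key: dict[tuple[str, str, str], list[Placement]] = {}
    for p in placements:
        by_key.setdefault((p.seq_id, p.contig_id, p.orientation), []).append(p)
    log = EditLog(sequences=log_sequences)
    replacements: dict[int, str] = {}
    per_seq_edits: dict[str, list[Edit]] = {s: [] for s in assembly.seq_ids}
    for seq_id, seq in assembly.sequences.items():
        gaps = gapcensus.find_n_runs(seq, seq_id)
        for gap in gaps:
            candidates = []
            for (sid, contig_id, orient), plist in by_key.items():
                if sid != seq_id:
                    continue
                lefts = [p for p in plist
                         if 0 <= gap.start - p.asm_end <= params.max_edge_distance
                         and p.aligned_bp >= params.min_anchor_bp]
                rights = [p for p in plist
                          if 0 <= p.asm_start - gap.end <= params.max_edge_distance
                          and p.aligned_bp >= params.min_anchor_bp]
                for pl in lefts:
                    for pr in rights:
                        c_gap_start = gap.start - pl.diagonal
                        c_gap_end = gap.end - pr.diagonal
                        implied = c_gap_end - c_gap_start
                        clen = pl.contig_length or len(contigs[contig_id])
                        if not (0 <= c_gap_start <= c_gap_end <= clen):
                            continue
                        if gap.klass == "sized":
                            if abs(implied - gap.length) > \
                                    params.span_tolerance * gap.length:
                                continue
                        elif implied < 1:
                            continue
                        key = (-(pl.aligned_bp + pr.aligned_bp),
                               -(pl.identity + pr.identity) / 2, contig_id)
                        candidates.append((key, contig_id, orient,
                                           c_gap_start, c_gap_end))
            if not candidates:
                continue
            candidates.sort(key=lambda c: c[0])
            if len(candidates) > 1 and candidates[0][0] == candidates[1][0] \
                    and candidates[0][1:] != candidates[1][1:]:
                raise AmbiguousFillError(
                    f"{seq_id}:{gap.start}-{gap.end}: contigs "
                    f"{candidates[0][1]} and {candidates[1][1]} tie on all "
                    "tie-break keys; resolve explicitly")
            _, contig_id, orient, c0, c1 = candidates[0]
            oseq = contigs[contig_id] if orient == "+" \
                else revcomp(contigs[contig_id])
            rep = oseq[c0:c1]
            edit = Edit("fill", seq_id, gap.start, gap.end, len(rep),
                        provenance=f"{contig_id}:{c0}-{c1}:{orient}",
                        meta={"klass": gap.klass})
            replacements[id(edit)] = rep
            per_seq_edits[seq_id].append(edit)
            log.edits.append(edit)
    new_seqs = {s: _apply_edits_to_seq(seq, per_seq_edits[s], replacements)
                for s, seq in assembly.sequences.items()}
    patched = Assembly(new_seqs, assembly.provenance +
                       [f"fill_gaps: {log.n_fills()} gap(s) closed"])
    return patched, log


# -------------------------------------------------------- duplication collapse

@dataclass
class CollapseParams:
    window: int = 25_000
    min_overlap: int = 1_000
    min_identity: float = 0.99


def _exact_overlap(left: str, right: str) -> int:
    """Longest n with left[-n:] == right[:n] (KMP border of right#left)."""
    s = right + "\x00" + left
    pi = [0] * len(s)
    k = 0
    for i in range(1, len(s)):
        while k and s[i] != s[k]:
            k = pi[k - 1]
        if s[i] == s[k]:
            k += 1
        pi[i] = k
    return pi[-1]


def _fuzzy_overlap(left: str, right: str, min_overlap: int,
                   min_identity: float) -> int:
    """Approximate duplicated-flank overlap via edlib probe alignment."""
    import edlib
    probe = right[:min_overlap]
    res = edlib.align(probe, left, mode="HW", task="locations")
    if res["editDistance"] < 0 or not res["locations"]:
        return 0
    if 1 - res["editDistance"] / len(probe) < min_identity:
        return 0
    start = res["locations"][0][0]
    n = len(left) - start
    if n < min_overlap or n > len(right):
        return 0
    check = edlib.align(left[-n:], right[:n], mode="NW", task="distance")
    if 1 - check["editDistance"] / n < min_identity:
        return 0
    return n


def collapse_duplication_artifacts(assembly: Assembly,
                                   params: CollapseParams | None = None
                                   ) -> tuple[Assembly, EditLog]:
    """Remove flank duplications spanning placeholder gaps.

    For each placeholder gap, the suffix of the left-flank window is
    compared with the prefix of the right-flank window. A near-identical
    overlap of at least ``min_overlap`` bp abutting the gap on both sides
    marks a scaffolding artifact: the gap and one copy of the overlap are
    removed, shortening the sequence by overlap + gap length.
    """
    params = params or CollapseParams()
    log = EditLog(sequences=set(assembly.seq_ids))
    replacements: dict[int, str] = {}
    per_seq: dict[str, list[Edit]] = {s: [] for s in assembly.seq_ids}
    for seq_id, seq in assembly.sequences.items():
        for gap in gapcensus.find_n_runs(seq, seq_id):
            if not gap.klass.startswith("placeholder"):
                continue
            left = seq[max(0, gap.start - params.window):gap.start]
            right = seq[gap.end:gap.end + params.window]
            if len(left) < params.min_overlap or len(right) < params.min_overlap:
                continue
            n = _exact_overlap(left, right)
            if n < params.min_overlap:
                n = _fuzzy_overlap(left, right, params.min_overlap,
                                   params.min_identity)
            if n < params.min_overlap:
                continue
            edit = Edit("collapse", seq_id, gap.start - n, gap.end, 0,
                        provenance=f"overlap={n}",
                        meta={"gap_start": gap.start, "overlap": n})
            per_seq[seq_id].append(edit)
            log.edits.append(edit)
    new_seqs = {s: _apply_edits_to_seq(seq, per_seq[s], replacements)
                for s, seq in assembly.sequences.items()}
    patched = Assembly(new_seqs, assembly.provenance +
                       [f"collapse: {log.n_collapses()} artifact(s) removed"])
    return patched, log
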