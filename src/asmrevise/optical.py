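"""Nick-site label maps: in-silico digestion, ordered-map DP alignment,
chimera detection, and super-scaffold placement validation/correction.

Optical (Bionano-style) maps record the ordered positions of nicking
endonuclease recognition sites (default Nt.BspQI, ``GCTCTTC``) along long
DNA molecules. Alignment compares inter-label fragment lengths, not bases.
The aligner here is a classic ordered-restriction-map dynamic program:
monotone pairings of labels, with bounded merging of adjacent fragments to
absorb missed or unresolved labels, a chi-square-like sizing cost per
aligned fragment pair, and a permutation-calibrated significance test in
place of the proprietary aligner's closed-form P-values.

Conventions (fixed for the whole package):

* a label sits at the motif *start* position on forward-strand coordinates,
  for occurrences on either strand — the nick offset cancels in fragment
  arithmetic;
* labels closer than ``resolution`` are merged to the midpoint of the
  cluster extremes, emulating instrument resolution;
* between equal-scoring orientations ``+`` is preferred; between
  equal-scoring loci the lowest ``(ref_id, position)`` wins.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .assembly import Assembly, revcomp
from . import gapcensus


class AlignmentError(ValueError):
    """Raised when a map is too small to align (fewer than 2 labels)."""


# ------------------------------------------------------------------ LabelMap

@dataclass
class LabelMap:
    """Ordered nick-site label positions for one sequence or map contig."""

    map_id: str
    length: int
    labels: np.ndarray  # strictly increasing positions, bp
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.float64)
        if self.labels.size and not np.all(np.diff(self.labels) > 0):
            raise ValueError(f"{self.map_id}: labels must strictly increase")
        if self.labels.size and (self.labels[0] < 0 or self.labels[-1] > self.length):
            raise ValueError(f"{self.map_id}: labels outside [0, length]")

    @property
    def n_labels(self) -> int:
        return int(self.labels.size)

    @property
    def fragments(self) -> np.ndarray:
        return np.diff(self.labels)

    def reversed(self) -> "LabelMap":
        """The map as seen from the other end of the molecule."""
        return LabelMap(self.map_id, self.length,
                        (self.length - self.labels)[::-1].copy(), dict(self.meta))


def _motif_sites(sequence: str, motif: str) -> tuple[np.ndarray, np.ndarray]:
    """Positions (motif start, forward coords) and strands of motif hits."""
    seq = sequence.upper()
    motif = motif.upper()
    rc = revcomp(motif)
    hits: list[tuple[int, int]] = []
    for pat, strand in ((motif, 1), (rc, -1)) if rc != motif else ((motif, 0),):
        i = seq.find(pat)
        while i != -1:
            hits.append((i, strand))
            i = seq.find(pat, i + 1)
    hits.sort()
    if not hits:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    pos, strand = zip(*hits)
    return np.asarray(pos, dtype=np.int64), np.asarray(strand, dtype=np.int64)


def _merge_labels(positions: np.ndarray, resolution: float) -> np.ndarray:
    """Greedy left-to-right clustering; clusters collapse to their midpoint."""
    if positions.size == 0 or resolution <= 0:
        return positions.astype(np.float64)
    out = []
    start = prev = positions[0]
    for p in positions[1:]:
        if p - prev < resolution:
            prev = p
        else:
            out.append((start + prev) / 2.0)
            start = prev = p
    out.append((start + prev) / 2.0)
    return np.asarray(out, dtype=np.float64)


def digest(sequence: str, motif: str = "GCTCTTC", resolution: int = 1000,
           map_id: str = "digest") -> LabelMap:
    """In-silico nick-site digestion of a DNA sequence.

    Labels are placed at every occurrence of ``motif`` on the forward strand
    and of its reverse complement (positions by motif start on forward
    coordinates), then merged within ``resolution``. N-runs match no motif
    and therefore yield no labels.
    """
    if len(motif) < 4:
        raise ValueError("motif length must be >= 4")
    if set(motif.upper()) - set("ACGT"):
        raise ValueError(f"motif {motif!r} contains non-ACGT characters")
    pos, _ = _motif_sites(sequence, motif)
    return LabelMap(map_id, len(sequence), _merge_labels(pos, resolution))


# -------------------------------------------------------------- map alignment

@dataclass
class AlignParams:
    """Aligner configuration.

    ``sizing_variance_scale`` (bp) scales the denominator of the sizing
    cost ``(x - y)^2 / (v (x + y) + 1)``; ``match_bonus`` rewards each
    matched label pair; ``miss_penalty`` charges each interior unmatched
    label; ``max_merge`` bounds how many fragments may merge into one
    aligned interval on each side. Significance is a permutation test:
    an alignment is significant iff its score exceeds the score of every
    one of ``n_permutations`` random shufflings of the reference fragment
    order and at least ``min_matched_labels`` labels are matched, i.e. a
    one-sided empirical alpha of 1/(n_permutations + 1).
    """

    sizing_variance_scale: float = 50.0
    match_bonus: float = 5.0
    miss_penalty: float = 3.0
    max_merge: int = 3
    min_matched_labels: int = 9
    n_permutations: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.sizing_variance_scale, self.match_bonus,
               self.miss_penalty) <= 0 or self.max_merge < 1:
            raise ValueError("alignment parameters must be positive, max_merge >= 1")

    @property
    def significance_alpha(self) -> float:
        return 1.0 / (self.n_permutations + 1)


@dataclass
class MapAlignment:
    """Best monotone pairing of two label maps."""

    query_id: str
    ref_id: str
    orientation: str                       # '+' | '-'
    pairs: list[tuple[tuple[int, int], tuple[int, int]]]  # merged index ranges
    score: float
    sizing_cost: float
    missed_query: int
    missed_ref: int
    significant: bool = False

    @property
    def n_matched(self) -> int:
        return len(self.pairs)

    @property
    def query_span(self) -> tuple[int, int]:
        return self.pairs[0][0][0], self.pairs[-1][0][1]

    @property
    def ref_span(self) -> tuple[int, int]:
        return self.pairs[0][1][0], self.pairs[-1][1][1]


def pair_cost(x: float, y: float, v: float) -> float:
    """Sizing cost of aligning query interval x against ref interval y."""
    return (x - y) ** 2 / (v * (x + y) + 1.0)


def _dp_align(q: np.ndarray, r: np.ndarray, p: AlignParams,
              traceback: bool = True):
    """Ends-free DP over matched label pairs; returns (score, pairs, cost, gq, gr)."""
    n, m = q.size, r.size
    B, P, v, d = p.match_bonus, p.miss_penalty, p.sizing_variance_scale, p.max_merge
    S = np.full((n, m), B, dtype=np.float64)
    if traceback:
        BG = np.zeros((n, m), dtype=np.int8)
        BH = np.zeros((n, m), dtype=np.int8)
    for i in range(1, n):
        row = S[i]
        for g in range(1, min(d, i) + 1):
            x = q[i] - q[i - g]
            prev = S[i - g]
            for h in range(1, min(d, m - 1) + 1):
                y = r[h:] - r[:-h]
                cand = prev[:-h] + B - (x - y) ** 2 / (v * (x + y) + 1.0) \
                    - P * (g + h - 2)
                better = cand > row[h:]
                if better.any():
                    row[h:] = np.where(better, cand, row[h:])
                    if traceback:
                        BG[i, h:][better] = g
                        BH[i, h:][better] = h
    flat = int(np.argmax(S))
    i, j = divmod(flat, m)
    best = float(S[i, j])
    if not traceback:
        return best, None, 0.0, 0, 0
    # walk back through the chain of matched pairs
    chain = [(i, j)]
    while BG[i, j]:
        g, h = int(BG[i, j]), int(BH[i, j])
        i, j = i - g, j - h
        chain.append((i, j))
    chain.reverse()
    pairs = []
    cost = 0.0
    gq = gr = 0
    for k, (qi, rj) in enumerate(chain):
        if k == 0:
            pairs.append(((qi, qi), (rj, rj)))
        else:
            pi, pj = chain[k - 1]
            cost += pair_cost(q[qi] - q[pi], r[rj] - r[pj], v)
            gq += qi - pi - 1
            gr += rj - pj - 1
            pairs.append(((pi + 1, qi), (pj + 1, rj)))
    return best, pairs, cost, gq, gr


def _permuted_ref(r: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    frags = np.diff(r)
    return np.concatenate(([r[0]], r[0] + np.cumsum(rng.permutation(frags))))


def map_align(query: LabelMap, ref: LabelMap, params: AlignParams) -> MapAlignment:
    """Best-scoring monotone alignment of ``query`` to ``ref``.

    Both orientations are tried ('+' preferred on ties). Significance is
    assessed by comparing the observed score with ``n_permutations``
    alignments against refs whose fragment order has been shuffled.
    """
    if query.n_labels < 2 or ref.n_labels < 2:
        raise AlignmentError("both maps need at least 2 labels")
    r = ref.labels
    results = {}
    for orient, qmap in (("+", query), ("-", query.reversed())):
        results[orient] = _dp_align(qmap.labels, r, params)
    orient = "+" if results["+"][0] >= results["-"][0] else "-"
    score, pairs, cost, gq, gr = results[orient]
    aln = MapAlignment(query.map_id, ref.map_id, orient, pairs, score, cost, gq, gr)
    if params.n_permutations > 0:
        rng = np.random.default_rng(params.seed)
        q_used = query.labels if orient == "+" else query.reversed().labels
        beaten = True
        for _ in range(params.n_permutations):
            perm_score = _dp_align(q_used, _permuted_ref(r, rng), params,
                                   traceback=False)[0]
            if perm_score >= score:
                beaten = False
                break
        aln.significant = beaten and aln.n_matched >= params.min_matched_labels
    return aln


def best_alignment(query: LabelMap, refs: list[LabelMap],
                   params: AlignParams) -> MapAlignment | None:
    """Best significant alignment over a reference set; ties broken by
    lowest (ref_id, position)."""
    best = None
    for ref in sorted(refs, key=lambda m: m.map_id):
        try:
            aln = map_align(query, ref, params)
        except AlignmentError:
            continue
        if not aln.significant:
            continue
        if best is None or aln.score > best.score:
            best = aln
    return best


# ---------------------------------------------------------- chimera detection

def _submap(m: LabelMap, lo: int, hi: int, suffix: str) -> LabelMap:
    """Sub-map over label index range [lo, hi)."""
    labels = m.labels[lo:hi]
    return LabelMap(f"{m.map_id}{suffix}", m.length, labels)


def detect_chimeras(contig: LabelMap, refs: list[LabelMap],
                    params: AlignParams, *,
                    locus_tolerance: float = 200_000.0) -> list[float]:
    """Split points (bp on the contig) where the two sides of the contig
    align significantly to inconsistent reference loci.

    A contig whose best alignment leaves a flank of at least
    ``min_matched_labels`` labels unaligned, and whose flank aligns
    significantly to a different reference (or to the same reference with a
    positional/orientation conflict beyond ``locus_tolerance``), is reported
    with the breakpoint midway between the two aligned blocks. Contigs with
    no significant alignment are returned as an empty list.
    """
    base = best_alignment(contig, refs, params)
    if base is None:
        return []
    qlo, qhi = base.query_span
    if base.orientation == "-":
        n = contig.n_labels
        qlo, qhi = n - 1 - qhi, n - 1 - qlo
    splits: list[float] = []
    for lo, hi, side in ((0, qlo, "left"), (qhi + 1, contig.n_labels, "right")):
        if hi - lo < params.min_matched_labels:
            continue
        flank = _submap(contig, lo, hi, f"_{side}")
        aln = best_alignment(flank, refs, params)
        if aln is None:
            continue
        conflict = aln.ref_id != base.ref_id or aln.orientation != base.orientation
        if not conflict:
            # same ref, same orientation: require a locus jump
            ref = next(m for m in refs if m.map_id == base.ref_id)
            base_pos = ref.labels[base.ref_span[0]]
            flank_pos = ref.labels[aln.ref_span[0]]
            conflict = abs(float(flank_pos - base_pos)) > locus_tolerance
        if conflict:
            if side == "left":
                split = (contig.labels[hi - 1] + contig.labels[qlo]) / 2.0
            else:
                split = (contig.labels[qhi] + contig.labels[lo]) / 2.0
            splits.append(float(split))
    return sorted(splits)


def split_sequence(seq: str, points: list[float]) -> list[str]:
    """Cut a contig sequence at chimera split points (bp)."""
    cuts = [0] + sorted(int(round(p)) for p in points) + [len(seq)]
    return [seq[a:b] for a, b in zip(cuts[:-1], cuts[1:]) if b > a]


# ------------------------------------------------- placement validation/edits

@dataclass
class FlipEdit:
    seq_id: str
    start: int
    end: int


@dataclass
class MoveEdit:
    seq_id: str
    start: int
    end: int
    target_seq: str
    target_pos: float   # approximate locus on target, current coordinates
    flip: bool = False


@dataclass
class PlacementConflict:
    seq_id: str
    start: int
    end: int
    kind: str           # 'misplaced' | 'misoriented'
    edit: FlipEdit | MoveEdit


def scaffold_segments(assembly: Assembly) -> dict[str, list[tuple[int, int]]]:
    """Per-sequence intervals between 1000-N scaffold joins (0-based
    half-open), the granularity at which placements are validated."""
    out: dict[str, list[tuple[int, int]]] = {}
    for seq_id, seq in assembly.sequences.items():
        joins = [g for g in gapcensus.find_n_runs(seq, seq_id)
                 if g.klass == "placeholder1000"]
        bounds = [0] + [b for g in joins for b in (g.start, g.end)] + [len(seq)]
        out[seq_id] = [(a, b) for a, b in zip(bounds[::2], bounds[1::2]) if b > a]
    return out


@dataclass
class _SegHit:
    """Best significant map alignment of one scaffold segment."""
    seq_id: str
    start: int
    end: int
    map_id: str
    ref_lo: float    # forward-map position of the first matched label
    ref_hi: float    # ... and the last
    d_lo: float      # draft position of the leftmost matched label
    d_hi: float      # ... and the rightmost
    orient: str      # segment orientation relative to the map forward frame

    @property
    def ref_mid(self) -> float:
        return (self.ref_lo + self.ref_hi) / 2.0

    def margin(self, facing_ref_lo: bool) -> float:
        """Unmatched draft bp between the segment edge and the matched
        label corresponding to the given ref endpoint."""
        left_is_ref_lo = self.orient == "+"
        if facing_ref_lo == left_is_ref_lo:
            return self.d_lo - self.start
        return self.end - self.d_hi

    @property
    def draft_mid(self) -> float:
        return (self.start + self.end) / 2.0


def _segment_hits(assembly: Assembly, maps: list[LabelMap],
                  params: AlignParams, motif: str, resolution: int
                  ) -> list[_SegHit]:
    quick = replace(params, n_permutations=0)
    hits = []
    for seq_id, segs in scaffold_segments(assembly).items():
        for start, end in segs:
            seg_map = digest(assembly.sequences[seq_id][start:end], motif,
                             resolution, map_id=f"{seq_id}:{start}-{end}")
            if seg_map.n_labels < params.min_matched_labels:
                continue
            best, best_key = None, None
            for m in sorted(maps, key=lambda m: m.map_id):
                try:
                    aln = map_align(seg_map, m, quick)
                except AlignmentError:
                    continue
                if aln.n_matched < params.min_matched_labels:
                    continue
                key = (-aln.score, m.map_id)
                if best is None or key < best_key:
                    best, best_key = (aln, m), key
            if best is None:
                continue
            aln, m = best
            # confirm the winner with the permutation test
            aln = map_align(seg_map, m, params)
            if not aln.significant:
                continue
            r0 = float(m.labels[aln.pairs[0][1][1]])
            r1 = float(m.labels[aln.pairs[-1][1][1]])
            q_used = seg_map.labels if aln.orientation == "+" else \
                seg_map.reversed().labels
            q0 = float(q_used[aln.pairs[0][0][1]])
            q1 = float(q_used[aln.pairs[-1][0][1]])
            if aln.orientation == "+":
                d_lo, d_hi = start + q0, start + q1
            else:
                seg_len = end - start
                d_lo, d_hi = start + seg_len - q1, start + seg_len - q0
            hits.append(_SegHit(seq_id, start, end, m.map_id, r0, r1,
                                d_lo, d_hi, aln.orientation))
    return hits


def _longest_monotone(values: list[float], increasing: bool) -> set[int]:
    """Indices of a longest strictly monotone subsequence (O(n^2))."""
    v = values if increasing else [-x for x in values]
    n = len(v)
    best_len = [1] * n
    prev = [-1] * n
    for i in range(n):
        for j in range(i):
            if v[j] < v[i] and best_len[j] + 1 > best_len[i]:
                best_len[i] = best_len[j] + 1
                prev[i] = j
    i = max(range(n), key=lambda i: (best_len[i], -i))
    keep = set()
    while i != -1:
        keep.add(i)
        i = prev[i]
    return keep


def validate_placements(assembly: Assembly, maps: list[LabelMap],
                        params: AlignParams, *, motif: str = "GCTCTTC",
                        resolution: int = 1000) -> list[PlacementConflict]:
    """Check each scaffold-level segment of the assembly against the
    optical maps and propose move/flip edits for conflicts.

    Each segment (AGP components joined by 1000-N gaps) is digested and
    aligned to every map; each map is then assigned to the assembly
    sequence contributing most aligned segment length, with a majority
    orientation. Conflicts:

    * *misplaced* — the segment's best map belongs to another sequence
      (proposed move to the map-implied locus there), or its map locus
      breaks the monotone order of its sequence's segments along the map
      (move within the sequence);
    * *misoriented* — the segment aligns opposite to its map's majority
      orientation at its own locus (proposed flip).

    Ordering rather than absolute offsets is checked along each map, so
    length-changing errors elsewhere on the sequence (an inserted foreign
    segment, closed gaps) do not flag innocent neighbours. Detection
    requires maps that bridge the affected scaffold junctions; an
    inversion spanning every map that touches it is undetectable from
    those maps. Segments with too few labels are skipped.
    """
    hits = _segment_hits(assembly, maps, params, motif, resolution)
    # map -> owning sequence: the sequence a map explains the largest
    # FRACTION of (absolute bp would let a bulk misplacement outvote the
    # smaller chromosome it came from); lowest id on ties
    votes: dict[str, dict[str, float]] = {}
    for h in hits:
        frac = (h.end - h.start) / len(assembly.sequences[h.seq_id])
        votes.setdefault(h.map_id, {}).setdefault(h.seq_id, 0)
        votes[h.map_id][h.seq_id] += frac
    owner = {m: sorted(v, key=lambda s: (-v[s], s))[0]
             for m, v in votes.items()}

    # per (owner sequence, map): choose the map frame by parsimony --
    # the orientation implying the fewest segment edits (flips plus
    # order outliers); '+' preferred on ties
    groups: dict[tuple[str, str], list[_SegHit]] = {}
    for h in hits:
        if owner[h.map_id] == h.seq_id:
            groups.setdefault((h.seq_id, h.map_id), []).append(h)
    map_frame: dict[str, str] = {}
    outliers: dict[str, set[int]] = {}   # order outliers only
    for (seq_id, map_id), group in sorted(groups.items()):
        group.sort(key=lambda h: h.start)
        best = None
        for orient in ("+", "-"):
            keep = _longest_monotone([h.ref_mid for h in group],
                                     orient == "+")
            order_bad = {i for i in range(len(group)) if i not in keep}
            n_bad = len(order_bad | {i for i, h in enumerate(group)
                                     if h.orient != orient})
            if best is None or n_bad < best[0]:
                best = (n_bad, orient, order_bad)
        _, map_frame[map_id], outliers[map_id] = best

    def insertion_locus(map_id: str, stray: _SegHit) -> float:
        """Junction position on the owner sequence where the stray
        segment belongs: bracketed between the consistently-placed
        segments around its map locus, refined by the map distance to the
        nearest aligned neighbour (unvalidated small segments may occupy
        part of the bracket, so the map distance arbitrates between the
        candidate junctions inside it)."""
        group = groups[(owner[map_id], map_id)]
        ok = [h for i, h in enumerate(group)
              if i not in outliers.get(map_id, set())] or list(group)
        ok.sort(key=lambda h: h.start)
        sign = 1.0 if map_frame[map_id] == "+" else -1.0
        prev = nxt = None
        for h in ok:
            if sign * (stray.ref_mid - h.ref_mid) < 0:
                nxt = h
                break
            prev = h
        lo = float(prev.end) if prev is not None else 0.0
        hi = float(nxt.start) if nxt is not None else \
            float(len(assembly.sequences[owner[map_id]]))
        # map distance between matched blocks, minus the unmatched draft
        # margins on both sides of the junction
        if prev is not None:
            if sign > 0:
                gap_bp = (stray.ref_lo - prev.ref_hi) \
                    - (prev.end - prev.d_hi) - stray.margin(True)
            else:
                gap_bp = (prev.ref_lo - stray.ref_hi) \
                    - (prev.end - prev.d_hi) - stray.margin(False)
            preferred = lo + max(0.0, gap_bp)
        elif nxt is not None:
            if sign > 0:
                gap_bp = (nxt.ref_lo - stray.ref_hi) \
                    - (nxt.d_lo - nxt.start) - stray.margin(False)
            else:
                gap_bp = (stray.ref_lo - nxt.ref_hi) \
                    - (nxt.d_lo - nxt.start) - stray.margin(True)
            preferred = hi - max(0.0, gap_bp)
        else:
            preferred = lo
        return min(max(preferred, lo), hi)

    conflicts: list[PlacementConflict] = []
    for h in hits:
        if owner[h.map_id] != h.seq_id:
            target = owner[h.map_id]
            pos = insertion_locus(h.map_id, h)
            conflicts.append(PlacementConflict(
                h.seq_id, h.start, h.end, "misplaced",
                MoveEdit(h.seq_id, h.start, h.end, target, pos,
                         flip=h.orient != map_frame[h.map_id])))
    for (seq_id, map_id), group in sorted(groups.items()):
        frame = map_frame[map_id]
        for i, h in enumerate(group):
            if i in outliers[map_id]:
                pos = insertion_locus(map_id, h)
                conflicts.append(PlacementConflict(
                    h.seq_id, h.start, h.end, "misplaced",
                    MoveEdit(h.seq_id, h.start, h.end, seq_id, pos,
                             flip=h.orient != frame)))
            elif h.orient != frame:
                conflicts.append(PlacementConflict(
                    h.seq_id, h.start, h.end, "misoriented",
                    FlipEdit(h.seq_id, h.start, h.end)))
    conflicts.sort(key=lambda c: (c.seq_id, c.start))
    return conflicts


# ---------------------------------------------------------------- apply_edits

@dataclass(eq=False)
class _Block:
    """A run of the output assembly: either original sequence or a join.

    Identity semantics (``eq=False``): blocks are tracked as objects while
    lists are rearranged.
    """
    src_seq: str | None   # None for a synthetic 1000-N join
    start: int            # original coordinates (ignored for joins)
    end: int
    orient: str = "+"
    is_join: bool = False

    def length(self) -> int:
        return 1000 if self.is_join else self.end - self.start


def _split_blocks(blocks: list[_Block], pos: int) -> None:
    """Split the block list (original-coordinate space) at position pos."""
    cur = 0
    for i, b in enumerate(blocks):
        if b.is_join:
            cur += b.length()
            continue
        if cur < pos < cur + b.length():
            off = pos - cur
            left = _Block(b.src_seq, b.start, b.start + off, b.orient)
            right = _Block(b.src_seq, b.start + off, b.end, b.orient)
            blocks[i:i + 1] = [left, right]
            return
        cur += b.length()


class EditConflictError(ValueError):
    """Two edits touch overlapping intervals."""


def apply_edits(assembly: Assembly, edits: list[FlipEdit | MoveEdit]
                ) -> tuple[Assembly, "pd.DataFrame"]:
    """Apply move/flip edits; returns the revised assembly and a lift-over
    table (old_seq, old_start, old_end, new_seq, new_start, orientation).

    1000-N joins are re-emitted at new junctions: a moved segment takes one
    adjacent join with it and is re-joined with fresh 1000-N runs at the
    insertion junction nearest ``target_pos``. Edits must be disjoint.
    """
    import pandas as pd

    intervals: dict[str, list[tuple[int, int]]] = {}
    for e in edits:
        for s, t in intervals.get(e.seq_id, []):
            if e.start < t and s < e.end:
                raise EditConflictError(
                    f"overlapping edits on {e.seq_id}: [{s},{t}) and "
                    f"[{e.start},{e.end})")
        intervals.setdefault(e.seq_id, []).append((e.start, e.end))

    # decompose each sequence into blocks, pre-split at every 1000-N join
    blocks: dict[str, list[_Block]] = {}
    for seq_id, seq in assembly.sequences.items():
        joins = [g for g in gapcensus.find_n_runs(seq, seq_id)
                 if g.klass == "placeholder1000"]
        bl, pos = [], 0
        for g in joins:
            if g.start > pos:
                bl.append(_Block(seq_id, pos, g.start))
            bl.append(_Block(None, g.start, g.end, is_join=True))
            pos = g.end
        if pos < len(seq):
            bl.append(_Block(seq_id, pos, len(seq)))
        blocks[seq_id] = bl

    # split every sequence at every edit boundary first (edit coordinates
    # refer to the input assembly), capturing block objects per edit
    edit_blocks: list[list[_Block]] = []
    for e in edits:
        _split_blocks(blocks[e.seq_id], e.start)
        _split_blocks(blocks[e.seq_id], e.end)
    for e in edits:
        bl = blocks[e.seq_id]
        cur, picked = 0, []
        for b in bl:
            if e.start <= cur and cur + b.length() <= e.end:
                picked.append(b)
            cur += b.length()
        if not picked or sum(b.length() for b in picked) != e.end - e.start:
            raise EditConflictError(
                f"edit [{e.start},{e.end}) does not fall on block boundaries "
                f"of {e.seq_id}")
        edit_blocks.append(picked)

    def locate(bl: list[_Block], picked: list[_Block]) -> tuple[int, int]:
        lo = bl.index(picked[0])
        hi = lo + len(picked)
        if bl[lo:hi] != picked:
            raise EditConflictError("edited blocks are no longer contiguous")
        return lo, hi

    for e, picked in zip(edits, edit_blocks):
        if isinstance(e, FlipEdit):
            bl = blocks[e.seq_id]
            lo, hi = locate(bl, picked)
            flipped = [replace(b, orient="-" if b.orient == "+" else "+")
                       for b in reversed(picked)]
            bl[lo:hi] = flipped
        else:
            seg = picked
            bl = blocks[e.seq_id]
            lo, hi = locate(bl, picked)
            # take one adjacent 1000-N join out with the segment
            if lo > 0 and bl[lo - 1].is_join:
                del bl[lo - 1:hi]
            elif hi < len(bl) and bl[hi].is_join:
                del bl[lo:hi + 1]
            else:
                del bl[lo:hi]
            if e.flip:
                seg = [replace(b, orient="-" if b.orient == "+" else "+")
                       for b in reversed(seg)]
            tgt = blocks[e.target_seq]
            # candidate junctions: sequence start, each join, sequence end
            cur, candidates = 0, [(0.0, "start", 0)]
            for i, b in enumerate(tgt):
                if b.is_join:
                    candidates.append((float(cur), "join", i))
                cur += b.length()
            candidates.append((float(cur), "end", len(tgt)))
            _, where, at = min(candidates,
                               key=lambda c: (abs(c[0] - e.target_pos), c[0]))
            join = _Block(None, 0, 0, is_join=True)
            if where == "start":
                tgt[0:0] = seg + [join]
            elif where == "end":
                tgt.extend([join] + seg)
            else:
                tgt[at + 1:at + 1] = seg + [join]

    # emit sequences and the lift-over table
    new_sequences: dict[str, str] = {}
    rows = []
    for seq_id in assembly.seq_ids:
        parts, cur = [], 0
        for b in blocks[seq_id]:
            if b.is_join:
                parts.append("N" * 1000)
            else:
                s = assembly.sequences[b.src_seq][b.start:b.end]
                if b.orient == "-":
                    s = revcomp(s)
                parts.append(s)
                rows.append((b.src_seq, b.start, b.end, seq_id, cur, b.orient))
            cur += b.length()
        new_sequences[seq_id] = "".join(parts)
    revised = Assembly(new_sequences,
                       assembly.provenance + [f"apply_edits: {len(edits)} edit(s)"])
    table = pd.DataFrame(rows, columns=["old_seq", "old_start", "old_end",
                                        "new_seq", "new_start", "orientation"])
    return revised, table


# ------------------------------------------------------------- CMAP-style I/O

def write_cmap_tsv(maps: list[LabelMap], path) -> None:
    """Simplified CMAP-style TSV: one row per label."""
    import pandas as pd
    rows = [(m.map_id, m.length, m.n_labels, i + 1, float(p))
            for m in maps for i, p in enumerate(m.labels)]
    pd.DataFrame(rows, columns=["map_id", "map_length", "n_labels",
                                "label_index", "label_position"]
                 ).to_csv(path, sep="\t", index=False)


def read_cmap_tsv(path) -> list[LabelMap]:
    import pandas as pd
    df = pd.read_csv(path, sep="\t")
    maps = []
    for map_id, grp in df.groupby("map_id", sort=False):
        grp = grp.sort_values("label_index")
        maps.append(LabelMap(str(map_id), int(grp["map_length"].iloc[0]),
                             grp["label_position"].to_numpy()))
    return maps
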