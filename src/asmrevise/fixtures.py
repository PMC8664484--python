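"""Deterministic synthetic truth: genomes, gapped draft assemblies,
simulated long-read contigs, and simulated optical maps.

The generator emulates a repeat-rich Triticeae-like genome at desk scale
so every downstream stage (placement validation, gap closing, duplication
collapse) can be tested against known truth without external data. All
stochastic draws come from a single numpy Generator per operation, in a
fixed documented order, so outputs are byte-identical for identical seeds
across platforms.

Draft-assembly conventions mirror the pseudomolecule construction they
emulate: 10-N runs link contigs, 100-N runs link hybrid-scaffolding
components, 1000-N runs link adjacent scaffolds; sized gaps emit an N
count equal to their true span. Placeholder gaps record their true span
separately from the emitted N count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .assembly import Assembly, revcomp
from .optical import LabelMap, digest, _motif_sites, _merge_labels

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _decode(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode("ascii")


def _random_seq_codes(rng: np.random.Generator, n: int) -> np.ndarray:
    return rng.integers(0, 4, n, dtype=np.uint8)


def _diverge(rng: np.random.Generator, codes: np.ndarray,
             divergence: float) -> np.ndarray:
    """Copy with ~divergence fraction of positions substituted."""
    out = codes.copy()
    k = rng.binomial(out.size, divergence)
    if k:
        pos = rng.choice(out.size, size=k, replace=False)
        out[pos] = (out[pos] + rng.integers(1, 4, k, dtype=np.uint8)) % 4
    return out


# ------------------------------------------------------------------- records

@dataclass
class SegmentPlacement:
    """Where a draft segment came from in the truth genome."""
    draft_seq: str
    draft_start: int
    draft_end: int
    truth_seq: str
    truth_start: int
    truth_end: int
    orientation: str  # '+' | '-'


@dataclass
class GapTruth:
    """One emitted N-run with its true physical span."""
    draft_seq: str
    draft_start: int
    draft_end: int
    klass: str
    true_span: int
    truth_seq: str
    truth_start: int
    artifact: bool = False  # Fig-2B-style duplication artifact, span 0


@dataclass
class PlantedError:
    kind: str  # misplacement | inversion | flank_duplication | chimeric_contig
    details: dict


@dataclass
class ContigPlacement:
    contig_id: str
    truth_seq: str
    truth_start: int
    truth_end: int
    orientation: str
    part: int = 0  # >0 for chimeric contig parts


@dataclass
class SyntheticTruth:
    """Ground truth for one synthetic experiment."""
    genome: dict[str, str]
    tandem_blocks: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    segment_layout: list[SegmentPlacement] = field(default_factory=list)
    gap_truth: list[GapTruth] = field(default_factory=list)
    planted_errors: list[PlantedError] = field(default_factory=list)
    contig_placements: list[ContigPlacement] = field(default_factory=list)


# ------------------------------------------------------------ genome synthesis

def generate_genome(seed: int, n_chrom: int = 2, chrom_length: int = 1_000_000,
                    tandem_block_rate: float = 10.0,
                    repeat_fraction: float = 0.3) -> SyntheticTruth:
    """Generate a repeat-rich truth genome over {A, C, G, T}.

    Parameters
    ----------
    tandem_block_rate
        Expected tandem-repeat blocks per Mb; block count per chromosome is
        Poisson with this intensity.
    repeat_fraction
        Approximate fraction of each chromosome overwritten with diverged
        copies (1–5% substitution divergence) from a small generated
        library of LTR-like (5–8 kb) and MITE-like (100–500 bp) monomers.
    """
    if n_chrom < 1 or chrom_length < 10_000:
        raise ValueError("need n_chrom >= 1 and chrom_length >= 10 kb")
    if not (0 <= repeat_fraction <= 1) or not np.isfinite(tandem_block_rate) \
            or tandem_block_rate < 0:
        raise ValueError("repeat_fraction must be in [0,1], rates finite "
                         "and non-negative")
    rng = np.random.default_rng(seed)
    # draw order: repeat library, then per chromosome: base sequence,
    # repeat placements, tandem blocks
    library = [_random_seq_codes(rng, int(rng.integers(5_000, 8_001)))
               for _ in range(3)]
    library += [_random_seq_codes(rng, int(rng.integers(100, 501)))
                for _ in range(4)]
    tandem_monomers = [_random_seq_codes(rng, int(rng.integers(10, 201)))
                       for _ in range(6)]
    genome: dict[str, str] = {}
    blocks: dict[str, list[tuple[int, int]]] = {}
    for c in range(1, n_chrom + 1):
        codes = _random_seq_codes(rng, chrom_length)
        target = repeat_fraction * chrom_length
        placed = 0.0
        while placed < target:
            mono = library[int(rng.integers(len(library)))]
            copy = _diverge(rng, mono, rng.uniform(0.01, 0.05))
            if copy.size >= chrom_length:
                break
            pos = int(rng.integers(0, chrom_length - copy.size))
            codes[pos:pos + copy.size] = copy
            placed += copy.size
        chrom_blocks = []
        n_blocks = rng.poisson(tandem_block_rate * chrom_length / 1e6)
        for _ in range(n_blocks):
            mono = _diverge(rng, tandem_monomers[int(rng.integers(6))],
                            rng.uniform(0.0, 0.02))
            block_len = int(rng.integers(500, 3001))
            reps = int(np.ceil(block_len / mono.size))
            block = np.tile(mono, reps)[:block_len]
            if block_len >= chrom_length:
                continue
            pos = int(rng.integers(0, chrom_length - block_len))
            codes[pos:pos + block_len] = block
            chrom_blocks.append((pos, pos + block_len))
        name = f"chr{c}"
        genome[name] = _decode(codes)
        blocks[name] = sorted(chrom_blocks)
    return SyntheticTruth(genome, blocks)


# -------------------------------------------------------- draft fragmentation

@dataclass
class ErrorSpec:
    """A planted error request for :func:`fragment_assembly`.

    kind: 'misplacement' | 'inversion' | 'flank_duplication'.
    seq_id optionally pins the (truth) chromosome; index pins the scaffold
    (misplacement/inversion) or inner 10-N junction (flank_duplication);
    target_seq names the destination chromosome for misplacements.
    """
    kind: str
    seq_id: str | None = None
    index: int | None = None
    target_seq: str | None = None


@dataclass
class _Gap:
    klass: str
    emit_n: int
    true_span: int
    truth_start: int       # start of deleted truth interval
    artifact: bool = False
    dup_len: int = 0       # flank duplication copy length


@dataclass
class _Seg:
    truth_seq: str
    start: int
    end: int


@dataclass
class _Scaffold:
    items: list  # alternating _Seg / inner _Gap, starting+ending with _Seg
    orient: str = "+"


def _choose_cuts(rng, length, n_cuts, blocks, min_seg=6_000, margin=3_000):
    """Junction positions, roughly evenly spaced with jitter, avoiding
    tandem blocks +- margin (a gap landing in a tandem block would mimic
    the duplication artifact the collapse step removes)."""
    forbidden = [(max(0, s - margin), e + margin) for s, e in blocks]
    spacing = length / (n_cuts + 1)
    cuts: list[int] = []
    for i in range(1, n_cuts + 1):
        for _ in range(60):
            c = int(i * spacing + rng.uniform(-0.3, 0.3) * spacing)
            c = min(max(c, min_seg), length - min_seg)
            if not (any(lo <= c < hi for lo, hi in forbidden)
                    or any(abs(c - x) < min_seg for x in cuts)):
                cuts.append(c)
                break
    return sorted(cuts)


def fragment_assembly(truth: SyntheticTruth,
                      placeholder_mix: dict[int, float] | None = None,
                      sized_gap_rate: float = 2.0,
                      error_plan: list[ErrorSpec] | None = None,
                      seed: int = 0, *, seg_mean_bp: int = 60_000,
                      max_span: int = 2_000) -> tuple[Assembly, SyntheticTruth]:
    """Fragment the truth genome into a gapped draft with known gap truth.

    Truth segments are concatenated with N-runs; placeholder junctions
    delete a true span of 1..max_span bp and emit exactly 10/100/1000 Ns
    (mixed per ``placeholder_mix``), sized junctions emit N count equal to
    the deleted span. Requested errors are planted on scaffold-level units
    (misplacement/inversion) or on 10-N junctions (flank duplication).
    """
    placeholder_mix = placeholder_mix or {10: 0.7, 100: 0.2, 1000: 0.1}
    if abs(sum(placeholder_mix.values()) - 1.0) > 1e-9:
        raise ValueError("placeholder_mix proportions must sum to 1")
    if set(placeholder_mix) - {10, 100, 1000}:
        raise ValueError("placeholder_mix keys must be in {10, 100, 1000}")
    rng = np.random.default_rng(seed)
    error_plan = list(error_plan or [])

    # ---------------------------------------------------------- build plans
    plans: dict[str, list] = {}   # chrom -> [_Scaffold, _Gap(1000), _Scaffold...]
    for chrom, seq in truth.genome.items():
        L = len(seq)
        n_junctions = max(1, int(round(L / seg_mean_bp)) - 1)
        cuts = _choose_cuts(rng, L, n_junctions, truth.tandem_blocks.get(chrom, []))
        n_junctions = len(cuts)
        n_sized = min(n_junctions,
                      int(rng.poisson(sized_gap_rate * L / 1e6)))
        # scaffold joins (1000 N) are spread evenly over the junctions so
        # scaffold sizes concentrate around L / (n_scaffolds); the other
        # junction classes are drawn per the mix
        n_1000 = int(round(n_junctions * placeholder_mix.get(1000, 0.0)))
        join_idx = set()
        if n_1000:
            step = n_junctions / n_1000
            join_idx = {min(n_junctions - 1, int((k + 0.5) * step))
                        for k in range(n_1000)}
        rest_mix = {k: v for k, v in placeholder_mix.items() if k != 1000}
        rest_total = sum(rest_mix.values())
        keys = sorted(rest_mix) or [10]
        probs = np.array([rest_mix.get(k, 1.0) / (rest_total or 1.0)
                          for k in keys], dtype=float)
        probs = probs / probs.sum()
        n_rest = n_junctions - len(join_idx)
        n_sized = min(n_rest, n_sized)
        rest_classes = ["sized"] * n_sized
        draws = rng.choice(len(keys), size=n_rest - n_sized, p=probs)
        rest_classes += [f"placeholder{keys[i]}" for i in draws]
        rng.shuffle(rest_classes)
        rest_iter = iter(rest_classes)
        classes = ["placeholder1000" if j in join_idx else next(rest_iter)
                   for j in range(n_junctions)]
        gaps = []
        for c, klass in zip(cuts, classes):
            span = int(rng.integers(1, max_span + 1)) if klass != "sized" \
                else int(rng.integers(100, max_span + 1))
            emit = span if klass == "sized" else int(klass[len("placeholder"):])
            gaps.append((c, _Gap(klass, emit, span, c)))
        # assemble scaffolds: split at 1000-N junctions
        items, plan, prev = [], [], 0
        for c, gap in gaps:
            items.append(_Seg(chrom, prev, c))
            prev = c + gap.true_span
            if gap.klass == "placeholder1000":
                plan.append(_Scaffold(items))
                plan.append(gap)
                items = []
            else:
                items.append(gap)
        items.append(_Seg(chrom, prev, L))
        plan.append(_Scaffold(items))
        plans[chrom] = plan

    # --------------------------------------------------------- plant errors
    def scaffold_span(s: _Scaffold) -> int:
        return sum((it.end - it.start) if isinstance(it, _Seg) else it.emit_n
                   for it in s.items)

    def prefer_large(candidates, chrom_len, key=scaffold_span,
                     floor=150_000):
        # planted structural errors must be detectable: prefer scaffolds
        # large enough to carry a significant label count, but not so
        # large that the rest of the chromosome cannot anchor its map
        # (real misplaced super-scaffolds are a small genome fraction)
        ceiling = chrom_len // 2
        big = [c for c in candidates if floor <= key(c) <= ceiling]
        if not big:
            small = [c for c in candidates if key(c) <= ceiling]
            big = [max(small, key=key)] if small else [min(candidates,
                                                           key=key)]
        return big[int(rng.integers(len(big)))]

    planted: list[PlantedError] = []
    for spec in error_plan:
        chroms = list(plans)
        if spec.kind == "inversion":
            chrom = spec.seq_id or chroms[int(rng.integers(len(chroms)))]
            scaffolds = [x for x in plans[chrom] if isinstance(x, _Scaffold)]
            if not scaffolds:
                raise ValueError(f"no scaffolds on {chrom}")
            if spec.index is not None:
                chosen = scaffolds[spec.index]
            else:
                chosen = prefer_large(scaffolds, len(truth.genome[chrom]))
            chosen.orient = "-"
            planted.append(PlantedError("inversion", {
                "seq_id": chrom, "scaffold_index": scaffolds.index(chosen)}))
        elif spec.kind == "misplacement":
            chrom = spec.seq_id or chroms[0]
            others = [c for c in chroms if c != chrom]
            target = spec.target_seq or others[int(rng.integers(len(others)))]
            plan = plans[chrom]
            sc_pos = [i for i, x in enumerate(plan) if isinstance(x, _Scaffold)]
            if len(sc_pos) < 2:
                raise ValueError(f"{chrom}: need >= 2 scaffolds to misplace one")
            # pick an interior scaffold so a join is adjacent on both sides
            if spec.index is not None:
                at = sc_pos[spec.index]
            else:
                chosen = prefer_large([plan[i] for i in sc_pos[1:]],
                                      len(truth.genome[chrom]))
                at = next(i for i in sc_pos[1:] if plan[i] is chosen)
            scaffold = plan[at]
            # remove the scaffold plus its preceding join gap
            if at > 0:
                del plan[at - 1:at + 1]
            else:
                del plan[at:at + 2]
            tgt = plans[target]
            tgt_sc = [i for i, x in enumerate(tgt) if isinstance(x, _Scaffold)]
            ins_after = tgt_sc[int(rng.integers(max(1, len(tgt_sc) - 1)))]
            join = _Gap("placeholder1000", 1000, int(rng.integers(1, max_span + 1)),
                        -1)
            tgt[ins_after + 1:ins_after + 1] = [join, scaffold]
            planted.append(PlantedError("misplacement", {
                "seq_id": chrom, "target_seq": target}))
        elif spec.kind == "flank_duplication":
            chrom = spec.seq_id or chroms[int(rng.integers(len(chroms)))]
            inner = []
            for x in plans[chrom]:
                if isinstance(x, _Scaffold):
                    for i, it in enumerate(x.items):
                        if isinstance(it, _Gap) and it.klass == "placeholder10":
                            left = x.items[i - 1]
                            if left.end - left.start > 4_000:
                                inner.append((x, i))
            if not inner:
                raise ValueError(f"no eligible 10-N junction on {chrom}")
            k = spec.index if spec.index is not None \
                else int(rng.integers(len(inner)))
            scaffold, i = inner[k]
            gap = scaffold.items[i]
            left = scaffold.items[i - 1]
            dup = int(rng.integers(1_200, min(2_500, left.end - left.start - 1_000)))
            # the junction becomes an artifact: nothing was really missing
            gap.true_span = 0
            gap.artifact = True
            gap.dup_len = dup
            # the deleted span no longer exists: shift the downstream segment
            nxt = scaffold.items[i + 1]
            restored = nxt.start - (gap.truth_start)
            nxt.start = gap.truth_start
            planted.append(PlantedError("flank_duplication", {
                "seq_id": chrom, "dup_len": dup, "restored_span": restored}))
        else:
            raise ValueError(f"unknown error kind {spec.kind!r}")

    # --------------------------------------------------------------- emission
    sequences: dict[str, str] = {}
    layout: list[SegmentPlacement] = []
    gap_truth: list[GapTruth] = []
    for chrom in truth.genome:
        parts: list[str] = []
        pos = 0
        plan = plans[chrom]
        for item in plan:
            if isinstance(item, _Gap):  # 1000-N scaffold join
                gap_truth.append(GapTruth(chrom, pos, pos + item.emit_n,
                                          item.klass, item.true_span,
                                          item.truth_seq if hasattr(item, "truth_seq")
                                          else chrom, item.truth_start))
                parts.append("N" * item.emit_n)
                pos += item.emit_n
                continue
            # scaffold: build its string and per-item offsets
            sub_parts: list[str] = []
            sub_meta: list[tuple] = []  # (offset, length, item)
            off = 0
            for it in item.items:
                if isinstance(it, _Seg):
                    s = truth.genome[it.truth_seq][it.start:it.end]
                    sub_parts.append(s)
                    sub_meta.append((off, len(s), it))
                    off += len(s)
                else:
                    if it.artifact and it.dup_len:
                        left = None
                        for o, ln, prev_it in reversed(sub_meta):
                            if isinstance(prev_it, _Seg):
                                left = prev_it
                                break
                        sub_parts.append("N" * it.emit_n)
                        sub_meta.append((off, it.emit_n, it))
                        off += it.emit_n
                        dup_seq = truth.genome[left.truth_seq][
                            left.end - it.dup_len:left.end]
                        sub_parts.append(dup_seq)
                        sub_meta.append((off, it.dup_len, ("dup", left, it.dup_len)))
                        off += it.dup_len
                    else:
                        sub_parts.append("N" * it.emit_n)
                        sub_meta.append((off, it.emit_n, it))
                        off += it.emit_n
            scaff = "".join(sub_parts)
            if item.orient == "-":
                scaff = revcomp(scaff)
            slen = len(scaff)
            for o, ln, it in sub_meta:
                if item.orient == "-":
                    d_start, d_end = pos + slen - (o + ln), pos + slen - o
                else:
                    d_start, d_end = pos + o, pos + o + ln
                if isinstance(it, _Seg):
                    layout.append(SegmentPlacement(chrom, d_start, d_end,
                                                   it.truth_seq, it.start,
                                                   it.end, item.orient))
                elif isinstance(it, _Gap):
                    gap_truth.append(GapTruth(chrom, d_start, d_end, it.klass,
                                              it.true_span, chrom,
                                              it.truth_start,
                                              artifact=it.artifact))
            parts.append(scaff)
            pos += slen
        sequences[chrom] = "".join(parts)
    gap_truth.sort(key=lambda g: (g.draft_seq, g.draft_start))
    layout.sort(key=lambda s: (s.draft_seq, s.draft_start))
    out_truth = SyntheticTruth(truth.genome, truth.tandem_blocks, layout,
                               gap_truth, planted, [])
    return Assembly(sequences, ["fragment_assembly"]), out_truth


# ------------------------------------------------------------ contig sampling

def simulate_contigs(truth: SyntheticTruth, n50_target: int = 50_000,
                     error_rate: float = 0.0, chimera_rate: float = 0.0,
                     seed: int = 0, *, min_overlap: int = 8_000,
                     max_overlap: int = 15_000
                     ) -> tuple[dict[str, str], SyntheticTruth]:
    """Sample long-read-like contigs tiling the truth genome.

    Contig lengths are uniform in [0.5, 1.5] x n50_target; successive
    contigs overlap by at least ``min_overlap`` bp so any short interval
    (a gap plus anchoring flanks) is fully contained in some contig. With
    probability ``chimera_rate`` a contig joins two unlinked truth
    intervals; the junction is recorded as a planted error. Substitution
    errors are applied at ``error_rate`` per bp.
    """
    if not (0 <= error_rate <= 0.05):
        raise ValueError("error_rate must be in [0, 0.05]")
    if not (0 <= chimera_rate <= 1):
        raise ValueError("chimera_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    contigs: dict[str, str] = {}
    placements: list[ContigPlacement] = []
    errors: list[PlantedError] = []
    n = 0
    chroms = list(truth.genome)
    for chrom in chroms:
        seq = truth.genome[chrom]
        L = len(seq)
        pos = 0
        while pos < L:
            length = int(rng.uniform(0.5, 1.5) * n50_target)
            end = min(pos + length, L)
            n += 1
            name = f"ctg{n:05d}"
            piece = seq[pos:end]
            chimeric = rng.random() < chimera_rate
            if chimeric:
                other = chroms[int(rng.integers(len(chroms)))]
                oL = len(truth.genome[other])
                plen = max(1, length // 2)
                opos = int(rng.integers(0, max(1, oL - plen)))
                part2 = truth.genome[other][opos:opos + plen]
                junction = len(piece)
                final = piece + part2
            else:
                final = piece
            orient = "+" if rng.random() < 0.5 else "-"
            if orient == "-":
                final = revcomp(final)
            if error_rate > 0:
                codes = np.frombuffer(final.encode(), dtype=np.uint8).copy()
                lut = np.zeros(256, dtype=np.uint8)
                lut[[65, 67, 71, 84]] = [0, 1, 2, 3]
                k = rng.binomial(len(final), error_rate)
                if k:
                    p = rng.choice(len(final), size=k, replace=False)
                    newc = (lut[codes[p]] + rng.integers(1, 4, k)) % 4
                    codes[p] = _BASES[newc]
                final = codes.tobytes().decode()
            contigs[name] = final
            if chimeric:
                errors.append(PlantedError("chimeric_contig", {
                    "contig_id": name,
                    "junction": len(final) - junction if orient == "-" else junction,
                    "parts": [(chrom, pos, end), (other, opos, opos + plen)],
                    "orientation": orient}))
                placements.append(ContigPlacement(name, chrom, pos, end, orient, 1))
                placements.append(ContigPlacement(name, other, opos, opos + plen,
                                                  orient, 2))
            else:
                placements.append(ContigPlacement(name, chrom, pos, end, orient))
            if end >= L:
                break
            pos = end - int(rng.integers(min_overlap, max_overlap + 1))
    out = SyntheticTruth(truth.genome, truth.tandem_blocks,
                         truth.segment_layout, truth.gap_truth,
                         truth.planted_errors + errors, placements)
    return contigs, out


# ------------------------------------------------------------- optical maps

def simulate_optical_map(target, motif: str = "GCTCTTC", resolution: int = 1000,
                         fragile_window: int = 100, sizing_cv: float = 0.0,
                         p_miss: float = 0.0, false_per_100kb: float = 0.0,
                         seed: int = 0) -> list[LabelMap]:
    """Simulate consensus nick-site maps of a genome or single sequence.

    Labels sit at motif occurrences on either strand; labels closer than
    ``resolution`` merge to their midpoint. Opposite-strand occurrences
    within ``fragile_window`` bp mark fragile sites where molecules break,
    so the consensus map splits there. Noise: per-label dropout ``p_miss``,
    spurious labels at ``false_per_100kb``, and fragment sizing noise with
    coefficient of variation ``sizing_cv``.
    """
    if not motif:
        raise ValueError("motif must be non-empty")
    if not (0 <= p_miss <= 1) or sizing_cv < 0 or false_per_100kb < 0:
        raise ValueError("noise parameters out of range")
    if isinstance(target, SyntheticTruth):
        seqs = target.genome
    elif isinstance(target, Assembly):
        seqs = target.sequences
    elif isinstance(target, dict):
        seqs = target
    else:
        seqs = {"seq": str(target)}
    rng = np.random.default_rng(seed)
    maps: list[LabelMap] = []
    for seq_id, seq in seqs.items():
        pos, strand = _motif_sites(seq, motif)
        breaks: list[int] = []
        if fragile_window > 0:
            for i in range(pos.size - 1):
                if strand[i] != strand[i + 1] and strand[i] != 0 and \
                        strand[i + 1] != 0 and pos[i + 1] - pos[i] <= fragile_window:
                    breaks.append(int((pos[i] + pos[i + 1]) // 2))
        bounds = [0] + breaks + [len(seq)]
        for k, (lo, hi) in enumerate(zip(bounds[:-1], bounds[1:])):
            if hi - lo < 2:
                continue
            piece = pos[(pos >= lo) & (pos < hi)] - lo
            labels = _merge_labels(piece, resolution)
            if p_miss > 0 and labels.size:
                keep = rng.random(labels.size) >= p_miss
                labels = labels[keep]
            n_false = rng.poisson(false_per_100kb * (hi - lo) / 1e5)
            if n_false:
                labels = np.sort(np.concatenate(
                    [labels, rng.uniform(0, hi - lo, n_false)]))
                labels = labels[np.concatenate(([True], np.diff(labels) > 0))]
            if sizing_cv > 0 and labels.size >= 2:
                frags = np.diff(labels)
                frags = np.maximum(1.0, frags * (1 + rng.normal(0, sizing_cv,
                                                                frags.size)))
                labels = np.concatenate(([labels[0]],
                                         labels[0] + np.cumsum(frags)))
            length = max(hi - lo, int(np.ceil(labels[-1])) + 1 if labels.size else 0)
            maps.append(LabelMap(f"{seq_id}_om{k}", length, labels,
                                 {"source_seq": seq_id, "source_start": lo,
                                  "source_end": hi}))
    return maps
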