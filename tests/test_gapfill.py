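"""Contig placement, gap closing, duplication collapse, and lift-over."""

import numpy as np
import pytest

from asmrevise import fixtures as fx
from asmrevise import gapcensus as gc
from asmrevise import gapfill as gf
from asmrevise.assembly import Assembly, revcomp


# ------------------------------------------------------------- place_contigs

def test_place_contigs_recovers_truth_placements(small_truth):
    contigs, t = fx.simulate_contigs(small_truth, n50_target=40_000,
                                     error_rate=0, chimera_rate=0, seed=41)
    asm = Assembly(dict(small_truth.genome))
    placements = gf.place_contigs(asm, contigs)
    best = {}
    for p in placements:
        if p.contig_id not in best or p.aligned_bp > best[p.contig_id].aligned_bp:
            best[p.contig_id] = p
    for tp in t.contig_placements:
        p = best[tp.contig_id]
        assert (p.seq_id, p.asm_start, p.asm_end, p.orientation) == \
            (tp.truth_seq, tp.truth_start, tp.truth_end, tp.orientation)
        assert p.identity == 1.0
        assert (p.contig_start, p.contig_end) == \
            (0, len(contigs[tp.contig_id]))


def test_place_contigs_absent_contig_unplaced(small_truth):
    rng = np.random.default_rng(42)
    foreign = "".join(rng.choice(list("ACGT"), 30_000))
    asm = Assembly(dict(small_truth.genome))
    assert gf.place_contigs(asm, {"foreign": foreign}) == []


def test_place_contigs_reverse_complement_orientation(small_truth):
    locus = small_truth.genome["chr1"][50_000:90_000]
    asm = Assembly(dict(small_truth.genome))
    placements = gf.place_contigs(asm, {"rc": revcomp(locus)})
    best = max(placements, key=lambda p: p.aligned_bp)
    assert best.orientation == "-"
    assert (best.asm_start, best.asm_end) == (50_000, 90_000)


def test_place_contigs_empty_set_and_bad_k(small_truth):
    asm = Assembly({"s": small_truth.genome["chr1"][:30_000]})
    assert gf.place_contigs(asm, {}) == []
    with pytest.raises(ValueError):
        gf.place_contigs(asm, {"c": "ACGT" * 100}, anchor_k=10)


# ----------------------------------------------------------------- fill_gaps

@pytest.fixture(scope="module")
def filled(small_truth, small_draft, small_contigs):
    draft, truth = small_draft
    contigs, _ = small_contigs
    placements = gf.place_contigs(draft, contigs)
    patched, log = gf.fill_gaps(draft, contigs, placements)
    return draft, truth, patched, log


def test_fill_closes_every_spanned_gap_exactly(small_truth, filled):
    draft, truth, patched, log = filled
    assert log.n_fills() == len(truth.gap_truth)
    assert patched.sequences == small_truth.genome


def test_fill_does_not_touch_non_n_bases(filled):
    draft, truth, patched, log = filled
    for seq_id, seq in draft.sequences.items():
        new = patched.sequences[seq_id]
        edits = log.for_seq(seq_id)
        pos_old = pos_new = 0
        for e in edits:
            assert seq[pos_old:e.old_start] == new[pos_new:pos_new +
                                                   (e.old_start - pos_old)]
            pos_new += (e.old_start - pos_old) + e.new_length
            pos_old = e.old_end
        assert seq[pos_old:] == new[pos_new:]


def test_fill_census_accounting(filled):
    """Closing k gaps reduces the census gap_number by exactly k."""
    draft, truth, patched, log = filled
    before = gc.census(draft).total_row()
    after = gc.census(patched).total_row()
    assert before["gap_number"] - after["gap_number"] == log.n_fills()
    assert after["effective_length"] >= before["effective_length"]


def test_fill_leaves_unspanned_gap_open():
    seq = "ACGTTGCA" * 200 + "N" * 10 + "TTGACGTC" * 200
    asm = Assembly({"s": seq})
    patched, log = gf.fill_gaps(asm, {}, [])
    assert log.n_fills() == 0
    assert patched.sequences["s"] == seq


def test_fill_sized_gap_span_tolerance(small_truth):
    """A sized gap only closes when the contig-implied span agrees with
    the recorded N count."""
    chrom = small_truth.genome["chr1"]
    cut, span = 60_000, 400
    draft = Assembly({"chr1": chrom[:cut] + "N" * span + chrom[cut + span:]})
    contig = {"c": chrom[cut - 5_000:cut + span + 5_000]}
    placements = gf.place_contigs(draft, contig)
    patched, log = gf.fill_gaps(draft, contig, placements)
    assert log.n_fills() == 1
    assert patched.sequences["chr1"] == chrom
    # same contig, but the draft lies about the span by > 50%
    wrong = Assembly({"chr1": chrom[:cut] + "N" * 1200 + chrom[cut + span:]})
    placements = gf.place_contigs(wrong, contig)
    _, log2 = gf.fill_gaps(wrong, contig, placements)
    assert log2.n_fills() == 0


# ------------------------------------------------------------------ collapse

def test_collapse_removes_planted_duplication(small_truth):
    draft, t = fx.fragment_assembly(
        small_truth, {10: 1.0}, sized_gap_rate=0,
        error_plan=[fx.ErrorSpec("flank_duplication", "chr1")], seed=43)
    err = t.planted_errors[0]
    patched, log = gf.collapse_duplication_artifacts(draft)
    assert log.n_collapses() == 1
    e = log.edits[0]
    assert e.meta["overlap"] == err.details["dup_len"]
    # locally equal to truth: the duplicated copy and the gap are gone
    clean, _ = fx.fragment_assembly(small_truth, {10: 1.0}, sized_gap_rate=0,
                                    seed=43)
    artifact_gap = next(g for g in t.gap_truth if g.artifact)
    assert len(patched.sequences["chr1"]) == \
        len(draft.sequences["chr1"]) - err.details["dup_len"] - 10
    assert gc.census(patched).frame.loc["chr1", "gap_number"] == \
        gc.census(draft).frame.loc["chr1", "gap_number"] - 1


def test_collapse_ignores_ordinary_gaps(small_draft):
    draft, truth = small_draft
    patched, log = gf.collapse_duplication_artifacts(draft)
    assert log.n_collapses() == 0
    assert patched.sequences == draft.sequences


def test_collapse_shortens_while_fill_lengthens(small_truth):
    """Release-notes direction-of-change contract: collapsing reduces
    total length; filling increases effective length."""
    draft, t = fx.fragment_assembly(
        small_truth, {10: 1.0}, sized_gap_rate=0,
        error_plan=[fx.ErrorSpec("flank_duplication", "chr2")], seed=44)
    collapsed, _ = gf.collapse_duplication_artifacts(draft)
    assert collapsed.total_length() < draft.total_length()
    contigs, _ = fx.simulate_contigs(t, n50_target=40_000, seed=45)
    placements = gf.place_contigs(collapsed, contigs)
    patched, _ = gf.fill_gaps(collapsed, contigs, placements)
    b, a = gc.census(collapsed).total_row(), gc.census(patched).total_row()
    assert a["effective_length"] > b["effective_length"]


# ------------------------------------------------------------------ liftover

def build_log():
    # fill of a 10-N gap at [100,110) with 250 bp; collapse of
    # [500,510) gap with 200 bp duplicated flank at [300,510)
    edits = [
        gf.Edit("fill", "s", 100, 110, 250),
        gf.Edit("collapse", "s", 300, 510, 0, meta={"gap_start": 500}),
    ]
    return gf.EditLog(edits, sequences={"s"})


def test_liftover_before_edits_unchanged():
    assert gf.liftover(build_log(), "s", 50) == 50


def test_liftover_shift_after_fill():
    # fill delta +240
    assert gf.liftover(build_log(), "s", 200) == 440


def test_liftover_inside_replaced_n_run_maps_to_start():
    assert gf.liftover(build_log(), "s", 105) == 100


def test_liftover_inside_collapsed_copy_maps_to_retained_copy():
    log = build_log()
    # offset 30 into the deleted copy [300,500) -> same offset in the
    # retained copy, which lands where the deleted copy began (+fill delta)
    assert gf.liftover(log, "s", 330) == 300 + 240 + 30
    # position after both edits: shifted by +240 - 210
    assert gf.liftover(log, "s", 600) == 630


def test_liftover_round_trip_identity_outside_edits():
    log = build_log()
    rng = np.random.default_rng(46)
    for pos in rng.integers(0, 5_000, 200):
        pos = int(pos)
        if 100 <= pos < 110 or 300 <= pos < 510:
            continue
        new = gf.liftover(log, "s", pos)
        assert gf.liftover(log, "s", new, direction="new_to_old") == pos


def test_liftover_unknown_sequence_errors():
    with pytest.raises(gf.LiftoverError):
        gf.liftover(build_log(), "nope", 0)


def test_lift_gff3_round_trip_unedited_features(filled):
    draft, truth, patched, log = filled
    lines = []
    rng = np.random.default_rng(47)
    edited = {(e.seq_id, e.old_start, e.old_end) for e in log.edits}
    for i in range(50):
        seq_id = list(draft.sequences)[i % 2]
        start = int(rng.integers(0, len(draft.sequences[seq_id]) - 300))
        end = start + 200
        if any(s == seq_id and start < oe and os < end
               for s, os, oe in edited):
            continue
        lines.append(f"{seq_id}\tsrc\tgene\t{start + 1}\t{end}\t.\t+\t."
                     f"\tID=g{i}")
    lifted = gf.lift_gff3(log, lines)
    back_log = log  # same edits; invert by direction
    restored = []
    for line in lifted:
        f = line.split("\t")
        s = gf.liftover(log, f[0], int(f[3]) - 1, "new_to_old") + 1
        e = gf.liftover(log, f[0], int(f[4]) - 1, "new_to_old") + 1
        f[3], f[4] = str(s), str(e)
        restored.append("\t".join(f))
    assert restored == lines


def test_fill_right_to_left_preserves_multigap_sequences(small_truth):
    """Several fills on one sequence compose correctly (applied
    right-to-left so earlier coordinates stay valid)."""
    chrom = small_truth.genome["chr2"]
    cuts = [40_000, 90_000, 150_000]
    parts, prev = [], 0
    for c in cuts:
        parts.append(chrom[prev:c])
        parts.append("N" * 10)
        prev = c + 700   # placeholder hides a 700 bp true span
    parts.append(chrom[prev:])
    draft = Assembly({"chr2": "".join(parts)})
    contigs = {f"c{i}": chrom[c - 6_000:c + 7_000] for i, c in enumerate(cuts)}
    placements = gf.place_contigs(draft, contigs)
    patched, log = gf.fill_gaps(draft, contigs, placements)
    assert log.n_fills() == 3
    assert patched.sequences["chr2"] == chrom


def test_paf_round_trip(tmp_path, small_truth):
    contigs, t = fx.simulate_contigs(small_truth, n50_target=40_000, seed=48)
    asm = Assembly(dict(small_truth.genome))
    placements = gf.place_contigs(asm, contigs)
    lines = []
    for p in placements:
        lines.append("\t".join(map(str, [
            p.contig_id, p.contig_length, p.contig_start, p.contig_end,
            p.orientation, p.seq_id, len(asm.sequences[p.seq_id]),
            p.asm_start, p.asm_end, int(p.identity * p.aligned_bp),
            p.aligned_bp, 60])))
    path = tmp_path / "aln.paf"
    path.write_text("\n".join(lines) + "\n")
    again = gf.read_paf(path)
    assert len(again) == len(placements)
    for a, b in zip(again, placements):
        assert (a.contig_id, a.seq_id, a.asm_start, a.asm_end,
                a.orientation) == (b.contig_id, b.seq_id, b.asm_start,
                                   b.asm_end, b.orientation)
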