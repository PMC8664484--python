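"""Digestion, ordered-map DP alignment (vs exhaustive enumeration),
chimera detection, placement validation, and edit application."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from asmrevise import fixtures as fx
from asmrevise import optical as op
from asmrevise.assembly import Assembly, revcomp

MOTIF, RC = "GCTCTTC", "GAAGAGC"


# -------------------------------------------------------------------- digest

def test_digest_single_site():
    seq = "A" * 500 + MOTIF + "A" * 400
    m = op.digest(seq, resolution=0)
    assert list(m.labels) == [500]


def test_digest_reverse_strand_site():
    seq = "A" * 300 + RC + "A" * 400
    m = op.digest(seq, resolution=0)
    assert list(m.labels) == [300]


def test_digest_merges_to_midpoint():
    seq = "A" * 500 + MOTIF + "A" * 393 + RC + "A" * 93
    m = op.digest(seq, resolution=1000)
    assert list(m.labels) == [700]


def test_digest_all_n_yields_no_labels():
    assert op.digest("N" * 10_000).n_labels == 0


def test_digest_rejects_bad_motif():
    with pytest.raises(ValueError):
        op.digest("ACGT" * 100, motif="GCT")
    with pytest.raises(ValueError):
        op.digest("ACGT" * 100, motif="GCTNTTC")


@given(st.integers(0, 2**31 - 1))
@settings(max_examples=25, deadline=None, derandomize=True)
def test_digest_reverse_complement_symmetry(seed):
    """Label positions of the reverse complement mirror the original."""
    rng = np.random.default_rng(seed)
    seq = "".join(rng.choice(list("ACGT"), 5_000))
    fwd = op.digest(seq, resolution=800)
    rev = op.digest(revcomp(seq), resolution=800)
    mirrored = np.sort(len(seq) - len(MOTIF) - fwd.labels)
    assert np.allclose(rev.labels, mirrored)


# ----------------------------------------------------- DP vs brute force

def chain_score(q, r, chain, p):
    """Score an explicit monotone chain of matched label pairs, straight
    from the definition: one bonus per pair, sizing cost per aligned
    interval, a penalty per interior unmatched label."""
    score = p.match_bonus
    for (i0, j0), (i1, j1) in zip(chain, chain[1:]):
        score += p.match_bonus \
            - op.pair_cost(q[i1] - q[i0], r[j1] - r[j0],
                           p.sizing_variance_scale) \
            - p.miss_penalty * ((i1 - i0 - 1) + (j1 - j0 - 1))
    return score


def brute_force_best(q, r, p):
    """Enumerate every monotone chain with merge runs <= max_merge."""
    n, m = len(q), len(r)
    best = -np.inf
    stack = [[(i, j)] for i in range(n) for j in range(m)]
    while stack:
        chain = stack.pop()
        best = max(best, chain_score(q, r, chain, p))
        i, j = chain[-1]
        for g in range(1, p.max_merge + 1):
            for h in range(1, p.max_merge + 1):
                if i + g < n and j + h < m:
                    stack.append(chain + [(i + g, j + h)])
    return best


def random_map_pair(rng, max_labels=8):
    nq = int(rng.integers(2, max_labels + 1))
    nr = int(rng.integers(2, max_labels + 1))
    q = np.cumsum(rng.integers(500, 20_000, nq)).astype(float)
    r = np.cumsum(rng.integers(500, 20_000, nr)).astype(float)
    qmap = op.LabelMap("q", int(q[-1]) + 500, q)
    rmap = op.LabelMap("r", int(r[-1]) + 500, r)
    return qmap, rmap


def test_dp_matches_brute_force_on_random_small_maps():
    rng = np.random.default_rng(2024)
    p = op.AlignParams(n_permutations=0, seed=0)
    for _ in range(150):
        qmap, rmap = random_map_pair(rng)
        aln = op.map_align(qmap, rmap, p)
        expect = max(brute_force_best(qmap.labels, rmap.labels, p),
                     brute_force_best(qmap.reversed().labels, rmap.labels, p))
        assert aln.score == pytest.approx(expect, abs=1e-9)
        # the reported pairs must reproduce the reported score
        used = qmap.labels if aln.orientation == "+" else \
            qmap.reversed().labels
        chain = [(a[1], b[1]) for a, b in aln.pairs]
        assert chain_score(used, rmap.labels, chain, p) == \
            pytest.approx(aln.score, abs=1e-9)


def test_map_align_identity():
    rng = np.random.default_rng(1)
    labels = np.cumsum(rng.integers(2_000, 9_000, 12)).astype(float)
    m = op.LabelMap("m", int(labels[-1]) + 100, labels)
    aln = op.map_align(m, m, op.AlignParams(n_permutations=50, seed=1))
    assert aln.orientation == "+"
    assert aln.n_matched == 12
    assert aln.sizing_cost == 0
    assert aln.missed_query == aln.missed_ref == 0
    assert aln.significant


def test_map_align_interior_deletion_merges():
    rng = np.random.default_rng(3)
    labels = np.cumsum(rng.integers(2_000, 9_000, 10)).astype(float)
    ref = op.LabelMap("ref", int(labels[-1]) + 100, labels)
    query = op.LabelMap("q", ref.length, np.delete(labels, 5))
    p = op.AlignParams(n_permutations=0, seed=0)
    aln = op.map_align(query, ref, p)
    assert aln.orientation == "+"
    assert aln.missed_query == 0
    assert aln.missed_ref == 1          # the deleted label is merged over
    assert aln.score == pytest.approx(
        brute_force_best(query.labels, ref.labels, p), abs=1e-9)


def test_map_align_reversed_query():
    rng = np.random.default_rng(4)
    labels = np.cumsum(rng.integers(2_000, 9_000, 12)).astype(float)
    ref = op.LabelMap("ref", int(labels[-1]) + 100, labels)
    aln = op.map_align(ref.reversed(), ref,
                       op.AlignParams(n_permutations=50, seed=2))
    assert aln.orientation == "-"
    assert aln.sizing_cost == 0
    assert aln.n_matched == 12


def test_map_align_rejects_tiny_maps():
    m = op.LabelMap("m", 1000, np.array([500.0]))
    big = op.LabelMap("b", 10_000, np.cumsum([1_000.0] * 5))
    with pytest.raises(op.AlignmentError):
        op.map_align(m, big, op.AlignParams(seed=0))


def test_random_maps_are_not_significant():
    rng = np.random.default_rng(9)
    q = op.LabelMap("q", 200_000,
                    np.cumsum(rng.integers(2_000, 20_000, 12)).astype(float))
    r = op.LabelMap("r", 200_000,
                    np.cumsum(rng.integers(2_000, 20_000, 15)).astype(float))
    aln = op.map_align(q, r, op.AlignParams(seed=3))
    assert not aln.significant


# ---------------------------------------------------------- chimera detection

@pytest.fixture(scope="module")
def chimera_setup():
    truth = fx.generate_genome(seed=21, n_chrom=2, chrom_length=600_000,
                               tandem_block_rate=5, repeat_fraction=0.2)
    refs = [op.digest(seq, map_id=name) for name, seq in truth.genome.items()]
    params = op.AlignParams(min_matched_labels=6, seed=5)
    return truth, refs, params


def test_detect_chimeras_finds_planted_junction(chimera_setup):
    truth, refs, params = chimera_setup
    contigs, t = fx.simulate_contigs(truth, n50_target=400_000,
                                     chimera_rate=1.0, seed=22)
    err = next(e for e in t.planted_errors if e.kind == "chimeric_contig")
    name = err.details["contig_id"]
    cmap = op.digest(contigs[name], map_id=name)
    splits = op.detect_chimeras(cmap, refs, params)
    assert len(splits) >= 1
    junction = err.details["junction"]
    labels = cmap.labels
    # planted junction within one label spacing of a reported split
    dist = min(abs(s - junction) for s in splits)
    spacing = np.diff(labels).max()
    assert dist <= spacing


def test_detect_chimeras_clean_contig_empty(chimera_setup):
    truth, refs, params = chimera_setup
    contigs, t = fx.simulate_contigs(truth, n50_target=400_000,
                                     chimera_rate=0.0, seed=23)
    name = next(iter(contigs))
    cmap = op.digest(contigs[name], map_id=name)
    assert op.detect_chimeras(cmap, refs, params) == []


def test_detect_chimeras_unaligned_contig_empty(chimera_setup):
    _, refs, params = chimera_setup
    rng = np.random.default_rng(6)
    random_seq = "".join(rng.choice(list("ACGT"), 400_000))
    cmap = op.digest(random_seq, map_id="random")
    if cmap.n_labels < 2:
        pytest.skip("degenerate random digest")
    assert op.detect_chimeras(cmap, refs, params) == []


# --------------------------------------------------- validation + apply_edits

MIX = {10: 0.55, 100: 0.15, 1000: 0.3}


@pytest.fixture(scope="module")
def validation_truth():
    return fx.generate_genome(seed=31, n_chrom=2, chrom_length=800_000,
                              tandem_block_rate=8, repeat_fraction=0.25)


@pytest.fixture(scope="module")
def validation_maps(validation_truth):
    return fx.simulate_optical_map(validation_truth, fragile_window=0,
                                   seed=32)


def test_validate_clean_assembly_no_conflicts(validation_truth,
                                              validation_maps):
    draft, _ = fx.fragment_assembly(validation_truth, MIX, sized_gap_rate=2,
                                    seed=33)
    conflicts = op.validate_placements(draft, validation_maps,
                                       op.AlignParams(seed=7))
    assert conflicts == []


def test_validate_recovers_planted_inversion(validation_truth,
                                             validation_maps):
    draft, t = fx.fragment_assembly(
        validation_truth, MIX, sized_gap_rate=2,
        error_plan=[fx.ErrorSpec("inversion", "chr1")], seed=34)
    conflicts = op.validate_placements(draft, validation_maps,
                                       op.AlignParams(seed=7))
    assert len(conflicts) == 1
    c = conflicts[0]
    assert c.kind == "misoriented"
    inv = [s for s in t.segment_layout if s.orientation == "-"]
    assert c.start == min(s.draft_start for s in inv)
    assert c.end == max(s.draft_end for s in inv)
    # applying the proposed flip restores the error-free draft
    revised, lift = op.apply_edits(draft, [c.edit])
    clean, _ = fx.fragment_assembly(validation_truth, MIX, sized_gap_rate=2,
                                    seed=34)
    assert revised.sequences == clean.sequences
    flipped = lift[(lift["old_seq"] == "chr1")
                   & (lift["orientation"] == "-")]
    assert len(flipped) >= 1


def test_validate_recovers_planted_misplacement(validation_truth,
                                                validation_maps):
    draft, t = fx.fragment_assembly(
        validation_truth, MIX, sized_gap_rate=2,
        error_plan=[fx.ErrorSpec("misplacement", "chr1", target_seq="chr2")],
        seed=35)
    conflicts = op.validate_placements(draft, validation_maps,
                                       op.AlignParams(seed=7))
    assert len(conflicts) == 1
    c = conflicts[0]
    assert c.kind == "misplaced"
    assert c.seq_id == "chr2"            # the stray segment sits on chr2
    assert c.edit.target_seq == "chr1"   # and belongs on chr1
    revised, _ = op.apply_edits(draft, [c.edit])
    clean, _ = fx.fragment_assembly(validation_truth, MIX, sized_gap_rate=2,
                                    seed=35)
    assert revised.sequences == clean.sequences


def test_apply_edits_empty_is_identity(validation_truth):
    draft, _ = fx.fragment_assembly(validation_truth, MIX, seed=36)
    revised, lift = op.apply_edits(draft, [])
    assert revised.sequences == draft.sequences
    assert (lift["old_start"] == lift["new_start"]).all()
    assert (lift["old_seq"] == lift["new_seq"]).all()


def test_apply_edits_flip_is_reverse_complement():
    asm = Assembly({"s": "ACGTACGTGG" + "N" * 1000 + "TTTTACCGGA"})
    revised, _ = op.apply_edits(asm, [op.FlipEdit("s", 0, 10)])
    assert revised.sequences["s"][:10] == revcomp("ACGTACGTGG")
    assert revised.sequences["s"][1010:] == "TTTTACCGGA"


def test_apply_edits_conserves_base_multiset(validation_truth):
    """Moves and flips neither create nor destroy non-N sequence."""
    from collections import Counter
    draft, _ = fx.fragment_assembly(
        validation_truth, MIX, sized_gap_rate=2,
        error_plan=[fx.ErrorSpec("inversion", "chr1")], seed=37)
    revised, _ = op.apply_edits(
        draft, [op.FlipEdit("chr1", 0, op.scaffold_segments(draft)["chr1"][0][1]),
                op.MoveEdit("chr2", 0,
                            op.scaffold_segments(draft)["chr2"][0][1],
                            "chr1", 0.0)])
    def bases(a):
        # flips reverse-complement, so count complement pairs
        c = Counter()
        for s in a.sequences.values():
            t = s.replace("N", "")
            c["AT"] += t.count("A") + t.count("T")
            c["CG"] += t.count("C") + t.count("G")
            c["len"] += len(t)
        return c
    assert bases(revised) == bases(draft)


def test_apply_edits_rejects_overlapping_edits():
    asm = Assembly({"s": "ACGT" * 1000})
    with pytest.raises(op.EditConflictError):
        op.apply_edits(asm, [op.FlipEdit("s", 0, 100),
                             op.FlipEdit("s", 50, 150)])


def test_cmap_tsv_round_trip(tmp_path, validation_maps):
    path = tmp_path / "maps.tsv"
    op.write_cmap_tsv(validation_maps, path)
    again = op.read_cmap_tsv(path)
    assert [m.map_id for m in again] == [m.map_id for m in validation_maps]
    for a, b in zip(again, validation_maps):
        assert np.array_equal(a.labels, b.labels)
        assert a.length == b.length
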