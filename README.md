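# asmrevise

Desk-scale genome **assembly revision** and annotation QC: validate and
correct scaffold placement against nick-site optical maps, close
placeholder N-gaps with long-read contig sequence, collapse duplication
artifacts at tandem repeats, grade gene models from homology evidence,
classify small-RNA reads, and keep the before/after census books.

The workflow it implements is the one used to turn a draft Triticeae
pseudomolecule assembly into a gap-closed release (the *Aegilops
tauschii* Aet v4.0 → v5.0 revision is the motivating example, and its
published census tables ship with the package as worked-example inputs).
It is aimed at assembly engineers and methods students who want every
stage — including the ordered-map aligner — as inspectable, tested
Python rather than a black box, runnable on synthetic data at the scale
of a laptop.

## The methods at the core

* **Gap taxonomy and census.** Draft pseudomolecules encode joins as
  N-runs of conventional size — 10 N (assembler contig links), 100 N
  (hybrid scaffolding), 1000 N (scaffold joins) — alongside *sized* gaps
  whose N count estimates the span. The census reports, per
  pseudomolecule, total length, gap length, effective length
  (total − gap, "length without Ns") and gap number, with differences
  printed as new − old.

* **Ordered-map alignment.** Optical maps are ordered nick-site label
  lists (Nt.BspQI, `GCTCTTC`); alignment compares inter-label fragment
  lengths, not bases. The aligner is an ends-free dynamic program over
  monotone label pairings with bounded fragment merging: score
  `Σ(B − (x−y)²/(v(x+y)+1)) − P·(interior unmatched labels)`, both
  orientations tried, and significance calibrated by a permutation test
  (score must beat all shuffled-reference re-alignments). The DP is
  verified exact against exhaustive enumeration.

* **Placement validation.** Scaffold-level segments are digested in
  silico and aligned to the maps; maps are assigned to sequences by the
  fraction of the sequence they explain and to a reading frame by
  parsimony. Segments that land on another sequence's map, break the
  monotone segment order along their map, or align in the wrong
  orientation yield move/flip edit proposals, which `apply_edits` turns
  into a revised assembly plus a lift-over table.

* **Gap closing.** A gap closes iff one contig anchors both flanks
  (≥ 500 aligned bp within 100 bp of each edge, collinear, same
  orientation); the contig subsequence between the anchor points
  replaces the Ns — gaps close entirely or not at all. Flank
  duplications spanning 10-N gaps (the tandem-repeat scaffolding
  artifact) are detected by near-identical left-suffix/right-prefix
  overlap and collapsed. All edits maintain a bidirectional coordinate
  lift-over.

* **Gene grading (HC/LC/REP).** Completeness plus best hits against
  curated (UniMag), Poaceae (UniPoa) and transposon-protein (PTREP)
  databases, with strict thresholds (E < 1e-10, coverage > 95%); silent
  evidence shapes grade `unclassified`, and all 54 shapes are pinned by
  a committed truth table.

* **Small RNAs.** Size profiles (total vs distinct), hc-siRNA
  attribution (21–24 nt on TEs, per superfamily), tRF classes (5-tRF /
  i-tRF / 3-tRF with nine positional bins via `ceil(9·start/len)`), and
  polycistron grouping of pre-miRNAs separated by < 3000 nt.

See `docs/methods.md` for the full model descriptions, parameter
defaults, and known limitations.

## Worked example

Generate a 2 × 1 Mb synthetic genome with a known truth, fragment it
into a gapped draft with three planted errors (an inverted scaffold, a
scaffold moved between chromosomes, and a duplicated gap flank), then
run the full revision pipeline:

```python
from asmrevise import fixtures as fx, optical as op, gapcensus as gc, report as rp
from asmrevise.pipeline import revise_assembly

truth = fx.generate_genome(seed=11, n_chrom=2, chrom_length=1_000_000,
                           tandem_block_rate=8, repeat_fraction=0.25)
plan = [fx.ErrorSpec("inversion", "chr1"),
        fx.ErrorSpec("misplacement", "chr2", target_seq="chr1"),
        fx.ErrorSpec("flank_duplication", "chr1")]
draft, t = fx.fragment_assembly(truth, {10: 0.55, 100: 0.15, 1000: 0.3},
                                sized_gap_rate=3, error_plan=plan, seed=12)
maps = fx.simulate_optical_map(truth, fragile_window=0, seed=13)
contigs, t = fx.simulate_contigs(t, n50_target=60_000, seed=14)

res = revise_assembly(draft, maps, contigs, align_params=op.AlignParams(seed=7))
print(res.summary)
print(rp.compare_censuses(gc.census(draft), gc.census(res.assembly)).to_string())
print("identical to truth:", res.assembly.sequences == truth.genome)
```

prints

```
{'conflicts': 2, 'collapsed_artifacts': 1, 'gaps_closed': 31,
 'gap_number_change': -32, 'total_length_change': 8863,
 'effective_length_change': 25275}
            total_length  gap_length  effective_length  gap_number
chr1             -179551      -10295           -169256         -19
chr2              188414       -6117            194531         -13
Difference          8863      -16412             25275         -32
identical to truth: True
```

Reading the numbers: the two structural conflicts are the planted
inversion (a flip edit) and the planted misplacement (chr1 loses the
~160 kb foreign scaffold back to chr2 — hence the opposite per-sequence
total-length changes); the collapsed artifact removes the duplicated
flank and its 10-N gap; all 31 real gaps close, so gap_number drops by
32 (31 fills + 1 collapsed artifact), effective length rises by the
recovered sequence, and the final assembly equals the truth genome
byte for byte.

The same stages are scriptable from the shell:

```bash
asmrevise simulate --seed 3 --n-chrom 2 --chrom-length 500000 --outdir sim/
asmrevise validate --fasta sim/draft.fasta --maps sim/maps.cmap.tsv --seed 1 --apply
asmrevise collapse --fasta validated.fasta
asmrevise fill --fasta collapsed.fasta --contigs sim/contigs.fasta
asmrevise census --fasta filled.fasta --table-out census.tsv
asmrevise check-tables
```

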