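# Methods

`asmrevise` re-implements, at desk scale, the workflow used to revise a
draft pseudomolecule assembly into a gap-closed release: structural
validation against nick-site optical maps, closing of placeholder N-gaps
with long-read contig sequence, removal of duplication artifacts at
tandem repeats, and the accompanying annotation QC (gene-model grading,
small-RNA classification, census bookkeeping). This note records the
models, the parameters that matter, and the choices made where the
design was genuinely open.

## Gap taxonomy and census

Draft Triticeae pseudomolecules encode joins as N-runs with conventional
sizes: 10 N between assembler contigs, 100 N between hybrid-scaffolding
components, 1000 N between adjacent scaffolds and super-scaffolds; any
other length is a *sized* gap whose N count estimates the physical span.
Classification is by exact length only — a real gap whose span happens
to be exactly 10/100/1000 bp is operationally indistinguishable from a
placeholder, and is treated as one. Runs of ambiguity codes other than N
are not gaps; the parser rejects them rather than guessing.

Coordinates are 0-based half-open internally; AGP output is 1-based
inclusive per AGP v2.1. The census reports, per sequence, total length,
gap length, effective length (total minus gap; "length without Ns"),
and gap count; the Total row is always recomputed from the per-sequence
rows, and before/after comparisons print new − old, so a release that
shrinks overall while gaining real sequence shows a negative
total-length difference next to a positive effective-length difference.

## Optical maps

### Model

A map is an ordered list of label positions (bp). Labels mark
occurrences of the nicking-endonuclease motif (default Nt.BspQI,
`GCTCTTC`) on either strand, recorded at the motif start on
forward-strand coordinates: the enzyme's nick offset is constant and
cancels in all fragment arithmetic, so it is not modelled. Labels closer
than `resolution` (default 1000 bp) merge to the midpoint of the cluster
extremes, emulating instrument resolution. Opposite-strand nick sites
within `fragile_window` bp (default 100) produce double-strand breaks
during sample handling, so simulated consensus maps split there.

Noise model of the simulator: per-label dropout with probability
`p_miss`; spurious labels as a Poisson process (`false_per_100kb`);
multiplicative fragment sizing error with coefficient of variation
`sizing_cv` (mean relative error `cv·√(2/π)`). All draws come from one
numpy Generator per call in a fixed order, so identical seeds give
byte-identical fixtures.

### Alignment

The aligner is a classic ordered-restriction-map dynamic program over
monotone pairings of labels. Up to `max_merge` (default 3) adjacent
fragments may merge into one aligned interval per side, absorbing missed
or unresolved labels. Scoring: each matched pair earns `match_bonus`
(B = 5); each aligned interval pays a sizing cost
`(x − y)² / (v(x + y) + 1)`; each interior unmatched label pays
`miss_penalty` (3). Alignment is ends-free (unmatched flanks are free);
both query orientations are tried, `+` preferred on ties.

The scale `v = 50` bp was calibrated so that, at Nt.BspQI-like label
density (~1 label / 8 kb), pairing two *random* fragments costs ≈ 15 —
well above the match bonus — while true pairings under realistic sizing
noise (cv ≈ 5%) cost ≪ 1. A larger `v` makes random chaining profitable
and lets alignments creep across chimeric junctions; a much smaller one
over-penalizes long merged fragments.

Significance is a permutation test, not a closed-form P-value: an
alignment is significant iff its score beats all `n_permutations`
(default 100) re-alignments against references whose fragment order has
been shuffled, and at least `min_matched_labels` (default 9) labels are
matched — an empirical one-sided alpha of 1/101. The proprietary
significance cutoffs used with commercial map software do not transfer
to this scoring, so no equivalence is claimed.

The DP is exact: a property suite checks it against exhaustive
enumeration of every monotone alignment on random map pairs with up to
8 labels.

### Placement validation

Scaffold-level segments (AGP components joined by 1000-N gaps) are
digested in silico and aligned to every map. Each map is then assigned
to the assembly sequence it explains the largest *fraction* of
(absolute aligned bp would let a bulk misplacement outvote the smaller
chromosome it came from), and a map reading frame (`+`/`−`) is chosen
by parsimony: the orientation implying the fewest segment edits (flips
plus order outliers). Conflicts:

* **misplaced** — the segment's best map belongs to another sequence, or
  its map locus breaks the monotone order of its sequence's segments
  along the map (longest-monotone-subsequence outlier). The proposed
  move targets the junction bracketed by the consistently-placed
  neighbours around its map locus, refined by map distance minus the
  unmatched label margins at the segment edges.
* **misoriented** — the segment aligns opposite to its map's frame at
  its own locus; the proposed edit is a flip.

Order, not absolute offset, is what is checked along each map: an
insertion or deletion elsewhere on the sequence shifts every downstream
offset but preserves order, so innocent neighbours are not flagged.

Detection limits (inherent, not implementation artifacts): a segment
whose digest carries fewer than `min_matched_labels` labels cannot be
validated; an inversion is invisible to a map set in which no map
bridges the inverted scaffold's junctions; if nearly all of a
chromosome's content is moved away, the residue may be too small to
anchor that chromosome's map and ownership becomes undecidable. The
end-to-end recovery fixtures therefore use unsplit chromosome-scale
consensus maps and plant errors on scaffolds of 150 kb – L/2 (about 18
expected labels at default density, and a residual chromosome that
still anchors its map). Fragile-site splitting, chimera detection, and
noise models are exercised in their own tests.

`apply_edits` resolves all edit coordinates against the input assembly
(blocks are pre-split and tracked by identity), re-emits 1000-N joins at
new junctions, takes one adjacent join out with a moved segment, and
returns a block-level lift-over table. Edits must be disjoint.

## Gap closing

Contigs are placed by unique exact k-mer anchors (k = 21) grouped by
diagonal, split at assembly N-runs, extended outward on the diagonal
through repeat regions that lack unique k-mers (stopping at N or a run
of 10 consecutive mismatches), and scored by ungapped identity. This is
a deliberate desk-scale stand-in for whole-genome alignment; externally
computed placements in minimal 12-column PAF are accepted equivalently.

A gap closes iff a single contig anchors both flanks: an alignment
block of ≥ `min_anchor_bp` (500) ending within `max_edge_distance`
(100 bp) of the left edge and another starting within the same distance
of the right edge, same orientation, collinear. The contig subsequence
between the flank anchor points replaces the N-run — nothing outside
the N-run is modified, and gaps close entirely or not at all (no
one-sided shrinking). Placeholder gaps accept any implied span ≥ 1;
sized gaps require agreement with the recorded span within a relative
`span_tolerance` of 0.5. Competing contigs are ranked by total anchored
bp, then identity, then contig id; an exact tie (possible only with
duplicate ids) is a hard error rather than an arbitrary choice.
Anchoring thresholds are declared defaults, not values inherited from
any published pipeline.

### Duplication artifacts

Erroneous scaffolding across a tandem-repeat block can emit the same
flank twice around a 10-N gap (dot-plot signature: a duplicated segment
interrupted by the gap). For every placeholder gap the suffix of the
left 25-kb window is compared with the prefix of the right window:
first by exact longest-overlap (KMP border), then, failing that, by an
edlib probe alignment accepting ≥ `min_identity` (0.99). An overlap of
≥ `min_overlap` (1000 bp) abutting the gap on both sides is collapsed:
the gap and one copy are removed, shortening the sequence while raising
its effective length. In the common case (the two copies are literal
duplicates created by the mis-join) the exact path gives base-precise
boundaries; with diverged copies the fuzzy path's boundary is
approximate.

The pipeline runs collapse before placement/fill, because a
duplication's second copy would otherwise shadow the k-mer uniqueness of
its flank.

### Lift-over

Fills and collapses accumulate in an edit log defining a
piecewise-affine monotone map: coordinates outside edited intervals map
bijectively (both directions); positions inside a replaced N-run map to
the replacement start; positions inside a collapsed copy map to the
retained copy. GFF3 features on unedited regions survive a round trip
byte-identically.

## Gene-model grading

Proteins are graded from completeness plus best BLAST hits against a
curated protein set (UniMag), a Poaceae set (UniPoa), and a hypothetical
transposon-protein set (PTREP). A hit is significant when its E-value is
strictly below `evalue_max` and the database-appropriate coverage —
subject coverage for the protein sets, query coverage for PTREP — is
strictly above `coverage_min` (95). The stated cutoff "10e-10" is read
as 1 × 10⁻¹⁰ by default; the literal reading (1e-9) ships as an
alternative preset.

The decision table: HC is a complete protein with a UniMag hit whose
subject *and* query coverage pass, or a complete protein absent from
UniMag with a significant UniPoa hit and no significant PTREP hit; REP
is complete, UniMag-absent, with a significant PTREP hit (evaluated
before the LC fallback); LC is an incomplete protein with a significant
UniMag or UniPoa hit and no significant PTREP hit, or a complete protein
with no hit anywhere. Every shape the rules leave silent (e.g. complete
with only a sub-threshold UniMag hit) grades `unclassified` — never
silently HC or LC. All 2 × 3³ = 54 evidence shapes are pinned by a
committed truth table, and grading is threshold-monotone (raising the
coverage floor never converts LC to HC).

BUSCO-style coverage is 100·(total − missing)/total, one decimal.

## Small RNAs

Reads are 18–34 nt (trimming bounds enforced at construction). Size
profiles are reported for all reads and for distinct sequences — the
diagnostic that separates a few abundant 21-nt miRNAs (total-count peak
only) from diverse 24-nt heterochromatic siRNAs (peak in both).
hc-siRNA counting admits only 21–24-nt reads overlapping an annotated
TE feature, categorized by superfamily attribute. tRFs are classified on
the mature tRNA (1-based): start = 1 → 5-tRF; end = length → 3-tRF;
otherwise i-tRF, with 5-tRF precedence for reads spanning the whole
molecule (a declared convention — the boundary case is not standardised).
The 5′-position bin is `ceil(9·start/length)`; nine equal bins are a
declared default (typical cleavage-position binning without a canonical
formula), configurable. Pre-miRNA loci on the same sequence separated by
strictly fewer than 3000 intervening nucleotides (end-to-start, not
start-to-start) group by single linkage; clusters of ≥ 2 are reported as
potential polycistrons. Multimapping reads count once per
classification; fractional weighting is off by default.

## Census validation

`validate_totals` checks declared part-of relations over labelled
counts: integer columns exactly, percentage columns within 0.01 (two
printed decimals). The shipped reference tables — the published
Aet v4.0/v5.0 pseudomolecule censuses, TE class census, intact LTR-RT
counts, gene-annotation summary, RGA counts, and BUSCO categories — all
pass; the interspersed-TE percentage column needs the rounding
tolerance (its parts sum to 86.64 against a printed 86.65), which is
itself asserted by a test.

## Synthetic data: what it does and does not emulate

The generator produces repeat-rich genomes (diverged copies of LTR-like
5–8 kb and MITE-like 100–500 bp monomers, plus tandem monomer blocks at
a Poisson per-Mb rate), fragments them into drafts with the three-way
placeholder taxonomy and recorded true spans, samples overlapping
contigs (uniform 0.5–1.5 × N50; minimum overlap 8 kb, larger than any
gap footprint, so every gap is spanned by construction), and simulates
consensus maps with the noise model above. Junctions avoid tandem
blocks — a real gap inside a tandem block is indistinguishable from the
duplication artifact — and are spread roughly evenly so scaffold sizes
are usable for validation at any seed.

What passing the end-to-end tests shows: with error-free contigs and
noise-free junction-bridging maps, the pipeline's bookkeeping is exact —
planted misplacement, inversion and flank duplication are recovered and
the patched assembly is byte-identical to the truth; with 0.5% contig
error, filled intervals match truth at ≥ 99% identity. What it does not
show: robustness to real long-read error profiles (indels dominate
there; the contig simulator only substitutes), to collapsed or
polymorphic repeats beyond the simple copy-paste model, to molecule-level
map assembly artifacts, or to scales beyond a few Mb. Default problem
sizes — 2 × 1 Mb in the test suite, 2 × 800 kb in the acceptance script
— were chosen as the smallest at which scaffolds, maps and contigs keep
realistic relative granularity.

## Numerical and degenerate-input choices

Ties in alignment orientation go to `+`; among equal-scoring reference
loci the lowest (ref_id, position) wins. A map whose fragments are all
equal is never significant under the permutation test (shuffling is a
no-op) — correct behaviour for an information-free map. Maps need ≥ 2
labels to align; segments below the label floor are skipped, not
guessed. Lift-over rejects unknown sequence ids. Empty contig sets and
empty edit lists are identities, not errors.
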