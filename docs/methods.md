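# Methods

This note records the models, conventions and numerical choices behind
`its2otu`, in the order the pipeline applies them.

## Read-level filtering

Reads are demultiplexed by 5′-anchored Hamming comparison of the barcode
(fixed-length library barcodes admit no indels; default 0 mismatches
allowed) and of the forward primer immediately after it (IUPAC codes on
the primer side are expanded; default ≤2 substitutions). The reverse
primer is removed cutadapt-style: an interior occurrence is located by
infix edit-distance search (edlib), so substitutions and indels both
count toward the overall error rate (default 0.15); when the primer runs
off the 3′ end, prefixes of ≥8 nt are matched against the read suffix by
substitution counting only — indels are not modelled in an 8–28 nt
overlap, where they are both rare and poorly identifiable. Reads lacking
the reverse primer are kept by default (`require_rev_primer` inverts
this), matching standard adapter-trimming behaviour.

Quality screening is purely sequence-based, in fixed order: any
ambiguous base discards the read (default `max_ambiguous` 0), then a
homopolymer run *strictly longer* than `max_homopolymer` (default 4,
so a run of 5 fails), then post-trim length < `min_length` (default
250 nt). Base qualities, when present, are carried through but never
consulted. The filter report books every read exactly once
(`input = kept + Σ discarded`), with barcode failures under a
`_unassigned` pseudo-sample.

Dereplication collapses identical strings into unique variants with
per-sample counts; singletons (total count 1 across the whole data set)
are removed after chimera flagging.

## Chimera flagging

The flagger is a deliberately simple abundance-skew, two-parent,
single-crossover model: a variant is flagged when some split point
leaves its 5′ segment within one mismatch of one parent and its 3′
segment within one mismatch of a *different* parent, both parents at
least 2× more abundant, while no single candidate explains the variant
to within two mismatches. Comparisons are positional (Hamming), so only
equal-length parents are considered and unequal-length variants are
never flagged. The stage is pluggable; users with access to a full
chimera detector can substitute its calls. Flagging runs on the pooled
table by default (per-sample mode available), since cross-sample
abundance gives the better parent estimates.

## Distances

Both clustering tiers use one distance definition: the uncorrected
p-distance on a pairwise global alignment. Alignment is
Needleman–Wunsch with affine gaps (Gotoh), scores +2/−2 and gap
open/extend −4/−2; a gap of length k costs `open + (k−1)·extend`.
Traceback ties are resolved deterministically (diagonal, then up, then
left), and each unordered pair is aligned in canonical (lexicographic)
order, so distance matrices are exactly symmetric and runs are
bit-reproducible. The distance counts each mismatched base column as
one difference over one comparable position; under the default gap
policy each maximal internal gap run counts as one difference over one
position (`gap_run_counts_as="each"` counts columns instead), and
terminal gap columns are excluded. Computing both tiers from pairwise
alignments rather than a per-clade multiple alignment removes the MSA
dependency and keeps every distance well defined; the calibration
module exists precisely so cut-offs are re-derived under this
convention rather than inherited from other toolchains.

The dynamic-programming fill is JIT-compiled (numba) with a pure-numpy
fallback, and a provable fast path handles the dominant case of
equal-length, few-substitution pairs: a gapped alignment of equal-length
sequences with g≥1 gap columns per sequence scores at most
`(L−g)·match + 2(open + (g−1)·extend)`, so whenever
`k·(match−mismatch) ≤ match − 2·open` (k ≤ 2 under the defaults) the
gap-free alignment is optimal and the distance is exactly k/L.

A consequence worth knowing: in homopolymer-rich or repeat-structured
contexts a gapped alignment can legitimately outscore the
substitution-only one, and with terminal gaps excluded the resulting
distance can fall below k/L. This mirrors the behaviour of any
alignment-based distance and is covered by a property test.

## Two-tier clustering

Average-neighbour clustering merges, at each step, the pair of clusters
with the smallest average inter-cluster distance, while that average is
≤ the cut-off (closed threshold); ties take the lowest index pair. The
implementation uses the Lance–Williams update and is checked in the
test suite against both a naive re-averaging agglomeration and cutting
scipy's UPGMA dendrogram.

Clades are the clusters at the coarse cut-off (default 0.15), numbered
by descending read count; clade labels are structural, and human-
readable identities come only from annotation of each cluster's
representative. Within each clade, the length screen discards a variant
when the fraction of the clade's variants strictly longer than it is ≥
0.90 — the direct reading of "shorter than 90% of sequences" (an
equal-length clade therefore discards nothing). OTUs are then formed at
the fine cut-off (default 0.03). Each OTU's representative is its most
abundant member, ties broken by lexicographically smallest sequence.

Annotation is an exhaustive nearest-reference search: the query is
globally aligned to every database entry and percent identity is
`100·(1 − d)` under the same gap policy. Ties go to the first entry in
database order and are reported; ties and identities below 90% are
labelled `unclassified_<clade>` rather than forced onto a type.

## Cut-off calibration

`intragenomic_stats` restricts a control sample to variants with ≥100
reads *in that sample* (the floor is per-sample, matching the
per-culture framing of the statistics; it guards against contamination
and ultralow-abundance artefacts) and reports mean, median, min, max
and range of all pairwise distances; fewer than two qualifying variants
yields an explicit insufficient-variants result, never silent zeros.
The median of an even number of distances is the midpoint of the two
central values. `derive_species_cutoff` clusters each control's
qualifying variants at every grid value (default 0.01–0.10 in 0.01
steps, bracketing typical species-level cut-offs cheaply) and returns
the smallest value at which every control collapses to one OTU; because
average-linkage merge heights are monotone, per-control OTU counts are
non-increasing along the grid, which is asserted in tests.
`clade_cutoff_check` scores candidate coarse cut-offs against known
clade labels with the adjusted Rand index.

## Summaries

Rank abundance sorts a sample's variants by count (ties lexicographic
by sequence). The dominance fold is top/second count; top-N fractions
sum the leading fractions. Rarefaction is computed analytically as the
hypergeometric expectation `E[S_n] = Σ_i (1 − C(N−N_i, n)/C(N, n))`
in log-gamma space — the exact expectation of the usual resampling
procedure — with a seeded Monte-Carlo mode for cross-checking.

## The simulator

The generator emulates the structure the pipeline is built for, with
defaults chosen once as the study conditions:

- **Genome model** — one (or two) dominant ITS2 copies carrying 80% of
  the copy mass, 30 rare variants within 0.02 uncorrected distance of a
  dominant (substitution mutants; 1..⌊0.02·L⌋ changes each), frequencies
  decaying geometrically (ratio 0.7). Dominant templates are ~320 nt,
  drawn per clade with homopolymer runs capped at 4 (an amplifiable
  template must survive the homopolymer filter) and inter-clade
  divergence forced >0.15 by rejection sampling; rare variants that
  would acquire a filter-failing run are redrawn for the same reason.
- **Copy-number bias** — read sampling weights are cell proportion ×
  `rdna_copy_weight`, so mixtures reproduce the qualitative result that
  lineages with more rDNA copies dominate read counts at equal cell
  input.
- **Read model** — reads are barcode + forward primer + mutated
  template + reverse primer. Default error rates emulate
  flowgram-denoised 454 reads, which is what a base-called pipeline of
  this kind consumes: substitutions at 2×10⁻⁴ per base, homopolymer ±1
  indels at 10⁻³ per run of ≥3, chimeras (two templates, one uniform
  crossover away from the ends) at a configurable rate, 0 by default.
- **Determinism** — every function takes a seed or Generator; the same
  seed gives byte-identical output.

What the simulator does *not* emulate: flowgram-level noise and
quality-score structure, PCR-cycle-correlated chimera formation,
length variation among intragenomic variants (rare variants are
substitution-only), and real ITS2 secondary-structure constraints.
Passing tests therefore demonstrate the pipeline's logic — collapse of
intragenomic variation, clade separation, calibration recovery — not
performance on raw, un-denoised instrument output.

## Problem sizes and defaults in the checks

The bundled checks run the full pipeline on 8 000–10 000 reads per
design, yielding on the order of 100–200 retained unique variants —
ample to exercise every stage while keeping a desk-scale footprint.
The calibration design uses three 6 000-read control cultures. All
sizes are stated in `scripts/acceptance.py` and the tests themselves.

## Known limitations

- Average-neighbour clustering is O(n³) overall; fine for the few
  hundred to few thousand unique variants typical after dereplication
  and singleton removal, not for raw-read-scale inputs.
- The chimera flagger trades sensitivity for transparency; it only
  models single-crossover, equal-length, high-skew chimeras.
- Barcode matching admits no indels; severely indel-corrupted barcodes
  are discarded rather than rescued.
- Distances between sequences from different clades are reported but —
  as for any alignment of effectively non-homologous sequences — should
  be read as "large", not as meaningful estimates; this is exactly why
  clade binning precedes the fine tier.
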