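# Methods

This note documents the models and numerical choices behind `rrnmap`: what
each stage assumes, which parameters matter, what the simulator does and
does not emulate, and the design decisions taken where the problem left
room.

## Markers and preprocessing

Two amplicons are supported: the full-length 16S rRNA gene (nominal
1,500 bp) and the 16S-ITS-23S span of the *rrn* operon (nominal 4,300 bp).
Each marker fixes a length-selection window — 16S: [1,200, 1,800] bp,
*rrn*: [3,500, 5,000] bp — and a minimum alignment block for assignment
(1,000 and 3,000 columns respectively). Windows are inclusive on both
bounds, the conservative reading of a range given without open/closed
detail, and are applied *after* the fixed 45 bp end trim, matching the
order of operations in the protocol the pipeline models (tags and primers
are trimmed, then reads are size-selected). Reads that would be empty after
trimming are rejected rather than erroring.

## Alignment

Mapping is minimizer seeding → diagonal chaining → banded local extension:

* **Minimizers**: window minima (k=15, w=10) of a splitmix64-hashed 2-bit
  k-mer encoding, indexed on the reference forward strands; the read is
  scanned on both strands. K-mers containing N are never selected, and N
  never counts as a match in alignment.
* **Chaining**: anchors to one reference are sorted by diagonal
  (ref − read position) and split where consecutive diagonals jump by more
  than 100; clusters with ≥ 3 anchors become extension candidates, ranked
  by anchor count, at most 6 per read and 2 per (reference, strand) — the
  second cluster exists so both segments of a chimera are seen.
* **Extension**: affine-gap local DP (match +2, mismatch −4, gap open −4,
  extend −2; a gap of length L costs 4 + 2L) inside a band around the chain
  diagonal, with z-drop 70: once the running best score falls 70 below the
  maximum the extension stops and the alignment is trimmed back to its
  maximum. The scoring mirrors minimap2's defaults so block-length and AS
  thresholds quoted for minimap2 output transfer directly. The band
  half-width defaults to max(100, 0.05 × read length) (~215 at 4.3 kb);
  indel drift at 11% total error has a standard deviation of ~15 bases over
  4.3 kb, so the band is >10 sigma while keeping the DP cheap. A fixed
  `band_width` can be set instead.
* **AS score** is exactly the local alignment score of the reported
  interval; `block_length` counts all alignment columns including gaps
  (PAF column-11 convention); `identity` = matches / columns. Hits are
  sorted by AS with ties broken by reference id then leftmost start, and at
  most `max_secondary`+1 = 6 are reported. Coordinates are 0-based
  half-open on the forward read everywhere.
* `smith_waterman` is the exact full-matrix implementation of the same
  scoring (the band is widened to cover the whole matrix and z-drop
  disabled); it is the oracle in the tests and usable on small inputs.

Degenerate cases: an empty database cannot be indexed (error); a reference
shorter than k indexes zero minimizers with a warning; a read with no
shared seeds simply returns no hits.

## Chimera scrubbing

Coverage profiles union the read intervals of all hits with multiplicity ≥
`min_cov` (default 1). A read is **chimeric** when (a) an internal
uncovered run ≥ 100 bp separates two covered intervals, or (b) two hits
from *different* references support read segments ≥ 400 bp each whose
overlap is < 20% of the shorter segment. Rule (b) is deliberate: against a
*complete* database the two parent alignments of a chimera abut at the
junction — the uncovered run between them is typically only a few bases and
frequently negative (the alignments overlap slightly) — so a pure coverage-gap
rule has essentially zero sensitivity there. Split-alignment support is the
observable signature and carries the detector's sensitivity; the gap rule
still catches junctions into sequence absent from the database. The 400 bp
segment floor keeps short conserved-segment captures (see the simulator
below) from triggering rule (b), and containment of a close relative's hit
inside the primary hit never looks like a split. A read covered over less
than 80% of its length (ends excepted only in the sense that end gaps do
not make a read chimeric) is **uncovered**; everything else is clean.
Chimeric and uncovered reads are excluded from classification.

## Classification

Hits below the marker's block threshold are dropped first; a read whose
hits all fail the filter is `filtered_block`, a read with no hits at all
`unassigned`. Among surviving hits the maximal AS wins. Ties spanning one
species assign that species (`n_best_ties` records the multiplicity); ties
spanning several species of one genus become genus-level calls under the
default `ambiguous_to_lca` policy (status `ambiguous`, genus recorded) and
plain `ambiguous` otherwise, or always plain `ambiguous` under
`drop_ambiguous`. One assignment is made per read; if disjoint read
intervals hit different references after scrubbing (rare), the higher AS
wins. Abundance tables normalise over classified reads at the requested
rank — genus tables include the genus-level LCA calls — rather than over
all sequenced reads; composition heat-map style reporting is the intended
consumer. Rarefaction curves subsample assigned reads without replacement,
averaged over replicates with a seeded generator.

## Database-completeness diagnostics

Histograms are taken over the best (highest-AS) hit per read, by default
before block filtering, since the diagnostic question is what the filter
*would* remove. Bimodality is flagged on a 5-bin moving average of a 50-bin
histogram: peaks are local maxima, each peak's mass is its basin (split at
the minima between peaks), and the flag is raised when two peaks each hold
≥ 5% of the mass with a valley no higher than half the smaller peak. The
smoothing, bin count and prominence are explicit parameters because the
underlying phenomenon — a second, low mode of short/weak alignments
appearing when a major taxon is missing from the database — is a visual
judgement made testable, not a sharp statistic. A formal dip test is out
of scope. The paired comparison (`compare_dbs`) joins per-read best hits
against two databases; removing references can never raise a read's best
AS, which the tests assert read-wise.

## The simulator

The generator emulates the study designs the pipeline targets, not a
sequencer:

* **References**: a master template is split into alternating conserved
  (150 bp) and variable (80 bp) segments. Each species keeps conserved
  segments with 2% per-species substitution drift and draws variable
  segments independently; per-species lengths get 1% Gaussian jitter. Expected
  cross-species identity is ~71% overall (~96% in conserved segments,
  random in variable ones). This architecture matters: reads of a species
  absent from the database still seed short conserved-segment alignments on
  other references — the low histogram mode and wrong-reference captures
  that make incomplete databases diagnosable. With i.i.d. random
  references such reads would simply be unmapped and the phenomenon could
  not occur. Species 0 and 1 are always a designated close pair: same
  genus, whole-sequence identity set by exact substitution count (default
  0.97, the hardest realistic within-genus confusion for these markers).
  Lineages (domain → species) are synthetic, with classes assigned
  round-robin so class-level subsetting experiments are possible.
  `add_close_relatives` salts a database with a ~97% decoy per listed
  species.
* **Reads**: per-base independent substitutions/insertions/deletions
  (default 0.055/0.0275/0.0275). The generative-alignment identity is
  (1−d)(1−s)/(1+i) ≈ 0.894 for the defaults, emulating ~89% read accuracy;
  optimal realignment recovers ~0.5 points more (measured ~89.9%), since an
  optimal aligner always beats the generative placement. The truth table
  records each read's generative identity. Read lengths get 3% Gaussian
  jitter (never longer than the source); short fragments (opt-in rate) are
  truncated amplicons at uniform 0.3–0.8× the marker length, which the
  length window removes; chimeras (opt-in rate) concatenate error-free
  segments from two distinct species (split point uniform in 0.3–0.7)
  before errors are applied. Strands are flipped with probability 0.5.
  Qualities are a constant Q12 placeholder — the pipeline never reads
  them. Chimera and short-fragment rates default to 0 so that a plain
  simulation is a clean sequencing run and artifacts are explicit choices.
* **Carryover**: `inject_carryover` mixes a contaminant pool into a run so
  contaminants form exactly the requested fraction of the total (600 of
  10,000 at 6%), flagged `is_carryover` with labels otherwise intact.
* **Determinism**: one seeded generator per invocation; identical seeds
  give byte-identical FASTQ and truth TSV.

Not emulated: signal-level behaviour, homopolymer-specific errors, PCR
amplification bias (real primer-driven over/under-representation is
documented but not quantified anywhere usable), quality-score structure,
and real phylogenetic topology. Passing tests therefore demonstrate the
pipeline's logic and its behaviour under calibrated noise, abundance
skew, database gaps and contamination — not performance on any particular
real community.

## Evaluation

Detection is read-count thresholding (default ≥ 1 assigned read) against
the truth membership, with off-target taxa reported as false positives.
The abundance regression fits log10(observed proportion) on
log10(expected copies/proportion) by ordinary least squares, excluding
zero-count species explicitly rather than pseudo-counting them; exclusions
are part of the report. Accuracy is reported both unconditionally (correct
assigned / all evaluable reads, where evaluable means non-chimeric,
non-carryover truth reads that reached classification) and conditional on
assignment; the conditional figure is what mock-community percentages of
this kind quote. Carryover is the summed relative abundance of
contaminant-only taxa; taxa shared with the expected sample are excluded
and listed, since composition alone cannot attribute them.

## Problem sizes and seeds

The evaluation script (`scripts/acceptance.py`) uses desk-scale analogs
chosen to keep the whole recomputation around ten minutes on one CPU while
leaving sampling error well inside the asserted tolerances: even 8-species
mocks at 2,000 reads per marker against decoy-salted databases, the
20-species staggered community at 20,000 reads (the 10³-copy stratum then
expects ~3–4 reads per species), isolates at 2,000 reads per marker,
carryover at 5,000 total reads, and 1,000 reads for the identity
measurement. All randomness flows from the single `--seed` argument
through derived per-stage seeds. The test suite pins its own seeds and
asserts the same quantities at the same scales.

## Known limitations

* The aligner is a faithful desk-scale stand-in for a production long-read
  mapper, not a replacement: no split/supplementary flag semantics, no
  MAPQ model, no SAM output, and indexes are built in memory per run.
* Chimera sensitivity is defined against reference mapping; reference-free
  (all-vs-all) scrubbing is out of scope.
* Genus-level truth in the evaluator is derived from the first token of
  the species name, which is correct for the synthetic taxonomy and for
  conventional binomials but not for arbitrary labels.
* With multiple operons per species, copy-number correction of abundances
  is deliberately not attempted.
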