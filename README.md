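# rrnmap

Species-level microbiota profiling from noisy long amplicon reads of two
ribosomal markers: the full-length 16S rRNA gene (~1,500 bp) and the
16S-ITS-23S span of the *rrn* operon (~4,300 bp).

Long nanopore amplicons cover enough signal to resolve bacteria to the
species level despite per-read accuracies near 89%, provided the analysis
deals with three failure modes: artifactual chimeric reads, reads captured
by the wrong reference when the right one is missing from the database, and
cross-run barcode carryover. `rrnmap` implements the complete mapping-based
workflow at desk scale, plus a read simulator with truth labels so every
stage can be validated without sequencing data. It is aimed at microbiome
researchers who want a transparent, testable reference implementation of
this style of pipeline.

## The method

Reads are processed as:

1. **Trim** a fixed 45 bp from each end (universal tag + primer).
2. **Length selection** into the marker window: 1,200–1,800 bp (16S) or
   3,500–5,000 bp (*rrn*), inclusive.
3. **Mapping** against a taxonomy-labelled reference FASTA with a
   minimizer (k=15, w=10) seed → diagonal chain → banded affine-gap
   Smith–Waterman extension with z-drop 70. Each hit carries an AS score
   (local alignment score at match +2, mismatch −4, gap open −4, gap
   extend −2) and a block length counting all alignment columns.
4. **Chimera scrubbing** from per-read coverage: a read is `chimeric` when
   its covered intervals leave an internal gap ≥ 100 bp or when two
   references support essentially disjoint read segments; `uncovered` when
   less than 80% of the read is covered.
5. **Block filter**: hits with a block < 1,000 columns (16S) or < 3,000
   (*rrn*) are discarded.
6. **Assignment**: the hits with the highest AS decide the species; ties
   across species fall back to the genus when the genera agree
   (`ambiguous_to_lca`), else the read is `ambiguous`.
7. **Profiles and evaluation**: abundance tables at species/genus rank,
   rarefaction curves, detection and log–log abundance regression against a
   mock-community truth, per-read accuracy, carryover quantification, and
   database-incompleteness diagnostics (block/AS histograms + bimodality
   flag, paired full-vs-subset DB comparison).

The simulator (`rrnmap.simulate`) generates labelled reference sets whose
sequences interleave conserved and hypervariable segments (as real rRNA
markers do) with one designated close-relative pair at ~97% identity, and
reads with independent substitution/insertion/deletion errors (default
5.5% / 2.75% / 2.75% ≈ 89% accuracy), staggered abundances over 10³–10⁶
operon copies, chimeras, short fragments and cross-run carryover.

## Worked example

Simulate an even 8-species *rrn* mock (500 reads, 3% chimeras) with a
synthetic reference set, profile it, and score it against the truth:

```bash
rrnmap simulate --synthesize 8 --marker rrn --n-reads 500 \
    --chimera-rate 0.03 --seed 7 --out-prefix mock
rrnmap classify --reads mock.fastq --db mock.refs.fasta --marker rrn --outdir run
rrnmap evaluate --abundance run/abundance_species.tsv \
    --truth-design mock.design.json \
    --assignments run/assignments.tsv --truth-reads mock.truth.tsv \
    --out report.json
rrnmap diagnose --hits run/hits.tsv --block-threshold 3000 --out-prefix diag
```

which prints

```
wrote 500 reads to mock.fastq
INFO preprocess: {'input': 500, 'trim_rejected': 0, 'kept': 500, 'discarded_short': 0, 'discarded_long': 0}
pipeline complete: run
detected 8/8 species
bimodal=False
```

`run/manifest.json` shows the stage accounting — 500 reads in, 482
assigned, 18 flagged chimeric (the injected 3% plus sampling noise), none
lost to the length or block filters:

```json
"status_counts": {"assigned": 482, "chimeric": 18}
```

and `report.json` the evaluation: all 8 species detected, species-level
accuracy 1.0 both unconditionally and conditional on assignment.
`run/abundance_species.tsv` holds the profile itself (top rows):

```
taxon              read_count  relative_abundance
Genus06 species06  72          0.1494
Genus00 species01  66          0.1369
```

`bimodal=False` from `diagnose` says the block-length histogram has a
single full-length mode — the signature of a complete reference database.
Rerun `classify` against a database with a whole class removed
(`rrnmap makedb --exclude class:Class01 ...`) and the flag flips.

The same functionality is available as a library (`rrnmap.simulate`,
`rrnmap.run_reads`, `rrnmap.evaluate`, ...) returning dataclasses and
pandas DataFrames.

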