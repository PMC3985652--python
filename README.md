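# h1scape

Analysis pipeline for mapping the genomic occupancy of linker histone H1
variants (H1.0, H1.2–H1.5, H1X) from ChIP-seq–style data. Unlike core
histones, H1 variants are not interchangeable: some track GC-poor,
lamina-associated, repressive chromatin while others follow GC-rich,
gene-dense space. This package implements the computational side of that
comparison — from aligned read positions to the domain-scale statistics
that tell an "H1.2-like" occupancy landscape apart from an "H1X-like"
one — together with a seeded synthetic-genome generator so that every
stage can be validated by parameter recovery.

## What it computes

**Input-subtracted signal.** Reads are extended to a fixed fragment size
(150 bp) from their 5′ end, counted in 50-bp bins, normalized by library
size and input-subtracted:

    Δ_b = (chip_b / N_chip − input_b / N_input) × 10⁶   (RPM)

**Promoter and metagene profiles.** Strand-aware average profiles over
−3.2 kb…+800 bp around the TSS (50-bp bins, optional LOESS smoothing),
stratified into expression deciles EG1 (highest) … EG10 (lowest), and a
length-normalized metagene (1-kb flanks, 60-bin body). These expose the
"H1 valley" at the TSS and its dependence on transcription.

**Island calling.** A SICER-style window/gap caller (window 200 bp, gap
200 bp, redundancy threshold 1, effective genome fraction 0.75): windows
beating a Poisson background threshold (p < 0.2) are merged across ≤ 1
ineligible window, islands are tested against the Poisson background,
Benjamini–Hochberg corrected (FDR 0.01) and filtered at fold change ≥ 2.
Depleted islands are called by swapping the ChIP and input channels.
Islands are annotated to the nearest TSS, to feature classes (promoter /
genic / downstream / distal intergenic, 3-kb promoter and downstream
margins), and to target genes over the span TSS−5 kb … TTS+3 kb.

**Domain statistics.**
- gene-richness coefficient per chromosome,
  `GRC_c = (genes_c / genes_total) / (bp_c / bp_total)`;
- chromosome occupancy (mean Δ per chromosome) with average-linkage
  clustering at 1 − Pearson distance;
- enrichment of Δ inside region sets (LADs, CpG islands, mark peaks)
  against a width-matched random-window null, two-sample
  Kolmogorov–Smirnov test with signed direction;
- genome-wide Pearson correlation of Δ with GC content in 1-kb windows;
- per-gene distal-promoter scores (−3200…−2000 bp from the TSS) and the
  top/bottom-10 % overlap analysis between two variants, with KS tests
  of each intersection's expression against the gene universe.

## Worked example

Simulate the default synthetic cohort (2 chromosomes × 5 Mb, 400 genes,
20 LADs, two variant libraries at 2 × 10⁶ reads each) and run the whole
pipeline:

```bash
python analysis/01_simulate_cohort.py 1
python analysis/02_run_pipeline.py
```

which prints:

```
H1.2-like:
  GC correlation r = -0.610 over 10000 1-kb windows
  LADs: enriched (KS p = 3.17e-24)
  islands: 17 enriched, 0 depleted
H1X-like:
  GC correlation r = +0.661 over 10000 1-kb windows
  LADs: depleted (KS p = 2.03e-30)
  islands: 0 enriched, 0 depleted
```

The H1.2-like library was generated with a negative GC coupling and a
+0.7 log enrichment inside LADs, the H1X-like one with both signs
flipped; the pipeline recovers the anti-correlated GC relationship, the
opposite LAD directions, and calls enriched islands only where the
generative fold change reaches the ×2 filter (the LAD domains of the
H1.2-like library). Per-variant tables (TSS/decile profiles, metagenes,
island annotation, distal scores, GC scatter) land under
`results/pipeline/`, with a machine-readable `summary.json`.
`analysis/03_parameter_recovery.py` and
`analysis/04_island_calibration.py` run the multi-seed recovery and
calibration panels.

The same stages are available as a CLI
(`h1scape simulate|coverage|subtract|profile|islands|annotate|domains|run-all`)
over plain-text formats: BED, fixed-step bedGraph, chrom.sizes and TSV.

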