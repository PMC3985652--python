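# Methods

## Signal model

All analyses run on per-chromosome, fixed-width binned signal (default
50 bp). Coverage extends each read to a fragment of 150 bp from its 5′
end in the read direction and counts a fragment in every bin it overlaps
by at least one base; deduplication (at most one read per position and
strand, the "redundancy threshold 1" convention) is applied first. The
working track is the library-size-normalized difference

Δ_b = (c_b / N_chip − i_b / N_input) × 10⁶,

in reads per million, which removes accessibility and copy-number
background and may be negative. A log2 ratio track
log2((chip_rpm + p)/(input_rpm + p)) is available for promoter-array
style analyses; sequencing ratios need the pseudocount (default p = 0.5
RPM, configurable) where array ratios did not, and the exact ratio
convention of array processing software is not reproduced — the log
track is a declared approximation.

Coordinates are uniformly 0-based half-open. Genes are stored in genomic
orientation with strand-aware anchors: TSS = `start` for `+` genes and
`end − 1` for `−` genes, TTS symmetric. Unknown chromosomes in any input
are skipped and counted rather than fatal. bedGraph output is fixed-step
with one record per bin at 6 decimal places, which round-trips exactly
at that precision.

## Profiles

A profile cell at transcriptional offset o covers transcribed bases
[o, o + bin) relative to the anchor (offset 0 = the anchor base);
minus-strand anchors are evaluated on mirrored genomic coordinates so
upstream is always transcriptionally upstream. Cell values are exact
per-bp means of the binned track over the cell's genomic footprint,
computed from a prefix integral of the step signal; this makes the
profile independent of how anchors align to the bin grid and defines the
resampling between unequal bin sizes (length-weighted averaging).
Cells extending past a chromosome end are masked, and column means are
taken over unmasked cells only (a fully masked column is missing, never
zero).

The default TSS window is −3200…+800 bp in 50-bp bins. Expression
deciles EG1…EG10 rank genes by expression descending with remainder
going to the first groups; ties break on the stable order of gene id so
the partition is deterministic. The metagene rescales the gene body
[TSS, TTS) to 60 bins by the same length-weighted integral (flanks of
1 kb stay at native resolution); genes shorter than body_bins × 10 bp
(default 600 bp) are excluded to avoid rescaling artifacts — the
threshold is a package choice, there is no canonical value.

LOESS smoothing is local degree-1 regression with tricube weights
(delegated to statsmodels lowess with zero robustness iterations, which
an independently coded weighted-least-squares oracle reproduces to
1e-15). The default span of 0.1 over the 80-column TSS window is
cosmetic and configurable; degree-1 fits are exact on linear profiles.

## Island calling

The caller follows the two-stage window/gap design of SICER-class
histone peak callers with the published parameter set (window 200 bp,
gap 200 bp, fragment 150 bp, effective genome fraction 0.75, FDR 0.01,
fold change ≥ 2). Extended-fragment midpoints are counted in
non-overlapping windows (midpoint assignment here, overlap counting in
the coverage module — both conventions are kept and tested separately).
With λ₀ = N·w / (G·f) the genome-wide background rate per window, a
window is eligible when its count clears the smallest k with
P(Pois(λ₀) ≥ k) < 0.2; eligible windows merge into islands across at
most gap/window ineligible windows. Island significance is the Poisson
tail of the island's total count against λ₀ × (windows spanned), with
Benjamini–Hochberg correction across all candidate islands — a
deliberate simplification of the original caller's random-background
score distribution, chosen because it is directly implementable and
testable; it is calibrated by simulation (below). The island score
Σ −ln P(count; λ₀) over eligible windows is retained for ranking. The
fold-change filter uses library-normalized chip/input counts with a
1-read floor on the input count so zero-input islands stay finite and
conservative. Depleted islands are exactly enriched islands of the
swapped channel pair, the declared interpretation of depleted-region
calling; note that against a truly uniform input (as in the simulator)
this test has no power, since the swapped "ChIP" channel is structure-
free — depleted calls require a structured input and are therefore
reported as zero on synthetic data.

Annotation: nearest gene by absolute midpoint-to-TSS distance, signed by
transcript orientation (negative = upstream), ties to the smaller
genomic coordinate; feature classes by region midpoint with priority
promoter > 5′UTR > exon > intron > 3′UTR > genic > downstream > distal
intergenic, using 3-kb promoter/downstream margins. Gene bodies without
exon structure are the undivided class "genic"; UTR classes require
explicit UTR intervals, which the synthetic annotation does not model.
Target genes are those whose extended span TSS−5 kb…TTS+3 kb overlaps an
island by ≥ 1 base (half-open arithmetic throughout).

## Domain statistics

- GRC_c = (genes_c/genes_total)/(bp_c/bp_total); the weighted sum
  Σ_c GRC_c · bpfrac_c = 1 holds algebraically for any placement and is
  tested to 1e-12.
- Chromosome occupancy is the plain mean of Δ over each chromosome's
  bins; variants (or chromosomes) are clustered by average linkage on
  1 − Pearson distance with deterministic leaf order; zero-variance rows
  fall back to Euclidean distance with a warning.
- Region enrichment compares per-region mean Δ against means over
  random windows whose widths resample the observed width multiset
  (preserving the width distribution while letting the null sample be
  larger) and whose positions are uniform genome-wide, avoiding
  chromosome ends; chromosome-matched sampling is available behind a
  flag. Significance is a two-sided two-sample KS test; the reported
  direction comes from the sign of the observed-minus-null median when
  p < α (the KS statistic itself is unsigned). LAD-boundary bins are
  included by bin midpoint rather than overlap-weighted.
- GC correlation averages both tracks into 1-kb windows (a trailing
  partial window is dropped) and reports Pearson's r.
- Distal-promoter scores are mean Δ over the strand-aware window
  −3200…−2000 bp from the TSS (partial windows at chromosome edges
  average over the available part). The overlap analysis takes the top
  and bottom ⌈0.10·N⌉ genes of each variant's score over the common
  universe, counts the four intersections, and KS-tests each
  intersection's expression against the full universe (the universe, not
  the complement, is the reference).

## Synthetic data

The generator emulates the large-scale structure the analyses are built
to detect, at the default study scale of 2 chromosomes × 5 Mb, 400
genes, 20 LADs and 2 × 10⁶ reads per library:

- GC landscape: a logistic-squashed, Gaussian-smoothed random walk in
  [0.3, 0.7] per 50-bp bin — autocorrelated, isochore-like domains.
- LADs: 150-kb intervals centered greedily on the lowest broadly
  smoothed GC stretches, non-overlapping (LADs live in low-GC space).
- Genes: 2–20-kb bodies with ≥ 1-kb spacing, placed with probability
  ∝ exp(5·GC) within their stratum; a gene falls outside LADs with
  probability 0.8. Expression is LogNormal(0, 1), scaled down 4× inside
  LADs, stored on the log2 scale (the 4× becomes −2 log2 units; the
  rank-based decile machinery is unaffected by the scale choice).
- Read intensity per bin:
  exp(γ_GC·GC + γ_LAD·1[LAD]) · Π_g (1 − d_g·K(x − TSS_g)) ·
  (1 + a·K₊(x − TSS_g)), with K a Gaussian bump of scale
  `valley_halfwidth`, d_g = `tss_valley_depth` × expression rank in
  (0, 1] (rank, not raw value, drives depth — deciles make rank the
  natural generative link), and K₊ a strand-aware Gaussian at +125 bp
  (scale 60 bp) for the +1-nucleosome peak. ChIP 5′ positions are a
  multinomial draw from the normalized intensity (uniform within bins
  and over strands); the input library is uniform — no mappability or
  GC bias model, reflecting the role of input as featureless background.
- Two reference archetypes: H1.2-like (γ_GC = −0.8, γ_LAD = +0.7, deep
  wide valley d = 0.9/hw 400 bp reaching low-expression genes, no +1
  peak) and H1X-like (γ_GC = +0.8, γ_LAD = −0.7, shallower narrower
  valley 0.5/250 bp, +1 peak a = 0.6). Effect sizes are chosen for test
  power — the real effect magnitudes are only known qualitatively — so
  passing recovery says the pipeline detects signs and orderings under
  realistic noise, not that the magnitudes match any particular cell
  line.

What the generator does not emulate: sequence-level reads, PCR
duplicates beyond what multinomial collisions produce, replicate
variance, mappability structure in the input, exon/UTR architecture, and
any coupling between expression and GC beyond the LAD pathway.

## Recovery and calibration experiments

- GC-sign recovery compares the sampled track's 1-kb GC correlation to
  the same statistic on the mean-centered noise-free intensity field;
  agreement within ±0.15 checks that sampling noise attenuates but does
  not distort the correlation.
- Valley ordering uses the minima of the LOESS-smoothed decile mean
  profiles (the smoothed profile is the object the decile figure
  plots); the check is min(EG1) < min(EG10) plus non-decreasing minima
  across all ten deciles.
- Chromosome-occupancy clustering runs on an 8-chromosome genome of the
  same total size (8 × 1.25 Mb): with only two chromosomes the
  1 − Pearson distance across chromosomes is degenerate (always 0 or 2).
  Four libraries (two per archetype, different seeds) share one input
  library, a common ChIP-seq design choice that halves simulation cost
  without touching the statistic.
- Island calibration uses a 5-Mb single-chromosome genome with both
  libraries uniform at 2 × 10⁶ reads (null: mean islands called, which
  should be ≈ 0 at FDR 0.01/FC 2) and with a planted 1-kb interval at
  5× background (power: fraction of seeds with an overlapping enriched
  island).
- KS-null calibration draws 20 test regions per repetition with the
  null's own sampler (widths 500–2500 bp) over iid Gaussian bin noise
  and tests against 200 null windows; over 1000 repetitions the
  rejection rate at α = 0.05 should sit near the nominal level (the
  slight conservatism of the exact two-sample KS at these sample sizes
  keeps it within 3–7 %).

Problem sizes throughout (10-Mb genomes, 2 × 10⁶-read libraries, tens of
seeds) are the package's chosen study scale: large enough for stable
decile profiles and window statistics, small enough that the full suite
runs in minutes.

## Numerical choices and degenerate inputs

Seeded `numpy` Generators drive all randomness; identical seeds give
bit-identical outputs, and the end-to-end driver is byte-deterministic
given its config. Ties: expression deciles and top/bottom score sets
break ties by stable gene-id order; nearest-gene ties go to the smaller
coordinate; clustering leaf order is scipy's deterministic order.
Degenerate cases are explicit errors rather than silent results: empty
region sets for the enrichment test, zero-variance series for the
Pearson correlation, spans too small for a 3-point LOESS window,
all-missing expression, infeasible gene placement (reported with
occupancy), genomes smaller than one caller window.

## Known limitations

The island caller's analytic Poisson/BH significance is simpler than
the original two-pass background-score recursion; its FDR behavior is
established here only by the null simulations. Depleted-island calling
has no power against uniform input by construction. The log2 ratio
track approximates, not reproduces, array-software ratios. The
synthetic data validate sign- and rank-level recovery, not effect-size
estimation on real chromatin.
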