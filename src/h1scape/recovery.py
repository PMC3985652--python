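"""Parameter-recovery and calibration experiments on synthetic data.

These drive the whole pipeline end-to-end under the study conditions the
synthetic generator encodes (2 x 5 Mb genome, 400 genes, 20 LADs, 2e6
reads per library) and ask whether the analyses recover the generative
parameters: the sign of the GC coupling, the LAD enrichment direction,
the expression-ranked TSS valley ordering, the +1 peak, the separation
of variant classes by chromosome-occupancy clustering, and the link
between distal-promoter occupancy contrasts and expression. They also
calibrate the island caller and the random-window KS null.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster

from .domains import (cluster_occupancy, chromosome_occupancy,
                      decile_overlap_analysis, distal_promoter_score,
                      gc_correlation, region_enrichment_test,
                      sample_null_windows)
from .genome import Genome, ReadSet, SignalTrack
from .islands import IslandParams, call_islands
from .profiles import (anchored_profile, column_mean_profile,
                       expression_deciles, loess_profile)
from .signal import bin_coverage, normalize_subtract
from .synth import (H12_LIKE, H1X_LIKE, SyntheticTruth, VariantModel,
                    generate_genome, intensity_field, simulate_reads)

DEPTH = 2_000_000


def variant_delta(truth: SyntheticTruth, model: VariantModel) -> SignalTrack:
    """Simulate one variant and return its input-subtracted RPM track."""
    chip, inp = simulate_reads(truth, model)
    return normalize_subtract(bin_coverage(chip, truth.genome),
                              bin_coverage(inp, truth.genome))


def decile_profile_minima(delta: SignalTrack, truth: SyntheticTruth,
                          span: float = 0.1) -> list[float]:
    """Minimum of the LOESS-smoothed mean TSS profile per expression
    decile, EG1 (highest expression) first."""
    labels, _ = expression_deciles(truth.genes)
    mat = anchored_profile(delta, truth.genes)
    minima = []
    for g in range(1, 11):
        ids = set(labels[labels == f"EG{g}"].index)
        sel = [i for i, rid in enumerate(mat.row_ids) if rid in ids]
        mean = np.nanmean(mat.values[sel], axis=0)
        minima.append(float(loess_profile(mean, span).min()))
    return minima


def has_plus1_peak(delta: SignalTrack, truth: SyntheticTruth,
                   span: float = 0.1, window_bp: int = 250) -> bool:
    """Local maximum of the smoothed mean TSS profile in (0, +250 bp]."""
    mean, _ = column_mean_profile(anchored_profile(delta, truth.genes))
    smooth = loess_profile(mean, span)
    offsets = np.arange(-3200, 800, 50)
    for i in range(1, len(smooth) - 1):
        if 0 < offsets[i] <= window_bp and \
                smooth[i] > smooth[i - 1] and smooth[i] >= smooth[i + 1]:
            return True
    return False


def field_gc_correlation(truth: SyntheticTruth, model: VariantModel) -> float:
    """GC correlation of the noise-free generative intensity field,
    mean-centered like the input-subtracted track it generates."""
    field = intensity_field(truth, model)
    flat = np.concatenate([field.values[c] for c in truth.genome.chrom_names])
    centered = SignalTrack(field.bin_size, {
        c: field.values[c] - flat.mean() for c in truth.genome.chrom_names})
    r, _, _ = gc_correlation(centered, truth.gc)
    return r


def recovery_trial(seed: int, depth: int = DEPTH) -> dict:
    """One full H1.2-like vs H1X-like recovery run on a fresh genome."""
    truth = generate_genome(seed=seed)
    models = {"h12": replace(H12_LIKE, depth=depth, seed=seed + 10_000),
              "h1x": replace(H1X_LIKE, depth=depth, seed=seed + 20_000)}
    out: dict = {"seed": seed}
    deltas = {}
    for name, model in models.items():
        delta = variant_delta(truth, model)
        deltas[name] = delta
        r, _, _ = gc_correlation(delta, truth.gc)
        out[f"gc_r_{name}"] = r
        out[f"gc_r_field_{name}"] = field_gc_correlation(truth, model)
        res = region_enrichment_test(delta, truth.lads, truth.genome,
                                     n_null=1000, seed=seed, region_class="LADs")
        out[f"lad_direction_{name}"] = res.direction
        out[f"lad_p_{name}"] = res.p_value
        out[f"plus1_{name}"] = has_plus1_peak(delta, truth)
    minima = decile_profile_minima(deltas["h12"], truth)
    out["decile_minima"] = minima
    out["valley_eg1_deeper"] = minima[0] < minima[-1]
    out["valley_monotone"] = all(minima[i] <= minima[i + 1] for i in range(9))
    scores_a = distal_promoter_score(deltas["h12"], truth.genes)
    scores_b = distal_promoter_score(deltas["h1x"], truth.genes)
    overlap = decile_overlap_analysis(scores_a, scores_b, truth.genes, 0.10)
    entry = overlap["sets"]["highA_lowB"]
    out["h2lx_count"] = entry["count"]
    out["h2lx_ks_p"] = entry["p_value"]
    out["h2lx_median_shift"] = entry["median_shift"]
    return out


def clustering_trial(seed: int, depth: int = DEPTH, n_chrom: int = 8) -> bool:
    """Do two H1.2-like and two H1X-like variants split into the two
    model classes when chromosomes are clustered by occupancy?

    Uses an 8-chromosome genome of the same total size: correlation
    distance across chromosomes is degenerate with only two of them.
    A single input library is shared by the four ChIP libraries.
    """
    truth = generate_genome(n_chrom=n_chrom,
                            chrom_length=10_000_000 // n_chrom, seed=seed,
                            n_lads=20, n_genes=400)
    input_model = VariantModel(depth=depth, seed=seed + 1)
    _, shared_input = simulate_reads(truth, input_model)
    input_cov = bin_coverage(shared_input, truth.genome)
    tracks = {}
    specs = [("h12_a", H12_LIKE, 2), ("h12_b", H12_LIKE, 3),
             ("h1x_a", H1X_LIKE, 4), ("h1x_b", H1X_LIKE, 5)]
    for name, base, k in specs:
        model = replace(base, depth=depth, seed=seed + k)
        chip, _ = simulate_reads(truth, model)
        tracks[name] = normalize_subtract(bin_coverage(chip, truth.genome),
                                          input_cov)
    occ = chromosome_occupancy(tracks)
    Z, _ = cluster_occupancy(occ, axis="variants")
    labels = fcluster(Z, 2, criterion="maxclust")
    by_name = dict(zip(occ.index, labels))
    return (by_name["h12_a"] == by_name["h12_b"]
            and by_name["h1x_a"] == by_name["h1x_b"]
            and by_name["h12_a"] != by_name["h1x_a"])


def _uniform_reads(genome: Genome, depth: int, rng: np.random.Generator,
                   boost: tuple[str, int, int, float] | None = None) -> ReadSet:
    """Uniform 5' positions, optionally with an interval at a higher rate."""
    cell = 50
    chroms, bins, weights = [], [], []
    for ci, c in enumerate(genome.chrom_names):
        n = genome.length_of(c) // cell
        w = np.ones(n)
        if boost is not None and boost[0] == c:
            _, s, e, fold = boost
            w[s // cell:e // cell] *= fold
        chroms.append(np.full(n, ci))
        bins.append(np.arange(n))
        weights.append(w)
    chroms = np.concatenate(chroms)
    bins = np.concatenate(bins)
    weights = np.concatenate(weights)
    counts = rng.multinomial(depth, weights / weights.sum())
    hit = np.flatnonzero(counts)
    reps = counts[hit]
    pos = np.repeat(bins[hit], reps) * cell + rng.integers(0, cell, int(reps.sum()))
    strand = np.where(rng.random(len(pos)) < 0.5, "+", "-")
    names = np.array(genome.chrom_names, dtype=object)
    return ReadSet(pd.DataFrame({"chrom": names[np.repeat(chroms[hit], reps)],
                                 "pos": pos, "strand": strand}))


NULL_GENOME = Genome(("chr1",), (5_000_000,))


def null_island_trial(seed: int, depth: int = DEPTH,
                      params: IslandParams | None = None) -> int:
    """Number of islands called on a matched-rate null (both libraries
    uniform at the same depth)."""
    rng = np.random.default_rng(seed)
    chip = _uniform_reads(NULL_GENOME, depth, rng)
    inp = _uniform_reads(NULL_GENOME, depth, rng)
    return len(call_islands(chip, inp, NULL_GENOME, params))


def planted_island_trial(seed: int, depth: int = DEPTH, fold: float = 5.0,
                         region: tuple[int, int] = (2_000_000, 2_001_000),
                         params: IslandParams | None = None) -> bool:
    """Is a planted 1-kb region at ``fold``x background recovered by an
    overlapping enriched island?"""
    rng = np.random.default_rng(seed)
    chip = _uniform_reads(NULL_GENOME, depth, rng,
                          boost=("chr1", region[0], region[1], fold))
    inp = _uniform_reads(NULL_GENOME, depth, rng)
    islands = call_islands(chip, inp, NULL_GENOME, params)
    return any(i.start < region[1] and i.end > region[0] for i in islands)


def ks_null_calibration(n_reps: int = 1000, seed: int = 0,
                        n_regions: int = 20, n_null: int = 200) -> float:
    """Fraction of repetitions with p < 0.05 when the tested regions are
    drawn by the null's own sampler over iid-noise signal."""
    genome = Genome(("chr1", "chr2"), (2_000_000, 2_000_000))
    widths = np.array([500, 1000, 1500, 2000, 2500] * 4)
    master = np.random.default_rng(seed)
    track = SignalTrack(50, {c: master.normal(size=genome.n_bins(c, 50))
                             for c in genome.chrom_names})
    hits = 0
    for rep in range(n_reps):
        rng = np.random.default_rng(seed + 1 + rep)
        regions = sample_null_windows(genome, widths, n_regions, rng)
        res = region_enrichment_test(track, regions, genome, n_null=n_null,
                                     alpha=0.05, seed=seed + 100_000 + rep)
        hits += res.p_value < 0.05
    return hits / n_reps
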