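"""Chromosome- and domain-scale statistics.

Covers the gene-richness coefficient (GRC), per-chromosome occupancy
and its hierarchical clustering, enrichment of signal inside region
classes (LADs, CpG islands, mark peaks) against a width-matched
random-window null with a two-sample Kolmogorov-Smirnov test, the
genome-wide GC correlation in 1-kb windows, per-gene distal-promoter
scores and the top/bottom-decile overlap analysis between two variants.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.stats import ks_2samp, pearsonr

from .genome import GeneSet, Genome, RegionSet, SignalTrack
from .profiles import windowed_means

__all__ = [
    "gene_richness", "chromosome_occupancy", "cluster_occupancy",
    "EnrichmentResult", "region_enrichment_test", "gc_correlation",
    "distal_promoter_score", "decile_overlap_analysis",
]


def gene_richness(genes: GeneSet, genome: Genome) -> pd.Series:
    """Gene-richness coefficient per chromosome:
    (share of genes on the chromosome) / (share of genomic bp).

    Satisfies sum_c GRC_c * bp_frac_c = 1 for any placement.
    """
    if len(genes) == 0:
        raise ValueError("need at least one gene")
    if any(length == 0 for length in genome.chrom_lengths):
        raise ValueError("zero-length chromosome")
    counts = genes.df["chrom"].value_counts()
    total_genes = len(genes)
    total_bp = genome.total_bp
    grc = {}
    for chrom, length in zip(genome.chrom_names, genome.chrom_lengths):
        gene_frac = counts.get(chrom, 0) / total_genes
        bp_frac = length / total_bp
        grc[chrom] = gene_frac / bp_frac
    return pd.Series(grc, name="GRC")


def chromosome_occupancy(tracks: dict[str, SignalTrack]) -> pd.DataFrame:
    """Mean input-subtracted signal per (variant, chromosome); all
    tracks must share the bin grid."""
    if not tracks:
        raise ValueError("no tracks")
    ref = next(iter(tracks.values()))
    rows = {}
    for name, track in tracks.items():
        if track.bin_size != ref.bin_size or set(track.values) != set(ref.values):
            raise ValueError(f"track {name!r} is on a different bin grid")
        rows[name] = {c: float(np.mean(v)) for c, v in track.values.items()}
    return pd.DataFrame(rows).T.loc[list(tracks), list(ref.values)]


def cluster_occupancy(occ: pd.DataFrame, axis: str = "variants"
                      ) -> tuple[np.ndarray, list[str]]:
    """Average-linkage hierarchical clustering with 1 - Pearson
    correlation distance across the other axis.

    Returns the scipy linkage matrix and the deterministic leaf order.
    Zero-variance rows fall back to Euclidean distance with a warning.
    """
    import warnings

    mat = occ if axis == "variants" else occ.T
    if len(mat) < 2:
        raise ValueError("need >= 2 items to cluster")
    X = mat.to_numpy(dtype=float)
    sd = X.std(axis=1)
    if np.any(sd == 0):
        warnings.warn("zero-variance row(s); falling back to Euclidean distance")
        Z = linkage(X, method="average", metric="euclidean")
    else:
        corr = np.corrcoef(X)
        dist = 1.0 - corr
        iu = np.triu_indices(len(X), k=1)
        Z = linkage(dist[iu], method="average")
    order = [mat.index[i] for i in leaves_list(Z)]
    return Z, order


@dataclass
class EnrichmentResult:
    region_class: str
    n_regions: int
    observed: np.ndarray  # per-region mean signal
    null: np.ndarray  # per-random-window mean signal
    D: float
    p_value: float
    direction: str  # enriched | depleted | n.s.
    seed: int


def _region_means(track: SignalTrack, regions: RegionSet) -> np.ndarray:
    out = np.empty(len(regions))
    for i, (chrom, start, end) in enumerate(regions):
        m = windowed_means(track, str(chrom), np.array([start, end], dtype=float))
        out[i] = m[0]
    return out


def sample_null_windows(genome: Genome, widths: np.ndarray, n: int,
                        rng: np.random.Generator,
                        chrom_matched: RegionSet | None = None) -> RegionSet:
    """Random windows with widths resampled from the observed multiset,
    placed uniformly genome-wide (or chromosome-matched when a template
    RegionSet is given), avoiding chromosome ends."""
    widths = np.asarray(widths, dtype=np.int64)
    if np.any(widths > max(genome.chrom_lengths)):
        raise ValueError("region wider than any chromosome")
    chosen_w = rng.choice(widths, size=n, replace=True)
    rows = []
    lengths = np.array(genome.chrom_lengths, dtype=np.int64)
    for wdt in chosen_w:
        ok = lengths >= wdt
        weights = np.where(ok, lengths - wdt + 1, 0).astype(float)
        weights /= weights.sum()
        ci = rng.choice(len(lengths), p=weights)
        start = int(rng.integers(0, lengths[ci] - wdt + 1))
        rows.append((genome.chrom_names[ci], start, start + int(wdt)))
    return RegionSet.from_records(rows)


def region_enrichment_test(track: SignalTrack, regions: RegionSet, genome: Genome,
                           n_null: int = 1000, alpha: float = 0.05,
                           seed: int = 0, region_class: str = "regions"
                           ) -> EnrichmentResult:
    """Two-sample KS test of per-region mean signal against mean signal
    in width-matched random windows; direction by the sign of
    (median observed - median null) when p < alpha."""
    if len(regions) == 0:
        raise ValueError("no regions: nothing to test")
    if n_null < len(regions):
        raise ValueError("n_null must be >= number of regions")
    rng = np.random.default_rng(seed)
    observed = _region_means(track, regions)
    null_regions = sample_null_windows(genome, regions.widths, n_null, rng)
    null = _region_means(track, null_regions)
    D, p = ks_2samp(observed, null)
    if p < alpha:
        direction = "enriched" if np.median(observed) > np.median(null) else "depleted"
    else:
        direction = "n.s."
    return EnrichmentResult(region_class=region_class, n_regions=len(regions),
                            observed=observed, null=null, D=float(D),
                            p_value=float(p), direction=direction, seed=seed)


def _rebin(track: SignalTrack, window: int) -> dict[str, np.ndarray]:
    """Average bins into ``window``-bp windows, dropping a trailing
    partial window."""
    if window % track.bin_size:
        raise ValueError("window must be a multiple of the track bin size")
    k = window // track.bin_size
    out = {}
    for c, v in track.values.items():
        n = len(v) // k
        if n:
            out[c] = v[: n * k].reshape(n, k).mean(axis=1)
    return out


def gc_correlation(track: SignalTrack, gc: SignalTrack, window: int = 1000
                   ) -> tuple[float, int, pd.DataFrame]:
    """Pearson correlation between mean signal and mean GC in fixed
    genomic windows (default 1 kb); returns (r, n_windows, scatter)."""
    sig_w = _rebin(track, window)
    gc_w = _rebin(gc, window)
    xs, ys, chroms = [], [], []
    for c in sig_w:
        if c not in gc_w:
            continue
        n = min(len(sig_w[c]), len(gc_w[c]))
        xs.append(sig_w[c][:n])
        ys.append(gc_w[c][:n])
        chroms.extend([c] * n)
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if np.std(x) == 0:
        raise ValueError("signal series has zero variance")
    if np.std(y) == 0:
        raise ValueError("GC series has zero variance")
    r, _ = pearsonr(x, y)
    scatter = pd.DataFrame({"chrom": np.array(chroms)[keep],
                            "signal": x, "gc": y})
    return float(r), int(len(x)), scatter


def distal_promoter_score(track: SignalTrack, genes: GeneSet,
                          window: tuple[int, int] = (-3200, -2000)) -> pd.Series:
    """Per-gene mean signal over a strand-aware window relative to the
    TSS (default the distal promoter, -3200..-2000 bp). Windows cut by
    a chromosome edge average over the available part; fully
    out-of-bounds windows are NaN."""
    lo, hi = window
    if hi <= lo:
        raise ValueError("empty window")
    tss = genes.tss
    out = np.full(len(genes), np.nan)
    for i in range(len(genes)):
        chrom = str(genes.df["chrom"].iloc[i])
        if chrom not in track.values:
            continue
        L = len(track.values[chrom]) * track.bin_size
        p = int(tss[i])
        if genes.df["strand"].iloc[i] == "+":
            a, b = p + lo, p + hi
        else:
            # transcriptional offsets [lo, hi) map to genomic p - t
            a, b = p - hi + 1, p - lo + 1
        a2, b2 = max(a, 0), min(b, L)
        if b2 > a2:
            out[i] = windowed_means(track, chrom, np.array([a2, b2], dtype=float))[0]
    return pd.Series(out, index=pd.Index(genes.df["id"], name="id"), name="distal_score")


def _top_bottom(scores: pd.Series, k: int) -> tuple[set, set]:
    """Top/bottom k gene ids by score, ties broken by stable id order."""
    df = scores.dropna().rename("s").reset_index().sort_values("id", kind="stable")
    order = np.argsort(-df["s"].to_numpy(), kind="stable")
    ranked = df["id"].to_numpy()[order]
    return set(ranked[:k]), set(ranked[-k:])


def decile_overlap_analysis(scores_a: pd.Series, scores_b: pd.Series,
                            genes: GeneSet, fraction: float = 0.10
                            ) -> dict:
    """Overlap of the top/bottom score fractions of two variants, with
    KS comparison of each intersection's expression against the full
    gene universe.

    Returns counts for highA&highB, highA&lowB, lowA&highB, lowA&lowB
    plus per-intersection KS statistic, p-value and median shift.
    """
    if not 0 < fraction <= 0.5:
        raise ValueError("fraction must be in (0, 0.5]")
    common = scores_a.dropna().index.intersection(scores_b.dropna().index)
    if len(common) < int(round(1 / fraction)):
        raise ValueError("too few genes with both scores")
    k = int(np.ceil(fraction * len(common)))
    high_a, low_a = _top_bottom(scores_a.loc[common], k)
    high_b, low_b = _top_bottom(scores_b.loc[common], k)
    expr = genes.df.set_index("id")["expression"]
    universe = expr.loc[list(common)].dropna()
    result: dict = {"n_universe": int(len(common)), "k": k, "sets": {}}
    for name, ids in (("highA_highB", high_a & high_b),
                      ("highA_lowB", high_a & low_b),
                      ("lowA_highB", low_a & high_b),
                      ("lowA_lowB", low_a & low_b)):
        entry: dict = {"count": len(ids)}
        sub = expr.loc[list(ids)].dropna() if ids else pd.Series(dtype=float)
        if len(sub) >= 3 and len(universe) >= 3:
            D, p = ks_2samp(sub, universe)
            entry.update(D=float(D), p_value=float(p),
                         median_shift=float(np.median(sub) - np.median(universe)))
        else:
            entry.update(D=np.nan, p_value=np.nan, median_shift=np.nan)
        entry["ids"] = sorted(ids)
        result["sets"][name] = entry
    return result
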