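"""Synthetic genomes and ChIP/input read sets with the statistical
structure of linker-histone occupancy data.

The generator emulates, as tunable knobs, the large-scale features the
downstream analyses are built to detect: an autocorrelated GC landscape,
lamina-associated domains (LADs) sitting in the lowest-GC stretches,
genes placed preferentially in GC-rich space and mostly outside LADs,
log-normal expression suppressed inside LADs, and a variant-specific
read intensity with GC coupling, LAD enrichment, an expression-dependent
occupancy valley at the TSS and an optional +1-nucleosome peak just
downstream of it. The input library is uniform. Every draw is seeded.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml
from scipy.ndimage import gaussian_filter1d

from .genome import GeneSet, Genome, ReadSet, RegionSet, SignalTrack

__all__ = ["VariantModel", "SyntheticTruth", "generate_genome", "simulate_reads",
           "intensity_field", "write_bundle", "H12_LIKE", "H1X_LIKE"]

GC_BIN = 50


@dataclass(frozen=True)
class VariantModel:
    """Generative knobs for one histone-variant ChIP library.

    ``gc_coupling``: slope of log intensity per unit GC fraction
    (negative mimics H1.2's inverse GC correlation, positive H1.0/H1X).
    ``lad_log_enrichment``: log fold change of intensity inside LADs.
    ``tss_valley_depth``: maximal fractional dip at the TSS for the most
    expressed genes (depth scales with expression rank).
    ``plus1_peak_amp``: amplitude of a peak centered +125 bp downstream
    of the TSS (0 mimics the missing +1 enrichment of H1.2).
    """

    gc_coupling: float = 0.0
    lad_log_enrichment: float = 0.0
    tss_valley_depth: float = 0.0
    valley_halfwidth: int = 300
    plus1_peak_amp: float = 0.0
    plus1_center: int = 125
    plus1_halfwidth: int = 60
    depth: int = 2_000_000
    seed: int = 0
    name: str = "variant"

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.valley_halfwidth <= 0:
            raise ValueError("valley_halfwidth must be > 0")
        if not 0 <= self.tss_valley_depth <= 1:
            raise ValueError("tss_valley_depth must be in [0, 1]")
        if self.plus1_peak_amp < 0:
            raise ValueError("plus1_peak_amp must be >= 0")


# Reference parameterizations of the two occupancy archetypes: an
# H1.2-like variant (GC-averse, LAD-enriched, deep wide TSS valley
# reaching low-expression genes, no +1 peak) and an H1X-like variant
# (GC-seeking, LAD-depleted, shallower valley, +1 peak present).
H12_LIKE = VariantModel(gc_coupling=-0.8, lad_log_enrichment=0.7,
                        tss_valley_depth=0.9, valley_halfwidth=400,
                        plus1_peak_amp=0.0, name="H1.2-like")
H1X_LIKE = VariantModel(gc_coupling=0.8, lad_log_enrichment=-0.7,
                        tss_valley_depth=0.5, valley_halfwidth=250,
                        plus1_peak_amp=0.6, name="H1X-like")


@dataclass
class SyntheticTruth:
    """Ground truth of one synthetic genome (annotation side)."""

    genome: Genome
    gc: SignalTrack  # GC fraction per 50-bp bin
    lads: RegionSet
    genes: GeneSet
    seed: int
    model: VariantModel | None = None


def _gc_landscape(n_bins: int, rng: np.random.Generator,
                  smooth_bins: float = 100.0) -> np.ndarray:
    """Logistic-squashed smoothed Gaussian random walk in [0.3, 0.7]."""
    walk = np.cumsum(rng.normal(size=n_bins))
    smooth = gaussian_filter1d(walk, smooth_bins, mode="nearest")
    z = (smooth - smooth.mean()) / max(smooth.std(), 1e-12)
    return 0.3 + 0.4 / (1.0 + np.exp(-z))


def _place_lads(genome: Genome, gc: SignalTrack, n_lads: int, lad_length: int,
                ) -> RegionSet:
    """LADs centered on the lowest-GC stretches (broadly smoothed GC),
    non-overlapping, greedy from the global minimum up."""
    if n_lads == 0:
        return RegionSet.empty()
    half = lad_length // 2
    broad = {c: gaussian_filter1d(gc.values[c], lad_length / GC_BIN / 2, mode="nearest")
             for c in genome.chrom_names}
    # mask bins too close to a chromosome end to center a LAD
    for c in genome.chrom_names:
        L = genome.length_of(c)
        centers_bp = np.arange(len(broad[c])) * GC_BIN + GC_BIN // 2
        broad[c][(centers_bp < half) | (centers_bp > L - half)] = np.inf
    rows = []
    for _ in range(n_lads):
        best_chrom, best_bin, best_val = None, None, np.inf
        for c in genome.chrom_names:
            i = int(np.argmin(broad[c]))
            if broad[c][i] < best_val:
                best_chrom, best_bin, best_val = c, i, broad[c][i]
        if best_chrom is None or not np.isfinite(best_val):
            raise ValueError(f"could not place {n_lads} LADs of {lad_length} bp")
        center = best_bin * GC_BIN + GC_BIN // 2
        start, end = center - half, center + half
        rows.append((best_chrom, int(start), int(end)))
        lo = max((start - lad_length) // GC_BIN, 0)
        hi = min((end + lad_length) // GC_BIN + 1, len(broad[best_chrom]))
        broad[best_chrom][lo:hi] = np.inf
    rows.sort()
    return RegionSet.from_records(rows, names=[f"LAD{i}" for i in range(len(rows))])


def _lad_mask(genome: Genome, lads: RegionSet, bin_size: int) -> dict[str, np.ndarray]:
    """Bin membership by bin midpoint, per chromosome."""
    mask = {c: np.zeros(genome.n_bins(c, bin_size), dtype=bool)
            for c in genome.chrom_names}
    for chrom, start, end in lads:
        mids = np.arange(len(mask[chrom])) * bin_size + bin_size // 2
        mask[chrom] |= (mids >= start) & (mids < end)
    return mask


def generate_genome(n_chrom: int = 2, chrom_length: int = 5_000_000,
                    n_genes: int = 400, n_lads: int = 20, seed: int = 0,
                    gene_length_range: tuple[int, int] = (2_000, 20_000),
                    gene_spacing: int = 1_000, gc_gamma: float = 5.0,
                    lad_length: int = 150_000,
                    p_gene_outside_lad: float = 0.8) -> SyntheticTruth:
    """Build a toy genome: GC landscape, LADs, genes, expression.

    Genes land with probability proportional to exp(gc_gamma * GC)
    within their LAD stratum (outside LADs with probability
    ``p_gene_outside_lad``), keep >= ``gene_spacing`` bp apart, and
    draw expression from LogNormal(0, 1), scaled down 4x inside LADs
    (stored on the log2 scale).
    """
    if n_chrom < 1:
        raise ValueError("n_chrom >= 1 required")
    rng = np.random.default_rng(seed)
    genome = Genome(tuple(f"chr{i + 1}" for i in range(n_chrom)),
                    tuple([chrom_length] * n_chrom))
    gc = SignalTrack(bin_size=GC_BIN,
                     values={c: _gc_landscape(genome.n_bins(c, GC_BIN), rng)
                             for c in genome.chrom_names})
    lads = _place_lads(genome, gc, n_lads, lad_length)
    lad_bins = _lad_mask(genome, lads, GC_BIN)

    # flattened sampling frame over (chrom, bin)
    chroms_flat = np.concatenate([np.full(genome.n_bins(c, GC_BIN), i)
                                  for i, c in enumerate(genome.chrom_names)])
    binidx_flat = np.concatenate([np.arange(genome.n_bins(c, GC_BIN))
                                  for c in genome.chrom_names])
    gc_flat = np.concatenate([gc.values[c] for c in genome.chrom_names])
    lad_flat = np.concatenate([lad_bins[c] for c in genome.chrom_names])
    weights = np.exp(gc_gamma * gc_flat)

    strata: dict[bool, tuple[np.ndarray, np.ndarray]] = {}
    for in_lad in (False, True):
        idx = np.flatnonzero(lad_flat == in_lad)
        if len(idx):
            cum = np.cumsum(weights[idx])
            strata[in_lad] = (idx, cum / cum[-1])

    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in genome.chrom_names}
    rows = []
    attempts, max_attempts = 0, 200 * max(n_genes, 1)
    gi = 0
    while gi < n_genes:
        attempts += 1
        if attempts > max_attempts:
            occ = sum(e - s for ivs in placed.values() for s, e in ivs)
            raise ValueError(
                f"gene placement infeasible: {gi}/{n_genes} placed, "
                f"{occ}/{genome.total_bp} bp occupied after {attempts} attempts")
        want_in_lad = bool(True in strata and rng.random() > p_gene_outside_lad)
        if want_in_lad not in strata:
            want_in_lad = not want_in_lad
        idx, cdf = strata[want_in_lad]
        pick = idx[np.searchsorted(cdf, rng.random())]
        chrom = genome.chrom_names[int(chroms_flat[pick])]
        start = int(binidx_flat[pick]) * GC_BIN + int(rng.integers(GC_BIN))
        length = int(rng.integers(gene_length_range[0], gene_length_range[1] + 1))
        end = start + length
        if end + gene_spacing > genome.length_of(chrom):
            continue
        ivs = placed[chrom]
        j = bisect.bisect_left(ivs, (start, end))
        if j > 0 and ivs[j - 1][1] + gene_spacing > start:
            continue
        if j < len(ivs) and end + gene_spacing > ivs[j][0]:
            continue
        ivs.insert(j, (start, end))
        strand = "+" if rng.random() < 0.5 else "-"
        expr_linear = float(rng.lognormal(0.0, 1.0))
        if want_in_lad:
            expr_linear /= 4.0
        rows.append({"id": f"g{gi:04d}", "chrom": chrom, "start": start, "end": end,
                     "strand": strand, "expression": float(np.log2(expr_linear)),
                     "in_lad": want_in_lad})
        gi += 1

    if rows:
        genes_df = pd.DataFrame(rows).sort_values(["chrom", "start"], kind="stable")
    else:
        genes_df = pd.DataFrame({"id": pd.Series(dtype=str), "chrom": pd.Series(dtype=str),
                                 "start": pd.Series(dtype=int), "end": pd.Series(dtype=int),
                                 "strand": pd.Series(dtype=str),
                                 "expression": pd.Series(dtype=float)})
    return SyntheticTruth(genome=genome, gc=gc, lads=lads,
                          genes=GeneSet(genes_df), seed=seed)


def intensity_field(truth: SyntheticTruth, model: VariantModel) -> SignalTrack:
    """Expected per-bin read intensity (unnormalized), combining GC
    coupling, LAD enrichment, expression-rank-scaled TSS valleys and the
    optional strand-aware +1 peak."""
    genome, gc = truth.genome, truth.gc
    lad_bins = _lad_mask(genome, truth.lads, GC_BIN)
    values = {}
    for c in genome.chrom_names:
        values[c] = np.exp(model.gc_coupling * gc.values[c]
                           + model.lad_log_enrichment * lad_bins[c])

    genes = truth.genes
    if len(genes) and (model.tss_valley_depth > 0 or model.plus1_peak_amp > 0):
        expr = genes.df["expression"].to_numpy()
        order = np.argsort(np.argsort(expr, kind="stable"), kind="stable")
        n = len(genes)
        rank_scaled = (order + 1) / n  # highest expression -> 1
        tss = genes.tss
        plus = genes.df["strand"].to_numpy() == "+"
        for i in range(n):
            chrom = str(genes.df["chrom"].iloc[i])
            vec = values[chrom]
            centers = np.arange(len(vec)) * GC_BIN + GC_BIN // 2
            t0 = int(tss[i])
            if model.tss_valley_depth > 0:
                hw = model.valley_halfwidth
                lo = max((t0 - 5 * hw) // GC_BIN, 0)
                hi = min((t0 + 5 * hw) // GC_BIN + 1, len(vec))
                d = model.tss_valley_depth * rank_scaled[i]
                bump = d * np.exp(-0.5 * ((centers[lo:hi] - t0) / hw) ** 2)
                vec[lo:hi] *= (1.0 - bump)
            if model.plus1_peak_amp > 0:
                hw = model.plus1_halfwidth
                c0 = t0 + model.plus1_center if plus[i] else t0 - model.plus1_center
                lo = max((c0 - 5 * hw) // GC_BIN, 0)
                hi = min((c0 + 5 * hw) // GC_BIN + 1, len(vec))
                bump = model.plus1_peak_amp * np.exp(
                    -0.5 * ((centers[lo:hi] - c0) / hw) ** 2)
                vec[lo:hi] *= (1.0 + bump)
    track = SignalTrack(bin_size=GC_BIN, values=values)
    for c, vec in track.values.items():
        if np.any(vec < 0):
            raise ValueError(f"negative intensity on {c}; check valley depth")
    return track


def _sample_reads(genome: Genome, probs_flat: np.ndarray, chrom_of_bin: np.ndarray,
                  binidx: np.ndarray, depth: int, rng: np.random.Generator) -> ReadSet:
    counts = rng.multinomial(depth, probs_flat)
    hit = np.flatnonzero(counts)
    reps = counts[hit]
    chrom_codes = np.repeat(chrom_of_bin[hit], reps)
    bins = np.repeat(binidx[hit], reps)
    offsets = rng.integers(0, GC_BIN, size=len(bins))
    pos = bins * GC_BIN + offsets
    # clip reads in a trailing partial bin to the chromosome
    lengths = np.array(genome.chrom_lengths)[chrom_codes]
    pos = np.minimum(pos, lengths - 1)
    strand = np.where(rng.random(len(bins)) < 0.5, "+", "-")
    names = np.array(genome.chrom_names, dtype=object)
    df = pd.DataFrame({"chrom": names[chrom_codes], "pos": pos, "strand": strand})
    return ReadSet(df)


def simulate_reads(truth: SyntheticTruth, model: VariantModel
                   ) -> tuple[ReadSet, ReadSet]:
    """Draw (chip, input) read sets of ``model.depth`` reads each.

    ChIP 5' positions are a multinomial sample from the normalized
    intensity field (uniform within the bin, uniform strand); the input
    library is a uniform sample over the genome.
    """
    genome = truth.genome
    intensity = intensity_field(truth, model)
    flat = np.concatenate([intensity.values[c] for c in genome.chrom_names])
    chrom_of_bin = np.concatenate([np.full(genome.n_bins(c, GC_BIN), i)
                                   for i, c in enumerate(genome.chrom_names)])
    binidx = np.concatenate([np.arange(genome.n_bins(c, GC_BIN))
                             for c in genome.chrom_names])
    # weight bins by their bp footprint so partial end bins are not oversampled
    widths = np.minimum((binidx + 1) * GC_BIN,
                        np.array(genome.chrom_lengths)[chrom_of_bin]) - binidx * GC_BIN
    probs = flat * widths
    probs = probs / probs.sum()
    rng = np.random.default_rng(model.seed)
    chip = _sample_reads(genome, probs, chrom_of_bin, binidx, model.depth, rng)
    uniform = widths / widths.sum()
    input_ = _sample_reads(genome, uniform, chrom_of_bin, binidx, model.depth, rng)
    return chip, input_


def write_bundle(truth: SyntheticTruth, models: list[VariantModel], outdir) -> None:
    """Write the full fixture bundle (chrom.sizes, annotation, tracks,
    per-variant read BEDs and the truth.yaml parameter record)."""
    from pathlib import Path

    from . import io as h1io

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    h1io.write_chrom_sizes(truth.genome, out / "chrom.sizes")
    h1io.write_genes(truth.genes, out / "genes.tsv", out / "expression.tsv")
    h1io.write_bed(truth.lads, out / "lads.bed")
    h1io.write_bedgraph(truth.gc, out / "gc.bedgraph")
    meta: dict = {"seed": truth.seed, "variants": {}}
    for model in models:
        chip, inp = simulate_reads(truth, model)
        safe = model.name.replace("/", "_").replace(" ", "_")
        h1io.write_reads_bed(chip, out / f"{safe}.chip.bed")
        h1io.write_reads_bed(inp, out / f"{safe}.input.bed")
        meta["variants"][model.name] = {
            k: getattr(model, k) for k in (
                "gc_coupling", "lad_log_enrichment", "tss_valley_depth",
                "valley_halfwidth", "plus1_peak_amp", "plus1_center",
                "plus1_halfwidth", "depth", "seed")}
    (out / "truth.yaml").write_text(yaml.safe_dump(meta, sort_keys=True))
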