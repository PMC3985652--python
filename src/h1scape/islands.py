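"""Window-based enriched/depleted island detection and annotation.

The caller follows the two-stage design of window/gap histone peak
callers: reads are deduplicated, extended-fragment midpoints are counted
in non-overlapping windows, windows beating a Poisson background
threshold (p < 0.2 against the genome-wide rate over the effective
genome fraction) are merged into islands across bounded gaps, and each
island is scored and tested against the same Poisson background, with
Benjamini-Hochberg control of the island-level FDR and a library-
normalized fold-change filter. Depleted islands are called by swapping
the ChIP and input channels.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd
from scipy.stats import poisson
from statsmodels.stats.multitest import multipletests

from .genome import GeneSet, Genome, ReadSet, RegionSet

__all__ = [
    "IslandParams", "Island", "FeatureClass", "call_islands",
    "islands_to_regionset", "annotate_nearest_gene", "classify_feature",
    "classify_regions", "target_genes", "overlap_regions",
]


@dataclass(frozen=True)
class IslandParams:
    window: int = 200
    gap: int = 200
    fdr: float = 0.01
    min_fold_change: float = 2.0
    fragment_size: int = 150
    effective_genome_fraction: float = 0.75
    redundancy_threshold: int = 1
    window_pvalue: float = 0.2  # per-window eligibility threshold

    def __post_init__(self) -> None:
        if self.window < 1:
            raise ValueError("window must be >= 1")
        if self.gap % self.window:
            raise ValueError("gap must be a multiple of window")
        if not 0 < self.fdr < 1:
            raise ValueError("fdr must be in (0, 1)")
        if self.min_fold_change <= 0:
            raise ValueError("min_fold_change must be > 0")


@dataclass
class Island:
    chrom: str
    start: int
    end: int
    chip_count: int
    input_count: int
    fold_change: float
    score: float
    p_value: float
    q_value: float
    direction: str  # enriched | depleted


class FeatureClass(str, Enum):
    PROMOTER = "promoter"
    UTR5 = "5'UTR"
    EXON = "exon"
    INTRON = "intron"
    UTR3 = "3'UTR"
    GENIC = "genic"  # undivided gene body when exon structure is absent
    DOWNSTREAM = "downstream"
    DISTAL = "distal intergenic"


def _dedup(reads: ReadSet, threshold: int) -> ReadSet:
    if threshold < 1:
        raise ValueError("redundancy threshold must be >= 1")
    df = reads.df
    if threshold == 1:
        return reads.dedup()
    keep = df.groupby(["chrom", "pos", "strand"], sort=False,
                      observed=True).cumcount() < threshold
    return ReadSet(df[keep])


def _midpoints(reads: ReadSet, genome: Genome, fragment_size: int) -> dict[str, np.ndarray]:
    """Extended-fragment midpoint per read, clipped to the chromosome."""
    out: dict[str, np.ndarray] = {}
    half = fragment_size // 2
    for chrom, sub in reads.df.groupby("chrom", sort=False, observed=True):
        pos = sub["pos"].to_numpy(dtype=np.int64)
        plus = sub["strand"].to_numpy() == "+"
        mid = np.where(plus, pos + half, pos - half)
        out[str(chrom)] = np.clip(mid, 0, genome.length_of(str(chrom)) - 1)
    return out


def _eligibility_threshold(lam: float, p: float) -> int:
    """Smallest count k >= 1 with P(Poisson(lam) >= k) < p."""
    k = max(int(poisson.isf(p, lam)), 0)
    while poisson.sf(k - 1, lam) >= p:
        k += 1
    while k > 1 and poisson.sf(k - 2, lam) < p:
        k -= 1
    return max(k, 1)


def call_islands(chip: ReadSet, input_: ReadSet, genome: Genome,
                 params: IslandParams | None = None,
                 direction: str = "enriched") -> list[Island]:
    """Call islands of ChIP enrichment (or depletion) over input.

    Candidate islands are formed genome-wide, assigned Poisson tail
    p-values for their total window count against the background rate,
    BH-corrected jointly, and reported if ``q <= fdr`` and the
    library-normalized fold change is at least ``min_fold_change``
    (input count floored at 1 read).
    """
    params = params or IslandParams()
    if direction not in ("enriched", "depleted"):
        raise ValueError(f"direction must be enriched or depleted, got {direction!r}")
    if direction == "depleted":
        chip, input_ = input_, chip
    if max(genome.chrom_lengths) < params.window:
        raise ValueError("genome smaller than one window")
    chip = _dedup(chip, params.redundancy_threshold)
    input_ = _dedup(input_, params.redundancy_threshold)
    if chip.libsize == 0:
        return []

    w = params.window
    lam0 = chip.libsize * w / (genome.total_bp * params.effective_genome_fraction)
    k_min = _eligibility_threshold(lam0, params.window_pvalue)
    gap_windows = params.gap // w

    chip_mids = _midpoints(chip, genome, params.fragment_size)
    input_mids = _midpoints(input_, genome, params.fragment_size)

    records: list[tuple[str, int, int, int, float]] = []  # chrom, first_w, last_w, chip_n, score
    for chrom in genome.chrom_names:
        mids = chip_mids.get(chrom)
        if mids is None or len(mids) == 0:
            continue
        n_win = genome.length_of(chrom) // w
        if n_win == 0:
            continue
        widx = np.minimum(mids // w, n_win - 1)
        counts = np.bincount(widx, minlength=n_win)
        eligible = np.flatnonzero(counts >= k_min)
        if len(eligible) == 0:
            continue
        breaks = np.flatnonzero(np.diff(eligible) > gap_windows + 1)
        starts = np.concatenate([[0], breaks + 1])
        ends = np.concatenate([breaks, [len(eligible) - 1]])
        with np.errstate(divide="ignore"):
            win_scores = -poisson.logpmf(counts, lam0)
        for a, b in zip(starts, ends):
            first, last = int(eligible[a]), int(eligible[b])
            members = eligible[a:b + 1]
            chip_n = int(counts[first:last + 1].sum())
            score = float(win_scores[members].sum())
            records.append((chrom, first, last, chip_n, score))

    if not records:
        return []

    # island p-values: Poisson tail of the spanned-window total count
    p_values = np.empty(len(records))
    input_counts = np.empty(len(records), dtype=int)
    for i, (chrom, first, last, chip_n, _score) in enumerate(records):
        span_windows = last - first + 1
        p_values[i] = poisson.sf(chip_n - 1, lam0 * span_windows)
        imids = input_mids.get(chrom)
        if imids is None:
            input_counts[i] = 0
        else:
            lo, hi = first * w, min((last + 1) * w, genome.length_of(chrom))
            input_counts[i] = int(((imids >= lo) & (imids < hi)).sum())

    q_values = multipletests(p_values, method="fdr_bh")[1]

    islands: list[Island] = []
    for i, (chrom, first, last, chip_n, score) in enumerate(records):
        inp_eff = max(int(input_counts[i]), 1)  # 1-read pseudocount
        fc = (chip_n / chip.libsize) / (inp_eff / max(input_.libsize, 1))
        if q_values[i] <= params.fdr and fc >= params.min_fold_change:
            islands.append(Island(
                chrom=chrom,
                start=first * w,
                end=min((last + 1) * w, genome.length_of(chrom)),
                chip_count=chip_n,
                input_count=int(input_counts[i]),
                fold_change=float(fc),
                score=score,
                p_value=float(p_values[i]),
                q_value=float(q_values[i]),
                direction=direction,
            ))
    return islands


def islands_to_regionset(islands: list[Island]) -> RegionSet:
    if not islands:
        return RegionSet.empty()
    df = pd.DataFrame([{
        "chrom": isl.chrom, "start": isl.start, "end": isl.end,
        "name": f"{isl.direction}_{i}", "score": isl.score,
        "fold_change": isl.fold_change, "p_value": isl.p_value,
        "q_value": isl.q_value, "direction": isl.direction,
    } for i, isl in enumerate(islands)])
    return RegionSet(df)


def annotate_nearest_gene(islands: RegionSet, genes: GeneSet) -> pd.DataFrame:
    """Nearest TSS per island midpoint; distance signed by the gene's
    orientation (negative = transcriptionally upstream of the TSS).
    Equidistant ties go to the gene at the smaller genomic coordinate;
    islands on gene-free chromosomes come back unassigned."""
    gdf = genes.df.assign(_tss=genes.tss).sort_values(
        ["chrom", "_tss", "start", "id"], kind="stable")
    by_chrom = {str(c): sub for c, sub in gdf.groupby("chrom", sort=False, observed=True)}
    out = []
    for i, (chrom, start, end) in enumerate(islands):
        mid = (start + end - 1) // 2
        sub = by_chrom.get(str(chrom))
        if sub is None or sub.empty:
            out.append({"island_index": i, "chrom": chrom, "start": start, "end": end,
                        "gene_id": None, "distance": np.nan, "assigned": False})
            continue
        tss = sub["_tss"].to_numpy()
        j = np.searchsorted(tss, mid)
        best, best_d = None, None
        for cand in (j - 1, j):
            if 0 <= cand < len(tss):
                d = abs(int(tss[cand]) - mid)
                # strict < keeps the smaller-coordinate gene on ties
                if best_d is None or d < best_d:
                    best, best_d = cand, d
        row = sub.iloc[best]
        signed = (mid - int(row["_tss"])) if row["strand"] == "+" \
            else (int(row["_tss"]) - mid)
        out.append({"island_index": i, "chrom": chrom, "start": start, "end": end,
                    "gene_id": row["id"], "distance": int(signed), "assigned": True})
    return pd.DataFrame(out)


_PRIORITY = [FeatureClass.PROMOTER, FeatureClass.UTR5, FeatureClass.EXON,
             FeatureClass.INTRON, FeatureClass.UTR3, FeatureClass.GENIC,
             FeatureClass.DOWNSTREAM, FeatureClass.DISTAL]


def classify_feature(region: tuple[str, int, int], genes: GeneSet,
                     promoter_bp: int = 3000, downstream_bp: int = 3000) -> FeatureClass:
    """Assign a region (by midpoint) to a genomic feature class.

    Promoter = up to ``promoter_bp`` upstream of a TSS; downstream = up
    to ``downstream_bp`` past the TTS; within a gene body, exon/intron
    if the gene carries exon structure, else the undivided "genic"
    class. Overlapping annotations resolve by the fixed priority
    promoter > 5'UTR > exon > intron > 3'UTR > genic > downstream.
    """
    chrom, start, end = region
    mid = (start + end - 1) // 2
    df = genes.df
    sub = df[df["chrom"] == chrom]
    candidates: set[FeatureClass] = set()
    has_exons = "exons" in df.columns
    for idx, g in sub.iterrows():
        plus = g["strand"] == "+"
        tss = g["start"] if plus else g["end"] - 1
        tts = g["end"] - 1 if plus else g["start"]
        t = (mid - tss) if plus else (tss - mid)
        if -promoter_bp <= t < 0:
            candidates.add(FeatureClass.PROMOTER)
        if g["start"] <= mid < g["end"]:
            exons = g.get("exons") if has_exons else None
            if exons:
                in_exon = any(s <= mid < e for s, e in exons)
                candidates.add(FeatureClass.EXON if in_exon else FeatureClass.INTRON)
            else:
                candidates.add(FeatureClass.GENIC)
        t_tts = (mid - tts) if plus else (tts - mid)
        if 0 < t_tts <= downstream_bp:
            candidates.add(FeatureClass.DOWNSTREAM)
    for cls in _PRIORITY:
        if cls in candidates:
            return cls
    return FeatureClass.DISTAL


def classify_regions(regions: RegionSet, genes: GeneSet,
                     promoter_bp: int = 3000, downstream_bp: int = 3000
                     ) -> list[FeatureClass]:
    return [classify_feature(r, genes, promoter_bp, downstream_bp) for r in regions]


def target_genes(islands: RegionSet, genes: GeneSet,
                 up: int = 5000, down: int = 3000) -> pd.Series:
    """Per-gene island counts over the extended span TSS-``up`` ..
    TTS+``down`` (strand-aware, >= 1 bp overlap); only genes with at
    least one overlapping island are returned."""
    plus = genes.df["strand"].to_numpy() == "+"
    span_start = np.where(plus, genes.df["start"].to_numpy() - up,
                          genes.df["start"].to_numpy() - down)
    span_end = np.where(plus, genes.df["end"].to_numpy() + down,
                        genes.df["end"].to_numpy() + up)
    spans = RegionSet(pd.DataFrame({
        "chrom": genes.df["chrom"],
        "start": span_start,  # may extend past the chromosome; overlap math is unaffected
        "end": span_end,
        "name": genes.df["id"],
    }))
    _pairs, flags = overlap_regions(spans, islands)
    counts = np.zeros(len(genes), dtype=int)
    for i, _j in _pairs:
        counts[i] += 1
    hit = counts > 0
    return pd.Series(counts[hit], index=pd.Index(genes.df["id"].to_numpy()[hit], name="id"),
                     name="island_count")


def overlap_regions(a: RegionSet, b: RegionSet
                    ) -> tuple[list[tuple[int, int]], np.ndarray]:
    """All index pairs (i, j) with >= 1 bp intersection, plus a per-``a``
    overlap flag. Sweep over ``b`` sorted by start per chromosome."""
    flags = np.zeros(len(a), dtype=bool)
    pairs: list[tuple[int, int]] = []
    if len(a) == 0 or len(b) == 0:
        return pairs, flags
    b_by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    bdf = b.df
    for chrom, sub in bdf.groupby("chrom", sort=False, observed=True):
        order = np.argsort(sub["start"].to_numpy(), kind="stable")
        idx = sub.index.to_numpy()[order]
        b_by_chrom[str(chrom)] = (sub["start"].to_numpy()[order],
                                  sub["end"].to_numpy()[order], idx)
    for i, (chrom, start, end) in enumerate(a):
        entry = b_by_chrom.get(str(chrom))
        if entry is None:
            continue
        bs, be, bidx = entry
        hi = np.searchsorted(bs, end)  # b.start < a.end
        if hi == 0:
            continue
        sel = np.flatnonzero(be[:hi] > start)
        if len(sel):
            flags[i] = True
            pairs.extend((i, int(bidx[j])) for j in sel)
    return pairs, flags
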