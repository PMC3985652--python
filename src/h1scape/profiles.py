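"""Anchored average-signal profiles: TSS windows, metagenes, site centers.

A profile cell at transcriptional offset ``o`` covers transcribed bases
``[o, o + bin)`` relative to the anchor (offset 0 = the anchor base
itself); minus-strand rows are computed on mirrored genomic coordinates
so "upstream" is always transcriptionally upstream. Cell values are the
exact per-bp mean of the binned track over the cell's genomic footprint
(length-weighted over overlapping source bins), so the profile is
independent of how the anchor aligns to the track's bin grid. Cells
extending beyond a chromosome are masked (NaN).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess

from .genome import GeneSet, RegionSet, SignalTrack

__all__ = [
    "ProfileSpec", "MetageneSpec", "ProfileMatrix",
    "anchored_profile", "column_mean_profile", "loess_profile",
    "expression_deciles", "metagene_profile", "metagene_matrix",
]


@dataclass(frozen=True)
class ProfileSpec:
    """Fixed window around an anchor: upstream 3.2 kb, downstream 800 bp,
    50-bp bins by default (the promoter window used throughout)."""

    upstream: int = 3200
    downstream: int = 800
    bin: int = 50
    anchor: str = "tss"  # tss | tts | site-center

    def __post_init__(self) -> None:
        if self.upstream < 0 or self.downstream < 0 or self.bin < 1:
            raise ValueError("window extents must be >= 0 and bin >= 1")
        if (self.upstream + self.downstream) % self.bin:
            raise ValueError("(upstream + downstream) must be a multiple of bin")
        if self.anchor not in ("tss", "tts", "site-center"):
            raise ValueError(f"unknown anchor {self.anchor!r}")

    @property
    def n_cols(self) -> int:
        return (self.upstream + self.downstream) // self.bin

    @property
    def offsets(self) -> np.ndarray:
        """Left-edge transcriptional offset of each column."""
        return -self.upstream + np.arange(self.n_cols) * self.bin


@dataclass(frozen=True)
class MetageneSpec:
    """Length-normalized gene body (default 60 bins ~ a 3-kb metagene at
    50 bp) flanked by fixed-bp margins at native track resolution."""

    body_bins: int = 60
    flank: int = 1000
    min_gene_length: int | None = None  # default body_bins * 10 bp

    def __post_init__(self) -> None:
        if self.body_bins < 1 or self.flank < 0:
            raise ValueError("body_bins >= 1 and flank >= 0 required")

    def resolved_min_length(self) -> int:
        return self.min_gene_length if self.min_gene_length is not None \
            else self.body_bins * 10


@dataclass
class ProfileMatrix:
    """Rows = genes/sites, columns = position bins; NaN cells are masked."""

    values: np.ndarray
    row_ids: list[str]
    col_labels: np.ndarray  # bp offsets or metagene bin labels

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.row_ids), len(self.col_labels)):
            raise ValueError("ProfileMatrix shape mismatch")

    @property
    def n_rows(self) -> int:
        return len(self.row_ids)


def _integral_at(track: SignalTrack, chrom: str, xs: np.ndarray) -> np.ndarray:
    """Integral of the per-bp step signal from 0 to x, vectorized; xs must
    lie in [0, chrom_length]."""
    v = track.values[chrom]
    bs = track.bin_size
    prefix = track._prefix(chrom)
    xs = np.asarray(xs, dtype=float)
    i = np.minimum((xs // bs).astype(np.int64), len(v))
    frac = xs - i * bs
    inside = i < len(v)
    contrib = np.where(inside, frac * v[np.minimum(i, len(v) - 1)], 0.0)
    return prefix[i] + contrib


def windowed_means(track: SignalTrack, chrom: str, boundaries: np.ndarray) -> np.ndarray:
    """Mean signal over the contiguous genomic cells delimited by an
    increasing boundary array; cells outside [0, L] come back NaN."""
    L = float(len(track.values[chrom]) * track.bin_size)
    true_L = L  # the last bin may be partial but signal is defined on the grid
    b = np.asarray(boundaries, dtype=float)
    valid = (b[:-1] >= 0) & (b[1:] <= true_L)
    clipped = np.clip(b, 0, true_L)
    integ = _integral_at(track, chrom, clipped)
    widths = np.diff(b)
    out = np.full(len(widths), np.nan)
    ok = valid & (widths > 0)
    out[ok] = np.diff(integ)[ok] / widths[ok]
    return out


def _anchor_positions(anchors: GeneSet | RegionSet, spec_anchor: str
                      ) -> tuple[list[str], np.ndarray, np.ndarray, np.ndarray]:
    """(ids, chroms, anchor bp, strand) for either anchor container."""
    if isinstance(anchors, GeneSet):
        df = anchors.df
        if spec_anchor == "tss":
            pos = anchors.tss
        elif spec_anchor == "tts":
            pos = anchors.tts
        else:
            pos = (df["start"].to_numpy() + df["end"].to_numpy() - 1) // 2
        if df["strand"].isna().any():
            raise ValueError("anchors with missing strand")
        return df["id"].astype(str).tolist(), df["chrom"].to_numpy(), pos, \
            df["strand"].to_numpy()
    df = anchors.df
    if spec_anchor in ("tss", "tts"):
        raise ValueError("RegionSet anchors support only anchor='site-center'")
    pos = (df["start"].to_numpy() + df["end"].to_numpy() - 1) // 2
    ids = df["name"].astype(str).tolist() if "name" in df.columns else \
        [f"region{i}" for i in range(len(df))]
    strand = df["strand"].to_numpy() if "strand" in df.columns else \
        np.full(len(df), "+")
    return ids, df["chrom"].to_numpy(), pos, strand


def _row_means(track: SignalTrack, chrom: str, anchor: int, strand: str,
               t_boundaries: np.ndarray) -> np.ndarray:
    """Cell means for one row given transcriptional cell boundaries."""
    if strand == "+":
        gb = anchor + t_boundaries
        return windowed_means(track, chrom, gb)
    # minus strand: transcribed base t sits at genomic anchor - t
    gb = (anchor + 1) - t_boundaries[::-1]
    return windowed_means(track, chrom, gb)[::-1]


def anchored_profile(track: SignalTrack, anchors: GeneSet | RegionSet,
                     spec: ProfileSpec | None = None) -> ProfileMatrix:
    """Signal matrix over ``[-upstream, +downstream)`` around each anchor."""
    spec = spec or ProfileSpec()
    ids, chroms, pos, strands = _anchor_positions(anchors, spec.anchor)
    tb = np.concatenate([spec.offsets, [spec.offsets[-1] + spec.bin]]).astype(float)
    rows = np.full((len(ids), spec.n_cols), np.nan)
    for i, (chrom, p, s) in enumerate(zip(chroms, pos, strands)):
        if chrom not in track.values:
            continue
        rows[i] = _row_means(track, str(chrom), int(p), str(s), tb)
    return ProfileMatrix(rows, ids, spec.offsets)


def column_mean_profile(matrix: ProfileMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Per-column mean over unmasked cells and the per-column n; a fully
    masked column yields NaN, never 0."""
    if matrix.n_rows == 0:
        raise ValueError("empty profile matrix")
    n = np.sum(~np.isnan(matrix.values), axis=0)
    with np.errstate(invalid="ignore"):
        means = np.where(n > 0, np.nansum(matrix.values, axis=0) / np.maximum(n, 1),
                         np.nan)
    return means, n


def loess_profile(profile: np.ndarray, span: float = 0.1) -> np.ndarray:
    """LOESS smoothing (tricube weights, local degree-1 fits) of a profile.

    ``span`` is the fraction of points in each local window; it must
    cover at least 3 neighbors. Cosmetic: defaults match the smooth TSS
    line plots, exact on linear inputs.
    """
    y = np.asarray(profile, dtype=float)
    n = len(y)
    if n < 3:
        raise ValueError("need >= 3 points")
    if not 0 < span <= 1:
        raise ValueError("span must be in (0, 1]")
    if int(span * n) < 3:
        raise ValueError(f"span too small: need span >= {3 / n:.6g} "
                         f"to include >= 3 neighbors")
    x = np.arange(n, dtype=float)
    return _sm_lowess(y, x, frac=span, it=0, return_sorted=False)


def expression_deciles(genes: GeneSet, n_groups: int = 10
                       ) -> tuple[pd.Series, int]:
    """Partition expressed genes into equal-size expression groups.

    Genes are ranked by expression descending (EG1 = highest); with
    ``N = n_groups*q + r`` genes the first ``r`` groups take ``q + 1``.
    Ties are broken by stable order of gene id. Returns a Series of
    labels indexed by gene id and the count of missing-expression genes
    excluded.
    """
    df = genes.df
    n_missing = int(df["expression"].isna().sum())
    expressed = df[df["expression"].notna()].copy()
    N = len(expressed)
    if N == 0:
        raise ValueError("all expression values missing")
    if N < n_groups:
        raise ValueError(f"need >= {n_groups} expressed genes, got {N}")
    expressed = expressed.sort_values("id", kind="stable")
    order = np.argsort(-expressed["expression"].to_numpy(), kind="stable")
    ranked_ids = expressed["id"].to_numpy()[order]
    q, r = divmod(N, n_groups)
    labels = np.empty(N, dtype=object)
    start = 0
    for g in range(n_groups):
        size = q + (1 if g < r else 0)
        labels[start:start + size] = f"EG{g + 1}"
        start += size
    return pd.Series(labels, index=pd.Index(ranked_ids, name="id"), name="group"), \
        n_missing


def metagene_matrix(track: SignalTrack, genes: GeneSet,
                    spec: MetageneSpec | None = None) -> ProfileMatrix:
    """Per-gene metagene rows: upstream flank at native bins, gene body
    rescaled to ``body_bins`` by length-weighted averaging, downstream
    flank at native bins; minus-strand genes flipped."""
    spec = spec or MetageneSpec()
    bs = track.bin_size
    if spec.flank % bs:
        raise ValueError("flank must be a multiple of the track bin size")
    min_len = spec.resolved_min_length()
    keep = genes.df[(genes.df["end"] - genes.df["start"]) >= min_len]
    if keep.empty:
        raise ValueError(f"no gene passes the min length filter ({min_len} bp)")
    sub = GeneSet(keep.copy())
    n_flank = spec.flank // bs
    tss, lengths = sub.tss, sub.lengths
    n_cols = 2 * n_flank + spec.body_bins
    rows = np.full((len(sub), n_cols), np.nan)
    for i in range(len(sub)):
        L = float(lengths[i])
        up = -spec.flank + np.arange(n_flank + 1, dtype=float) * bs
        body = np.arange(1, spec.body_bins + 1, dtype=float) * (L / spec.body_bins)
        down = L + np.arange(1, n_flank + 1, dtype=float) * bs
        tb = np.concatenate([up, body, down])
        chrom = str(sub.df["chrom"].iloc[i])
        rows[i] = _row_means(track, chrom, int(tss[i]), str(sub.df["strand"].iloc[i]), tb)
    labels = np.array(
        [f"up{j - n_flank}" for j in range(n_flank)]
        + [f"body{j + 1}" for j in range(spec.body_bins)]
        + [f"down{j + 1}" for j in range(n_flank)], dtype=object)
    return ProfileMatrix(rows, sub.df["id"].astype(str).tolist(), labels)


def metagene_profile(track: SignalTrack, genes: GeneSet,
                     spec: MetageneSpec | None = None) -> np.ndarray:
    """Mean metagene vector (flank + rescaled body + flank) over genes."""
    means, _ = column_mean_profile(metagene_matrix(track, genes, spec))
    return means
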