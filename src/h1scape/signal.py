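"""Read sets -> normalized, input-subtracted binned signal.

Reads are extended to a fixed fragment size from their 5' end in the
read direction (the single-end convention used by window-based histone
peak callers); a bin counts every extended fragment overlapping it by at
least one base. Normalization is reads-per-million by total mapped
library size, and the background is removed by subtracting the
normalized input coverage bin-by-bin, so values can be negative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome import Genome, ReadSet, SignalTrack

__all__ = ["CoverageParams", "bin_coverage", "normalize_subtract", "fold_change_track",
           "fragment_intervals"]


@dataclass(frozen=True)
class CoverageParams:
    bin_size: int = 50
    fragment_size: int = 150
    dedup: bool = True  # at most one read per (position, strand)
    midpoint: bool = False  # assign by fragment midpoint instead of overlap

    def __post_init__(self) -> None:
        if self.bin_size < 1 or self.fragment_size < 1:
            raise ValueError("bin_size and fragment_size must be >= 1")


def fragment_intervals(pos: np.ndarray, strand: np.ndarray, fragment_size: int,
                       chrom_length: int) -> tuple[np.ndarray, np.ndarray]:
    """Extended-fragment [start, end) per read, clipped to the chromosome."""
    plus = strand == "+"
    start = np.where(plus, pos, pos - fragment_size + 1)
    end = np.where(plus, pos + fragment_size, pos + 1)
    return np.clip(start, 0, chrom_length), np.clip(end, 0, chrom_length)


def bin_coverage(reads: ReadSet, genome: Genome, params: CoverageParams | None = None
                 ) -> SignalTrack:
    """Count extended fragments per fixed-width bin.

    Returns a track whose ``libsize`` is the number of reads counted
    (after deduplication when enabled).
    """
    params = params or CoverageParams()
    if params.dedup:
        reads = reads.dedup()
    bs = params.bin_size
    values = {c: np.zeros(genome.n_bins(c, bs)) for c in genome.chrom_names}
    for chrom, sub in reads.df.groupby("chrom", sort=False, observed=True):
        L = genome.length_of(str(chrom))
        pos = sub["pos"].to_numpy(dtype=np.int64)
        strand = sub["strand"].to_numpy()
        fs, fe = fragment_intervals(pos, strand, params.fragment_size, L)
        keep = fe > fs
        fs, fe = fs[keep], fe[keep]
        nb = len(values[str(chrom)])
        if params.midpoint:
            mid = np.clip((fs + fe - 1) // 2, 0, L - 1)
            values[str(chrom)] += np.bincount(mid // bs, minlength=nb).astype(float)
            continue
        first = fs // bs
        last = (fe - 1) // bs  # inclusive
        # fragments span few bins; accumulate one diagonal at a time
        span = int((last - first).max()) + 1 if len(fs) else 0
        for k in range(span):
            idx = first + k
            sel = idx <= last
            values[str(chrom)] += np.bincount(idx[sel], minlength=nb).astype(float)
    return SignalTrack(bin_size=bs, values=values, libsize=int(reads.libsize))


def _check_grids(chip: SignalTrack, input_: SignalTrack) -> None:
    if not chip.same_grid(input_):
        raise ValueError("chip and input tracks are on different bin grids")


def normalize_subtract(chip: SignalTrack, input_: SignalTrack,
                       chip_lib: int | None = None, input_lib: int | None = None
                       ) -> SignalTrack:
    """Input-subtracted signal on the reads-per-million scale:
    ``(chip_bin/chip_lib - input_bin/input_lib) * 1e6``."""
    _check_grids(chip, input_)
    chip_lib = chip_lib if chip_lib is not None else chip.libsize
    input_lib = input_lib if input_lib is not None else input_.libsize
    if not chip_lib or not input_lib or chip_lib < 1 or input_lib < 1:
        raise ValueError("library sizes must be >= 1")
    values = {
        c: (chip.values[c] / chip_lib - input_.values[c] / input_lib) * 1e6
        for c in chip.values
    }
    return SignalTrack(bin_size=chip.bin_size, values=values)


def fold_change_track(chip: SignalTrack, input_: SignalTrack,
                      chip_lib: int | None = None, input_lib: int | None = None,
                      pseudocount: float = 0.5) -> SignalTrack:
    """log2 ratio of RPM coverage, ``log2((chip_rpm + p) / (input_rpm + p))``.

    The pseudocount (RPM units, default 0.5) keeps sequencing ratios
    finite at empty bins.
    """
    _check_grids(chip, input_)
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    chip_lib = chip_lib if chip_lib is not None else chip.libsize
    input_lib = input_lib if input_lib is not None else input_.libsize
    if not chip_lib or not input_lib or chip_lib < 1 or input_lib < 1:
        raise ValueError("library sizes must be >= 1")
    values = {
        c: np.log2((chip.values[c] / chip_lib * 1e6 + pseudocount)
                   / (input_.values[c] / input_lib * 1e6 + pseudocount))
        for c in chip.values
    }
    return SignalTrack(bin_size=chip.bin_size, values=values)
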