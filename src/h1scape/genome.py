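"""Core coordinate-frame types shared by every pipeline stage.

All coordinates are 0-based, half-open. Genes are stored in genomic
orientation as (chrom, start, end, strand); the transcription start site
is ``start`` for ``+`` genes and ``end - 1`` for ``-`` genes, and the
termination site is the opposite anchor. Signal lives on fixed-width bin
grids (one vector per chromosome, length ``ceil(L / bin_size)``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "Genome",
    "Gene",
    "GeneSet",
    "SignalTrack",
    "RegionSet",
    "ReadSet",
]


@dataclass(frozen=True)
class Genome:
    """Ordered chromosome names and lengths (bp)."""

    chrom_names: tuple[str, ...]
    chrom_lengths: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.chrom_names) != len(self.chrom_lengths):
            raise ValueError("chrom_names and chrom_lengths differ in length")
        if len(set(self.chrom_names)) != len(self.chrom_names):
            raise ValueError("duplicate chromosome names")
        if any(length < 1 for length in self.chrom_lengths):
            raise ValueError("chromosome lengths must be >= 1")

    @classmethod
    def from_dict(cls, lengths: dict[str, int]) -> "Genome":
        return cls(tuple(lengths), tuple(lengths.values()))

    @property
    def lengths(self) -> dict[str, int]:
        return dict(zip(self.chrom_names, self.chrom_lengths))

    @property
    def total_bp(self) -> int:
        return int(sum(self.chrom_lengths))

    def length_of(self, chrom: str) -> int:
        try:
            return self.chrom_lengths[self.chrom_names.index(chrom)]
        except ValueError:
            raise KeyError(f"unknown chromosome {chrom!r}") from None

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.chrom_names

    def n_bins(self, chrom: str, bin_size: int) -> int:
        return math.ceil(self.length_of(chrom) / bin_size)


@dataclass(frozen=True)
class Gene:
    """One gene in genomic orientation; TSS/TTS are strand-aware anchors."""

    id: str
    chrom: str
    start: int
    end: int
    strand: str
    expression: float | None = None
    exons: tuple[tuple[int, int], ...] | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("start must be < end")
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tts(self) -> int:
        return self.end - 1 if self.strand == "+" else self.start


@dataclass
class SignalTrack:
    """Per-chromosome fixed-width binned signal.

    ``values[chrom]`` has length ``ceil(chrom_length / bin_size)``; the
    trailing bin may cover a partial window at the chromosome end.
    """

    bin_size: int
    values: dict[str, np.ndarray]
    libsize: int | None = None

    def __post_init__(self) -> None:
        if self.bin_size < 1:
            raise ValueError("bin_size must be >= 1")
        self.values = {c: np.asarray(v, dtype=float) for c, v in self.values.items()}

    def validate(self, genome: Genome) -> None:
        for chrom, vec in self.values.items():
            expect = genome.n_bins(chrom, self.bin_size)
            if len(vec) != expect:
                raise ValueError(
                    f"{chrom}: {len(vec)} bins, expected {expect} "
                    f"for length {genome.length_of(chrom)} at bin {self.bin_size}"
                )
            if not np.all(np.isfinite(vec)):
                raise ValueError(f"{chrom}: non-finite signal values")

    @property
    def chroms(self) -> list[str]:
        return list(self.values)

    def same_grid(self, other: "SignalTrack") -> bool:
        return (
            self.bin_size == other.bin_size
            and set(self.values) == set(other.values)
            and all(len(self.values[c]) == len(other.values[c]) for c in self.values)
        )

    @classmethod
    def zeros(cls, genome: Genome, bin_size: int, libsize: int | None = None) -> "SignalTrack":
        vals = {c: np.zeros(genome.n_bins(c, bin_size)) for c in genome.chrom_names}
        return cls(bin_size=bin_size, values=vals, libsize=libsize)

    def mean_over(self, chrom: str, start: float, end: float) -> float:
        """Exact mean of the per-bp step signal over genomic [start, end).

        The per-bp signal at base x is the value of the bin containing x;
        fractional bounds are supported (used by metagene rescaling).
        """
        if end <= start:
            raise ValueError("empty interval")
        return (self._integral(chrom, end) - self._integral(chrom, start)) / (end - start)

    def _integral(self, chrom: str, x: float) -> float:
        v = self.values[chrom]
        prefix = self._prefix(chrom)
        i = int(x // self.bin_size)
        i = min(i, len(v))  # x may equal the chromosome end
        frac = x - i * self.bin_size
        return prefix[i] + (frac * v[i] if i < len(v) and frac > 0 else 0.0)

    def _prefix(self, chrom: str) -> np.ndarray:
        cache = getattr(self, "_prefix_cache", None)
        if cache is None:
            cache = {}
            object.__setattr__(self, "_prefix_cache", cache)
        if chrom not in cache:
            cache[chrom] = np.concatenate(
                [[0.0], np.cumsum(self.values[chrom] * float(self.bin_size))]
            )
        return cache[chrom]

    def invalidate_cache(self) -> None:
        if hasattr(self, "_prefix_cache"):
            object.__setattr__(self, "_prefix_cache", None)


@dataclass
class RegionSet:
    """Named genomic intervals, half-open, possibly overlapping.

    Backed by a DataFrame with columns chrom, start, end and optional
    name/score columns; input order is preserved.
    """

    df: pd.DataFrame

    REQUIRED = ("chrom", "start", "end")

    def __post_init__(self) -> None:
        for col in self.REQUIRED:
            if col not in self.df.columns:
                raise ValueError(f"RegionSet missing column {col!r}")
        self.df = self.df.reset_index(drop=True)
        bad = self.df["start"] >= self.df["end"]
        if bad.any():
            raise ValueError(f"{int(bad.sum())} regions with start >= end")

    @classmethod
    def from_records(cls, records, names: list[str] | None = None) -> "RegionSet":
        df = pd.DataFrame(records, columns=["chrom", "start", "end"])
        if names is not None:
            df["name"] = names
        return cls(df)

    @classmethod
    def empty(cls) -> "RegionSet":
        return cls(pd.DataFrame({"chrom": pd.Series(dtype=str),
                                 "start": pd.Series(dtype=int),
                                 "end": pd.Series(dtype=int)}))

    def __len__(self) -> int:
        return len(self.df)

    def __iter__(self):
        return iter(self.df[["chrom", "start", "end"]].itertuples(index=False, name=None))

    @property
    def widths(self) -> np.ndarray:
        return (self.df["end"] - self.df["start"]).to_numpy()

    def validate(self, genome: Genome) -> None:
        for chrom, sub in self.df.groupby("chrom", sort=False, observed=True):
            if chrom not in genome:
                raise ValueError(f"region on unknown chromosome {chrom!r}")
            L = genome.length_of(str(chrom))
            if (sub["start"] < 0).any() or (sub["end"] > L).any():
                raise ValueError(f"region out of bounds on {chrom}")

    def total_bp_in(self, genome: Genome) -> int:
        """Union length (bp) of the regions, merged per chromosome."""
        total = 0
        for _, sub in self.df.groupby("chrom", sort=False, observed=True):
            ivs = sub[["start", "end"]].sort_values("start").to_numpy()
            cur_s, cur_e = None, None
            for s, e in ivs:
                if cur_e is None or s > cur_e:
                    if cur_e is not None:
                        total += cur_e - cur_s
                    cur_s, cur_e = s, e
                else:
                    cur_e = max(cur_e, e)
            if cur_e is not None:
                total += cur_e - cur_s
        return int(total)


@dataclass
class ReadSet:
    """Aligned single-end reads reduced to (chrom, 5' position, strand)."""

    df: pd.DataFrame  # columns chrom, pos, strand

    def __post_init__(self) -> None:
        for col in ("chrom", "pos", "strand"):
            if col not in self.df.columns:
                raise ValueError(f"ReadSet missing column {col!r}")
        self.df = self.df.reset_index(drop=True)
        # categorical chrom/strand keep dedup and grouping fast at depth 1e6+
        for col in ("chrom", "strand"):
            if self.df[col].dtype == object:
                self.df[col] = self.df[col].astype("category")

    @property
    def libsize(self) -> int:
        return len(self.df)

    def validate(self, genome: Genome) -> None:
        for chrom, sub in self.df.groupby("chrom", sort=False, observed=True):
            if chrom not in genome:
                raise ValueError(f"read on unknown chromosome {chrom!r}")
            L = genome.length_of(str(chrom))
            if (sub["pos"] < 0).any() or (sub["pos"] >= L).any():
                raise ValueError(f"read position out of bounds on {chrom}")
        if not self.df["strand"].isin(["+", "-"]).all():
            raise ValueError("strand must be '+' or '-'")

    def dedup(self) -> "ReadSet":
        """At most one read per (chrom, position, strand)."""
        return ReadSet(self.df.drop_duplicates(["chrom", "pos", "strand"]))


@dataclass
class GeneSet:
    """Genes with strand-aware TSS/TTS anchors and optional expression.

    DataFrame columns: id, chrom, start, end, strand, expression (NaN =
    missing), optionally exons (list of (start, end) tuples or None).
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        for col in ("id", "chrom", "start", "end", "strand"):
            if col not in self.df.columns:
                raise ValueError(f"GeneSet missing column {col!r}")
        if self.df["id"].duplicated().any():
            dups = self.df.loc[self.df["id"].duplicated(), "id"].tolist()
            raise ValueError(f"duplicate gene ids: {dups[:5]}")
        if "expression" not in self.df.columns:
            self.df = self.df.assign(expression=np.nan)
        self.df = self.df.reset_index(drop=True)
        bad = self.df["start"] >= self.df["end"]
        if bad.any():
            raise ValueError(f"{int(bad.sum())} genes with start >= end")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def tss(self) -> np.ndarray:
        """Transcription start site, strand-aware (the first transcribed base)."""
        plus = self.df["strand"].to_numpy() == "+"
        return np.where(plus, self.df["start"].to_numpy(), self.df["end"].to_numpy() - 1)

    @property
    def tts(self) -> np.ndarray:
        """Transcription termination site (the last transcribed base)."""
        plus = self.df["strand"].to_numpy() == "+"
        return np.where(plus, self.df["end"].to_numpy() - 1, self.df["start"].to_numpy())

    @property
    def lengths(self) -> np.ndarray:
        return (self.df["end"] - self.df["start"]).to_numpy()

    def expressed(self) -> "GeneSet":
        return GeneSet(self.df[self.df["expression"].notna()].copy())

    def validate(self, genome: Genome) -> None:
        for chrom, sub in self.df.groupby("chrom", sort=False, observed=True):
            if chrom not in genome:
                raise ValueError(f"gene on unknown chromosome {chrom!r}")
            L = genome.length_of(str(chrom))
            if (sub["start"] < 0).any() or (sub["end"] > L).any():
                raise ValueError(f"gene out of bounds on {chrom}")
        if not self.df["strand"].isin(["+", "-"]).all():
            raise ValueError("strand must be '+' or '-'")
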