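"""Readers and writers for the plain-text genomics formats the pipeline uses.

Formats: two-column chrom.sizes TSV, BED3/BED6 (regions; reads as BED6
with the 5' position in the start column), bedGraph with one fixed-step
record per bin (signal, 6 decimal places), gene TSV
(id, chrom, start, end, strand) and expression TSV (id, log2 value).
BED input is already 0-based half-open, so no coordinate shifting occurs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .genome import GeneSet, Genome, ReadSet, RegionSet, SignalTrack

log = logging.getLogger(__name__)

BEDGRAPH_DECIMALS = 6


class ParseError(ValueError):
    """A malformed record, reported with its file and line number."""


@dataclass
class SkipReport:
    """Counts of records dropped while reading a file."""

    unknown_chrom: int = 0
    out_of_bounds: int = 0

    @property
    def total(self) -> int:
        return self.unknown_chrom + self.out_of_bounds


def read_chrom_sizes(path: str | Path) -> Genome:
    names: list[str] = []
    lengths: list[int] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 2:
            raise ParseError(f"{path}:{lineno}: expected 2 tab-separated columns")
        try:
            length = int(fields[1])
        except ValueError:
            raise ParseError(f"{path}:{lineno}: non-integer length {fields[1]!r}") from None
        names.append(fields[0])
        lengths.append(length)
    return Genome(tuple(names), tuple(lengths))


def write_chrom_sizes(genome: Genome, path: str | Path) -> None:
    lines = [f"{c}\t{l}" for c, l in zip(genome.chrom_names, genome.chrom_lengths)]
    Path(path).write_text("\n".join(lines) + "\n")


def _parse_bed_line(path, lineno: int, line: str):
    fields = line.rstrip("\n").split("\t")
    if len(fields) < 3:
        raise ParseError(f"{path}:{lineno}: BED needs >= 3 columns, got {len(fields)}")
    try:
        start, end = int(fields[1]), int(fields[2])
    except ValueError:
        raise ParseError(f"{path}:{lineno}: non-integer coordinates") from None
    return fields, start, end


def read_bed(path: str | Path, genome: Genome) -> tuple[RegionSet, SkipReport]:
    """Read BED3+ into a RegionSet; unknown-chromosome and out-of-bounds
    records are skipped and counted, order otherwise preserved."""
    rows: list[tuple] = []
    names: list[str] = []
    have_names = False
    report = SkipReport()
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        fields, start, end = _parse_bed_line(path, lineno, line)
        chrom = fields[0]
        if chrom not in genome:
            report.unknown_chrom += 1
            continue
        if end <= start:
            raise ParseError(f"{path}:{lineno}: end <= start ({start}, {end})")
        if start < 0 or end > genome.length_of(chrom):
            report.out_of_bounds += 1
            log.warning("%s:%d: record out of bounds on %s, skipped", path, lineno, chrom)
            continue
        rows.append((chrom, start, end))
        names.append(fields[3] if len(fields) > 3 else "")
        have_names = have_names or len(fields) > 3
    regions = RegionSet.from_records(rows, names=names if have_names else None) \
        if rows else RegionSet.empty()
    return regions, report


def write_bed(regions: RegionSet, path: str | Path) -> None:
    cols = ["chrom", "start", "end"]
    extra = [c for c in ("name", "score", "strand") if c in regions.df.columns]
    regions.df[cols + extra].to_csv(path, sep="\t", header=False, index=False)


def read_reads_bed(path: str | Path, genome: Genome) -> tuple[ReadSet, SkipReport]:
    """Read BED6 reads: the start column is the 5' position, column 6 the strand."""
    rows = []
    report = SkipReport()
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith(("#", "track")):
            continue
        fields, start, _end = _parse_bed_line(path, lineno, line)
        if len(fields) < 6:
            raise ParseError(f"{path}:{lineno}: reads need BED6 (strand in column 6)")
        chrom, strand = fields[0], fields[5]
        if strand not in "+-":
            raise ParseError(f"{path}:{lineno}: bad strand {strand!r}")
        if chrom not in genome:
            report.unknown_chrom += 1
            continue
        if start < 0 or start >= genome.length_of(chrom):
            report.out_of_bounds += 1
            continue
        rows.append((chrom, start, strand))
    df = pd.DataFrame(rows, columns=["chrom", "pos", "strand"]) if rows else \
        pd.DataFrame({"chrom": pd.Series(dtype=str), "pos": pd.Series(dtype=int),
                      "strand": pd.Series(dtype=str)})
    return ReadSet(df), report


def write_reads_bed(reads: ReadSet, path: str | Path, read_name: str = "r") -> None:
    df = reads.df
    out = pd.DataFrame({
        "chrom": df["chrom"],
        "start": df["pos"],
        "end": df["pos"] + 1,
        "name": [f"{read_name}{i}" for i in range(len(df))],
        "score": 0,
        "strand": df["strand"],
    })
    out.to_csv(path, sep="\t", header=False, index=False)


def write_bedgraph(track: SignalTrack, path: str | Path) -> None:
    """One record per bin, fixed step of ``bin_size``, values at 6 decimals.

    Zero bins are written explicitly so the file round-trips bit-exactly
    at the printed precision."""
    step = track.bin_size
    with open(path, "w") as fh:
        for chrom, vec in track.values.items():
            starts = np.arange(len(vec), dtype=np.int64) * step
            ends = starts + step
            for s, e, v in zip(starts, ends, vec):
                fh.write(f"{chrom}\t{s}\t{e}\t{v:.{BEDGRAPH_DECIMALS}f}\n")


def read_bedgraph(path: str | Path, genome: Genome, bin_size: int) -> SignalTrack:
    """Read a fixed-step bedGraph produced by :func:`write_bedgraph`.

    Records must align to the bin grid; bins absent from the file are 0."""
    values = {c: np.zeros(genome.n_bins(c, bin_size)) for c in genome.chrom_names}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith(("#", "track")):
            continue
        fields = line.split("\t")
        if len(fields) < 4:
            raise ParseError(f"{path}:{lineno}: bedGraph needs 4 columns")
        chrom, start, end, value = fields[0], int(fields[1]), int(fields[2]), float(fields[3])
        if chrom not in values:
            continue
        if start % bin_size != 0:
            raise ParseError(f"{path}:{lineno}: record not on the {bin_size}-bp grid")
        first = start // bin_size
        last = math.ceil(end / bin_size)
        values[chrom][first:last] = value
    return SignalTrack(bin_size=bin_size, values=values)


def load_genes(path: str | Path, expression_path: str | Path | None = None
               ) -> tuple[GeneSet, int]:
    """Join a gene annotation TSV with an expression TSV on gene id.

    Returns the GeneSet and the number of expression ids that matched no
    gene. Duplicate annotation ids and non-numeric expression are errors.
    """
    genes = pd.read_csv(path, sep="\t", dtype={"id": str, "chrom": str, "strand": str})
    required = {"id", "chrom", "start", "end", "strand"}
    missing = required - set(genes.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    if genes["id"].duplicated().any():
        dup = genes.loc[genes["id"].duplicated(), "id"].iloc[0]
        raise ParseError(f"{path}: duplicate gene id {dup!r}")

    unmatched = 0
    if expression_path is not None:
        expr = pd.read_csv(expression_path, sep="\t", dtype={"id": str})
        if "expression" not in expr.columns:
            raise ParseError(f"{expression_path}: missing 'expression' column")
        vals = pd.to_numeric(expr["expression"], errors="coerce")
        bad = vals.isna() & expr["expression"].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # header + 1-based
        if bad.any():
            raise ParseError(f"{expression_path}: non-numeric expression at row {row}")
        expr = expr.assign(expression=vals)
        unmatched = int((~expr["id"].isin(genes["id"])).sum())
        genes = genes.drop(columns=[c for c in ("expression",) if c in genes.columns])
        genes = genes.merge(expr[["id", "expression"]], on="id", how="left")
    elif "expression" not in genes.columns:
        genes = genes.assign(expression=np.nan)
    return GeneSet(genes), unmatched


def write_genes(genes: GeneSet, path: str | Path, expression_path: str | Path | None = None
                ) -> None:
    genes.df[["id", "chrom", "start", "end", "strand"]].to_csv(path, sep="\t", index=False)
    if expression_path is not None:
        expressed = genes.df[genes.df["expression"].notna()]
        expressed[["id", "expression"]].to_csv(expression_path, sep="\t", index=False,
                                               float_format="%.6f")
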