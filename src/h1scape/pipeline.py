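"""End-to-end driver: coverage -> subtraction -> profiles -> islands ->
annotation -> domain statistics, from a single YAML config.

Every stage writes plain-text tables under the output directory; a
machine-readable ``summary.json`` collects the headline statistics
(per-variant GC correlation, LAD enrichment direction/p, island counts
by feature class, decile overlap counts) and ``manifest.json`` records
which stages completed. All randomness is seeded from the config, so a
rerun with the same config is byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as h1io
from .domains import (chromosome_occupancy, cluster_occupancy, decile_overlap_analysis,
                      distal_promoter_score, gc_correlation, gene_richness,
                      region_enrichment_test)
from .genome import SignalTrack
from .islands import (IslandParams, annotate_nearest_gene, call_islands,
                      classify_regions, islands_to_regionset, target_genes)
from .profiles import (MetageneSpec, ProfileSpec, anchored_profile,
                       column_mean_profile, expression_deciles, loess_profile,
                       metagene_profile)
from .signal import CoverageParams, bin_coverage, normalize_subtract

log = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    chrom_sizes: str
    genes: str
    expression: str
    lads: str
    gc: str
    variants: dict[str, dict[str, str]]  # name -> {chip, input}
    outdir: str
    seed: int = 0
    n_null: int = 1000
    alpha: float = 0.05
    n_groups: int = 10
    top_fraction: float = 0.10
    loess_span: float = 0.1
    coverage: CoverageParams = field(default_factory=CoverageParams)
    islands: IslandParams = field(default_factory=IslandParams)
    profile: ProfileSpec = field(default_factory=ProfileSpec)
    metagene: MetageneSpec = field(default_factory=MetageneSpec)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        kwargs = dict(raw)
        for key, typ in (("coverage", CoverageParams), ("islands", IslandParams),
                         ("profile", ProfileSpec), ("metagene", MetageneSpec)):
            if key in kwargs and isinstance(kwargs[key], dict):
                kwargs[key] = typ(**kwargs[key])
        if "seed" not in kwargs:
            raise ValueError("config must set an explicit seed")
        return cls(**kwargs)

    def validate(self) -> None:
        paths = [self.chrom_sizes, self.genes, self.expression, self.lads, self.gc]
        for v in self.variants.values():
            paths += [v["chip"], v["input"]]
        missing = [p for p in paths if not Path(p).exists()]
        if missing:
            raise FileNotFoundError(f"missing inputs: {missing}")

    def echo(self) -> dict:
        d = {k: v for k, v in self.__dict__.items()
             if k not in ("coverage", "islands", "profile", "metagene")}
        for key in ("coverage", "islands", "profile", "metagene"):
            d[key] = dict(getattr(self, key).__dict__)
        return d


def _write_tsv(df: pd.DataFrame, path: Path, **kw) -> None:
    df.to_csv(path, sep="\t", float_format="%.6g", **kw)


def run_all(config: RunConfig) -> dict:
    """Run the whole pipeline; returns the summary dict (also written
    as summary.json). Partial outputs survive a stage failure, with the
    manifest marking what completed."""
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config_echo.yaml").write_text(yaml.safe_dump(config.echo(), sort_keys=True))
    manifest: dict[str, str] = {}
    summary: dict = {"variants": {}}

    def stage(name):
        def deco(fn):
            try:
                result = fn()
                manifest[name] = "ok"
                return result
            except Exception as exc:  # noqa: BLE001 - report stage and cause
                manifest[name] = f"failed: {exc}"
                (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
                raise StageError(name, exc) from exc
        return deco

    @stage("load_inputs")
    def inputs():
        genome = h1io.read_chrom_sizes(config.chrom_sizes)
        genes, _ = h1io.load_genes(config.genes, config.expression)
        genes.validate(genome)
        lads, _ = h1io.read_bed(config.lads, genome)
        gc = h1io.read_bedgraph(config.gc, genome, bin_size=config.coverage.bin_size)
        return genome, genes, lads, gc

    genome, genes, lads, gc = inputs

    delta_tracks: dict[str, SignalTrack] = {}
    reads_by_variant: dict[str, tuple] = {}

    @stage("coverage_subtract")
    def _coverage():
        for name, files in config.variants.items():
            chip, _ = h1io.read_reads_bed(files["chip"], genome)
            inp, _ = h1io.read_reads_bed(files["input"], genome)
            reads_by_variant[name] = (chip, inp)
            chip_cov = bin_coverage(chip, genome, config.coverage)
            inp_cov = bin_coverage(inp, genome, config.coverage)
            delta = normalize_subtract(chip_cov, inp_cov)
            delta_tracks[name] = delta
            h1io.write_bedgraph(delta, out / f"{name}.delta.bedgraph")
    _coverage

    @stage("profiles")
    def _profiles():
        labels, n_missing = expression_deciles(genes, config.n_groups)
        for name, delta in delta_tracks.items():
            mat = anchored_profile(delta, genes, config.profile)
            mean, n = column_mean_profile(mat)
            rows = {"offset": config.profile.offsets, "mean": mean, "n": n,
                    "loess": loess_profile(mean, config.loess_span)}
            for g in range(1, config.n_groups + 1):
                ids = set(labels[labels == f"EG{g}"].index)
                sel = [i for i, rid in enumerate(mat.row_ids) if rid in ids]
                sub_mean = np.nanmean(mat.values[sel], axis=0)
                rows[f"EG{g}"] = sub_mean
            _write_tsv(pd.DataFrame(rows), out / f"{name}.tss_profile.tsv", index=False)
            mg = metagene_profile(delta, genes, config.metagene)
            _write_tsv(pd.DataFrame({"bin": np.arange(len(mg)), "mean": mg}),
                       out / f"{name}.metagene.tsv", index=False)
        return n_missing
    _profiles

    @stage("islands_annotation")
    def _islands():
        for name, (chip, inp) in reads_by_variant.items():
            var_summary = summary["variants"].setdefault(name, {})
            for direction in ("enriched", "depleted"):
                isl = call_islands(chip, inp, genome, config.islands, direction)
                regions = islands_to_regionset(isl)
                h1io.write_bed(regions, out / f"{name}.{direction}.islands.bed")
                if len(regions):
                    ann = annotate_nearest_gene(regions, genes)
                    ann["feature"] = [f.value for f in classify_regions(regions, genes)]
                    _write_tsv(ann, out / f"{name}.{direction}.annotation.tsv",
                               index=False)
                    targets = target_genes(regions, genes)
                    _write_tsv(targets.to_frame(),
                               out / f"{name}.{direction}.targets.tsv")
                    feature_counts = ann["feature"].value_counts().to_dict()
                else:
                    feature_counts = {}
                var_summary[f"islands_{direction}"] = {
                    "n": len(regions),
                    "by_feature": feature_counts,
                }
    _islands

    @stage("domain_stats")
    def _domains():
        grc = gene_richness(genes, genome)
        _write_tsv(grc.to_frame(), out / "grc.tsv")
        occ = chromosome_occupancy(delta_tracks)
        _write_tsv(occ, out / "chrom_occupancy.tsv")
        if len(delta_tracks) >= 2:
            _, order = cluster_occupancy(occ, axis="variants")
            (out / "variant_cluster_order.txt").write_text("\n".join(order) + "\n")
            summary["variant_cluster_order"] = order
        scores: dict[str, pd.Series] = {}
        for name, delta in delta_tracks.items():
            var_summary = summary["variants"].setdefault(name, {})
            if len(lads):
                res = region_enrichment_test(delta, lads, genome,
                                             n_null=config.n_null, alpha=config.alpha,
                                             seed=config.seed, region_class="LADs")
                var_summary["lad_test"] = {"D": res.D, "p_value": res.p_value,
                                           "direction": res.direction}
            else:
                var_summary["lad_test"] = {"direction": "no regions"}
            r, n_w, scatter = gc_correlation(delta, gc)
            var_summary["gc_correlation"] = {"r": r, "n_windows": n_w}
            _write_tsv(scatter, out / f"{name}.gc_scatter.tsv", index=False)
            scores[name] = distal_promoter_score(delta, genes)
            _write_tsv(scores[name].to_frame(), out / f"{name}.distal_score.tsv")
        names = list(scores)
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                a, b = names[i], names[j]
                res = decile_overlap_analysis(scores[a], scores[b], genes,
                                              config.top_fraction)
                counts = {k: v["count"] for k, v in res["sets"].items()}
                ks = {k: {kk: v[kk] for kk in ("D", "p_value", "median_shift")}
                      for k, v in res["sets"].items()}
                summary.setdefault("decile_overlap", {})[f"{a}__vs__{b}"] = {
                    "counts": counts, "ks_vs_universe": ks, "k": res["k"],
                    "n_universe": res["n_universe"]}
        summary["grc"] = {c: float(v) for c, v in grc.items()}
    _domains

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary
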