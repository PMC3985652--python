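"""Domain-scale statistics: GRC, occupancy clustering, enrichment null,
GC correlation, distal-promoter scores and decile overlap."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.cluster.hierarchy import fcluster

from h1scape.domains import (chromosome_occupancy, cluster_occupancy,
                             decile_overlap_analysis, distal_promoter_score,
                             gc_correlation, gene_richness,
                             region_enrichment_test, sample_null_windows)
from h1scape.genome import GeneSet, Genome, RegionSet, SignalTrack

from conftest import make_genes, random_track


class TestGeneRichness:
    def test_forced_ratio(self):
        # chrom with 20% of genes and 10% of bp -> GRC 2.0
        genome = Genome(("c1", "c2"), (100_000, 900_000))
        rows = [(f"a{i}", "c1", i * 100, i * 100 + 50, "+", 0.0) for i in range(2)] + \
               [(f"b{i}", "c2", i * 100, i * 100 + 50, "+", 0.0) for i in range(8)]
        grc = gene_richness(make_genes(rows), genome)
        assert grc["c1"] == pytest.approx(2.0)

    def test_proportional_placement_gives_unity(self):
        genome = Genome(("c1", "c2"), (100_000, 300_000))
        rows = [(f"a{i}", "c1", i * 100, i * 100 + 50, "+", 0.0) for i in range(5)] + \
               [(f"b{i}", "c2", i * 100, i * 100 + 50, "+", 0.0) for i in range(15)]
        grc = gene_richness(make_genes(rows), genome)
        np.testing.assert_allclose(grc.to_numpy(), 1.0)

    def test_geneless_chromosome_gets_zero(self):
        genome = Genome(("c1", "c2"), (1000, 1000))
        grc = gene_richness(make_genes([("g", "c1", 0, 10, "+", 0.0)]), genome)
        assert grc["c2"] == 0.0

    def test_conservation_identity_on_random_placements(self, rng):
        # sum_c GRC_c * bpfrac_c = 1 exactly, for any placement
        for _ in range(100):
            n_chrom = int(rng.integers(2, 8))
            lengths = rng.integers(10_000, 500_000, size=n_chrom)
            genome = Genome(tuple(f"c{i}" for i in range(n_chrom)), tuple(lengths))
            n_genes = int(rng.integers(1, 200))
            chroms = rng.choice(genome.chrom_names, size=n_genes)
            rows = [(f"g{i}", chroms[i], 0, 10, "+", 0.0) for i in range(n_genes)]
            grc = gene_richness(make_genes(rows), genome)
            bpfrac = np.array(lengths) / lengths.sum()
            assert abs(float((grc.to_numpy() * bpfrac).sum()) - 1) < 1e-12


class TestChromosomeOccupancy:
    def test_constant_track(self, small_genome):
        t = SignalTrack(50, {c: np.full(small_genome.n_bins(c, 50), 3.0)
                             for c in small_genome.chrom_names})
        occ = chromosome_occupancy({"v": t})
        np.testing.assert_allclose(occ.loc["v"], 3.0)

    def test_signed_means(self, small_genome):
        t = SignalTrack(50, {"chrA": np.ones(200), "chrB": -np.ones(160)})
        occ = chromosome_occupancy({"v": t})
        assert occ.loc["v", "chrA"] == 1.0 and occ.loc["v", "chrB"] == -1.0

    def test_random_tracks_match_oracle_means(self, small_genome, rng):
        tracks = {f"v{i}": random_track(small_genome, 50, rng) for i in range(3)}
        occ = chromosome_occupancy(tracks)
        for name, t in tracks.items():
            for c in small_genome.chrom_names:
                assert occ.loc[name, c] == pytest.approx(t.values[c].mean())

    def test_bin_mismatch_rejected(self, small_genome, rng):
        a = random_track(small_genome, 50, rng)
        b = random_track(small_genome, 100, rng)
        with pytest.raises(ValueError, match="grid"):
            chromosome_occupancy({"a": a, "b": b})


class TestClusterOccupancy:
    def test_identical_variants_merge_at_zero(self):
        occ = pd.DataFrame({"c1": [1.0, 1.0, 5.0], "c2": [2.0, 2.0, 1.0],
                            "c3": [0.5, 0.5, 9.0]}, index=["a", "b", "c"])
        Z, order = cluster_occupancy(occ)
        assert Z[0, 2] == pytest.approx(0.0)  # first merge at distance 0

    def test_anticorrelated_distance_two(self):
        x = np.array([1.0, 2.0, 4.0, 3.0])
        occ = pd.DataFrame([x, -x], index=["x", "negx"],
                           columns=[f"c{i}" for i in range(4)])
        Z, _ = cluster_occupancy(occ)
        assert Z[0, 2] == pytest.approx(2.0)

    def test_zero_variance_falls_back_with_warning(self):
        occ = pd.DataFrame([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]],
                           index=["flat", "x"], columns=["a", "b", "c"])
        with pytest.warns(UserWarning, match="zero-variance"):
            cluster_occupancy(occ)

    def test_two_model_classes_separate(self, rng):
        # two pairs of correlated rows must form the two top clusters
        base1, base2 = rng.normal(size=12), rng.normal(size=12)
        occ = pd.DataFrame([base1 + rng.normal(0, 0.1, 12) for _ in range(2)]
                           + [base2 + rng.normal(0, 0.1, 12) for _ in range(2)],
                           index=["a1", "a2", "b1", "b2"])
        Z, _ = cluster_occupancy(occ)
        labels = fcluster(Z, 2, criterion="maxclust")
        assert labels[0] == labels[1] and labels[2] == labels[3]
        assert labels[0] != labels[2]


class TestRegionEnrichment:
    def test_constant_signal_not_significant(self, small_genome):
        t = SignalTrack(50, {c: np.full(small_genome.n_bins(c, 50), 2.0)
                             for c in small_genome.chrom_names})
        regions = RegionSet.from_records([("chrA", 100, 600), ("chrB", 0, 500)])
        res = region_enrichment_test(t, regions, small_genome, n_null=100, seed=1)
        assert res.p_value >= 0.05 and res.direction == "n.s."

    def test_seed_determinism(self, small_genome, rng):
        t = random_track(small_genome, 50, rng)
        regions = RegionSet.from_records([("chrA", 100, 600), ("chrB", 0, 500)])
        r1 = region_enrichment_test(t, regions, small_genome, n_null=200, seed=9)
        r2 = region_enrichment_test(t, regions, small_genome, n_null=200, seed=9)
        assert r1.p_value == r2.p_value
        np.testing.assert_array_equal(r1.null, r2.null)

    def test_enriched_regions_detected_with_direction(self, small_genome, rng):
        t = random_track(small_genome, 50, rng)
        t.values["chrA"][2:12] += 10  # hot stretch [100, 600)
        regions = RegionSet.from_records([("chrA", 100, 600)] )
        res = region_enrichment_test(t, regions, small_genome, n_null=300, seed=3)
        assert res.direction == "enriched" and res.p_value < 0.05

    def test_width_multiset_resampled(self, small_genome, rng):
        regions = RegionSet.from_records([("chrA", 0, 100), ("chrA", 200, 800)])
        null = sample_null_windows(small_genome, regions.widths, 50,
                                   np.random.default_rng(0))
        assert set(null.widths) <= {100, 600}
        null.validate(small_genome)

    def test_region_wider_than_genome_errors(self, small_genome):
        with pytest.raises(ValueError, match="wider"):
            sample_null_windows(small_genome, np.array([50_000]), 10,
                                np.random.default_rng(0))

    def test_n_null_must_cover_regions(self, small_genome, rng):
        t = random_track(small_genome, 50, rng)
        regions = RegionSet.from_records([("chrA", 0, 100)] * 5)
        with pytest.raises(ValueError, match="n_null"):
            region_enrichment_test(t, regions, small_genome, n_null=3, seed=0)


class TestGCCorrelation:
    def test_affine_signal_of_gc_gives_unit_correlation(self, small_genome, rng):
        gc = random_track(small_genome, 50, rng)
        pos = SignalTrack(50, {c: 3 * v + 1 for c, v in gc.values.items()})
        neg = SignalTrack(50, {c: -v for c, v in gc.values.items()})
        assert gc_correlation(pos, gc)[0] == pytest.approx(1.0)
        assert gc_correlation(neg, gc)[0] == pytest.approx(-1.0)

    def test_zero_variance_names_series(self, small_genome, rng):
        gc = random_track(small_genome, 50, rng)
        flat = SignalTrack(50, {c: np.zeros_like(v) for c, v in gc.values.items()})
        with pytest.raises(ValueError, match="signal"):
            gc_correlation(flat, gc)
        with pytest.raises(ValueError, match="GC"):
            gc_correlation(gc, flat)

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(scale=st.floats(-5, 5).filter(lambda s: abs(s) > 1e-3),
           offset=st.floats(-10, 10))
    def test_affine_invariance_of_magnitude(self, scale, offset):
        rng = np.random.default_rng(0)
        genome = Genome(("c",), (100_000,))
        sig = random_track(genome, 50, rng)
        gc = random_track(genome, 50, rng)
        r0, _, _ = gc_correlation(sig, gc)
        scaled = SignalTrack(50, {"c": scale * sig.values["c"] + offset})
        r1, _, _ = gc_correlation(scaled, gc)
        assert abs(r1) == pytest.approx(abs(r0), abs=1e-9)
        assert np.sign(r1) == np.sign(r0) * np.sign(scale)

    def test_window_must_align(self, small_genome, rng):
        with pytest.raises(ValueError, match="multiple"):
            gc_correlation(random_track(small_genome, 50, rng),
                           random_track(small_genome, 50, rng), window=75)


class TestDistalPromoterScore:
    def test_uniform_track_identical_scores(self, small_genome):
        t = SignalTrack(50, {c: np.full(small_genome.n_bins(c, 50), 1.7)
                             for c in small_genome.chrom_names})
        genes = make_genes([("g1", "chrA", 5000, 7000, "+", 0.0),
                            ("g2", "chrB", 2000, 4000, "-", 0.0)])
        scores = distal_promoter_score(t, genes)
        np.testing.assert_allclose(scores.to_numpy(), 1.7)

    def test_minus_strand_window_on_opposite_side(self):
        genome = Genome(("c",), (20_000,))
        vals = np.zeros(400)
        vals[240:270] = 5.0  # genomic [12000, 13500)
        t = SignalTrack(50, {"c": vals})
        # minus gene with TSS at 9999: distal window = genomic [12000, 13200)
        minus = make_genes([("m", "c", 5000, 10_000, "-", 0.0)])
        plus = make_genes([("p", "c", 9999, 15_000, "+", 0.0)])
        assert distal_promoter_score(t, minus)["m"] == pytest.approx(5.0)
        assert distal_promoter_score(t, plus)["p"] == pytest.approx(0.0)

    def test_partial_window_at_chromosome_start(self):
        genome = Genome(("c",), (20_000,))
        t = SignalTrack(50, {"c": np.ones(400)})
        genes = make_genes([("g", "c", 2500, 5000, "+", 0.0)])  # window [-700, 500)
        s = distal_promoter_score(t, genes)
        assert s["g"] == pytest.approx(1.0)  # mean over the available 500 bp

    def test_thirty_gene_fixture_matches_oracle(self, small_genome, rng):
        t = random_track(small_genome, 50, rng)
        rows = []
        for i in range(30):
            chrom = small_genome.chrom_names[i % 2]
            start = int(rng.integers(3300, small_genome.length_of(chrom) - 4300))
            strand = "+" if i % 2 else "-"
            rows.append((f"g{i}", chrom, start, start + 1000, strand, 0.0))
        genes = make_genes(rows)
        scores = distal_promoter_score(t, genes)
        for i, (gid, chrom, start, end, strand, _) in enumerate(rows):
            tss = start if strand == "+" else end - 1
            vals = []
            for off in range(-3200, -2000):
                g = tss + off if strand == "+" else tss - off
                vals.append(t.values[chrom][g // 50])
            assert scores[gid] == pytest.approx(np.mean(vals), abs=1e-9)


class TestDecileOverlap:
    @staticmethod
    def _setup(n=100, seed=0):
        rng = np.random.default_rng(seed)
        genes = make_genes([(f"g{i:03d}", "chrA", i * 10, i * 10 + 5, "+",
                             float(rng.normal())) for i in range(n)])
        scores = pd.Series(rng.normal(size=n),
                           index=pd.Index([f"g{i:03d}" for i in range(n)], name="id"))
        return genes, scores

    def test_identical_scores_full_overlap(self):
        genes, s = self._setup()
        res = decile_overlap_analysis(s, s.copy(), genes, 0.10)
        assert res["sets"]["highA_highB"]["count"] == res["k"] == 10
        assert res["sets"]["highA_lowB"]["count"] == 0

    def test_negated_scores_anti_overlap(self):
        genes, s = self._setup()
        res = decile_overlap_analysis(s, -s, genes, 0.10)
        assert res["sets"]["highA_lowB"]["count"] == res["k"]
        assert res["sets"]["highA_highB"]["count"] == 0

    def test_set_sizes_ceil_of_fraction(self):
        genes, s = self._setup(n=101)
        res = decile_overlap_analysis(s, s.copy(), genes, 0.10)
        assert res["k"] == 11  # ceil(0.1 * 101)

    def test_low_expression_intersection_detected(self):
        # genes where A is high and B is low have depressed expression
        rng = np.random.default_rng(5)
        n = 200
        ids = [f"g{i:03d}" for i in range(n)]
        a = pd.Series(rng.normal(size=n), index=pd.Index(ids, name="id"))
        b = pd.Series(rng.normal(size=n), index=pd.Index(ids, name="id"))
        expr = rng.normal(size=n)
        high_a = a.nlargest(40).index
        low_b = b.nsmallest(40).index
        target = high_a.intersection(low_b)
        expr[[ids.index(t) for t in target]] -= 4.0
        genes = make_genes([(ids[i], "chrA", i * 10, i * 10 + 5, "+",
                             float(expr[i])) for i in range(n)])
        res = decile_overlap_analysis(a, b, genes, 0.20)
        entry = res["sets"]["highA_lowB"]
        assert entry["count"] >= 3
        assert entry["p_value"] < 0.05 and entry["median_shift"] < 0

    def test_fraction_bounds(self):
        genes, s = self._setup()
        with pytest.raises(ValueError, match="fraction"):
            decile_overlap_analysis(s, s, genes, 0.7)
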