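import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from chromatlas import linking, synthetic
from chromatlas.core.genes import GeneAnnotation
from chromatlas.core.intervals import GenomicInterval, IntervalSet
from chromatlas.core.matrix import SampleKey, SignalGrid, log2_with_zero_floor


class TestDeriveEnhancerRegions:
    def test_arithmetic_chain(self):
        calls = [IntervalSet.from_tuples([("chr1", 1000, 3000),
                                          ("chr1", 2500, 5000)])]
        tads = IntervalSet.from_tuples([("chr1", 0, 100_000)])
        regions, tad_ids, dropped = linking.derive_enhancer_regions(
            calls, [("chr1", 4000)], tads)
        # merge -> (1000,5000); subtract (1500,6500) -> (1000,1500);
        # pad about midpoint 1250 -> (250,2250)
        assert [(iv.start, iv.end) for iv in regions] == [(250, 2250)]
        assert tad_ids == [0]
        assert dropped == 0

    def test_large_region_unchanged(self):
        calls = [IntervalSet.from_tuples([("chr1", 50_000, 56_000)])]
        tads = IntervalSet.from_tuples([("chr1", 0, 100_000)])
        regions, _, _ = linking.derive_enhancer_regions(calls, [], tads)
        assert [(iv.start, iv.end) for iv in regions] == [(50_000, 56_000)]

    def test_outside_tads_dropped(self):
        calls = [IntervalSet.from_tuples([("chr1", 50_000, 56_000)])]
        tads = IntervalSet.from_tuples([("chr1", 70_000, 100_000)])
        regions, _, dropped = linking.derive_enhancer_regions(calls, [], tads)
        assert len(regions) == 0 and dropped == 1

    def test_invariant_sweep_min_width(self, rng):
        tads = IntervalSet.from_tuples([("chr1", 0, 1_000_000)])
        calls = [IntervalSet.from_tuples(
            [("chr1", int(x), int(x) + int(rng.integers(200, 6000)))
             for x in rng.integers(10_000, 900_000, 50)])]
        tss = [("chr1", int(p)) for p in rng.integers(10_000, 900_000, 30)]
        regions, _, _ = linking.derive_enhancer_regions(calls, tss, tads)
        assert all(len(iv) >= 2000 for iv in regions)

    def test_pre_padding_remnants_are_tss_free(self, rng):
        # the subtraction step removes every TSS window before padding
        from chromatlas.core.intervals import (merge_intervals,
                                               subtract_intervals,
                                               window_overlap)
        calls = IntervalSet.from_tuples(
            [("chr1", int(x), int(x) + int(rng.integers(200, 6000)))
             for x in rng.integers(10_000, 900_000, 50)])
        tss = [("chr1", int(p)) for p in rng.integers(10_000, 900_000, 30)]
        windows = IntervalSet.from_tuples(
            [("chr1", p - 2500, p + 2500) for _, p in tss])
        remnants = subtract_intervals(merge_intervals(calls), windows)
        if len(remnants):
            assert not window_overlap(remnants, tss, 2500).any()


class TestLinkByCorrelation:
    @staticmethod
    def toy_setup(n_samples=20):
        """One TAD, one gene, two enhancers: enhancer 0 shares the gene's
        monotone profile."""
        samples = [SampleKey("t", f"E{j}", "1") for j in range(n_samples)]
        profile = np.linspace(1, 5, n_samples)
        other = np.ones(n_samples) * 3
        other[::2] += 0.3
        enh_regions = IntervalSet.from_tuples(
            [("chr1", 10_000, 12_000), ("chr1", 20_000, 22_000)])
        enh = SignalGrid(enh_regions, samples, np.vstack([profile, other]),
                         "log2RPKM")
        genes = [GeneAnnotation("g1", "chr1", "+", [50_000])]
        expr_regions = IntervalSet.from_tuples([("chr1", 50_000, 50_001)],
                                               labels=["g1"])
        expr = SignalGrid(expr_regions, samples, profile[None, :] * 2,
                          "log2FPKM")
        tads = IntervalSet.from_tuples([("chr1", 0, 100_000)])
        return enh, expr, tads, genes

    def test_noiseless_planted_link(self):
        enh, expr, tads, genes = self.toy_setup()
        out = linking.link_by_correlation(enh, expr, tads, genes,
                                          alpha=1.0, min_scc=0.25)
        assert len(out) == 1
        assert out.iloc[0]["gene_id"] == "g1"
        assert out.iloc[0]["enhancer"] == 0
        assert out.iloc[0]["scc"] == pytest.approx(1.0)

    def test_gene_without_tad_enhancer_absent(self):
        enh, expr, tads, genes = self.toy_setup()
        far_tads = IntervalSet.from_tuples([("chr1", 40_000, 100_000)])
        out = linking.link_by_correlation(enh, expr, far_tads, genes,
                                          alpha=1.0)
        assert out.empty

    def test_non_coding_genes_excluded(self):
        enh, expr, tads, genes = self.toy_setup()
        genes[0].biotype = "lincRNA"
        out = linking.link_by_correlation(enh, expr, tads, genes, alpha=1.0)
        assert out.empty

    def test_misaligned_samples_error(self):
        enh, expr, tads, genes = self.toy_setup()
        expr2 = SignalGrid(expr.regions, list(reversed(expr.samples)),
                           expr.values, expr.units)
        with pytest.raises(ValueError):
            linking.link_by_correlation(enh, expr2, tads, genes)

    def test_sample_permutation_invariant(self, small_atlas):
        genes, tads, _ = small_atlas
        h3k, _, expr, _ = synthetic.gen_signal_grid(
            genes, tads, n_enhancers=40, n_links=15, seed=3, n_reps=1)
        lexpr = log2_with_zero_floor(expr)
        out1 = linking.link_by_correlation(h3k, lexpr, tads, genes)
        rng = np.random.default_rng(0)
        perm = list(rng.permutation(h3k.n_samples))
        out2 = linking.link_by_correlation(
            h3k.subset_samples(perm), lexpr.subset_samples(perm), tads, genes)
        pd.testing.assert_frame_equal(
            out1.sort_values(["gene_id"]).reset_index(drop=True),
            out2.sort_values(["gene_id"]).reset_index(drop=True))

    def test_recovery_precision_recall(self):
        stages = ["E10.5", "E11.5", "E12.5", "E13.5", "E14.5", "E15.5",
                  "E16.5", "P0", "P1", "P2", "P3"]  # 6 tissues x 11 = 66
        genes, tads = synthetic.gen_annotation_and_tads(
            n_chrom=2, chrom_len=10_000_000, n_genes=400,
            n_tads_per_chrom=15, seed=2)
        h3k, _, expr, truth = synthetic.gen_signal_grid(
            genes, tads, n_enhancers=600, n_links=300, link_strength=0.9,
            stages=stages, seed=2)

        def rep_cols(grid, rep):
            return [j for j, k in enumerate(grid.samples) if k.replicate == rep]

        maps = []
        for rep in ("1", "2"):
            enh = h3k.subset_samples(rep_cols(h3k, rep))
            expr_r = log2_with_zero_floor(expr.subset_samples(rep_cols(expr, rep)))
            maps.append(linking.link_by_correlation(enh, expr_r, tads, genes))
        final = linking.intersect_replicate_maps(*maps)
        true_set = {(c, s, e, g) for c, s, e, g, _ in truth.true_links}
        pred = {(r.enh_chrom, r.enh_start, r.enh_end, r.gene_id)
                for r in final.itertuples(index=False)}
        tp = len(pred & true_set)
        precision = tp / len(pred)
        recall = tp / len(true_set)
        assert precision >= 0.9
        assert recall >= 0.85
        # intersection at least as precise as either single-replicate map
        for m in maps:
            mp = {(r.enh_chrom, r.enh_start, r.enh_end, r.gene_id)
                  for r in m.itertuples(index=False)}
            assert precision >= len(mp & true_set) / len(mp) - 1e-9

    def test_empirical_p_uniform_for_unlinked(self):
        # a deep gene pool keeps the empirical null's discreteness below the
        # KS resolution
        genes, tads = synthetic.gen_annotation_and_tads(
            n_chrom=2, chrom_len=10_000_000, n_genes=500,
            n_tads_per_chrom=12, seed=5)
        h3k, _, expr, _ = synthetic.gen_signal_grid(
            genes, tads, n_enhancers=60, n_links=0, seed=5, n_reps=1)
        lexpr = log2_with_zero_floor(expr)
        from chromatlas.core.stats import pairwise_pearson, rank_transform
        enh_ranks = rank_transform(h3k.values)
        gene_ranks = rank_transform(lexpr.values)
        scc = pairwise_pearson(enh_ranks, gene_ranks)
        gene_chrom = np.array([iv.chrom for iv in lexpr.regions.intervals])
        enh_chrom = np.array([iv.chrom for iv in h3k.regions.intervals])
        rng = np.random.default_rng(0)
        pvals = []
        for _ in range(1000):
            e = int(rng.integers(0, len(enh_chrom)))
            gcols = np.flatnonzero(gene_chrom == enh_chrom[e])
            g = int(gcols[rng.integers(0, len(gcols))])
            null = scc[e, gcols]
            pvals.append(float(np.mean(null >= scc[e, g])))
        ks = sps.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01


class TestIntersectReplicateMaps:
    @staticmethod
    def map_of(rows):
        return pd.DataFrame(rows, columns=["enh_chrom", "enh_start",
                                           "enh_end", "gene_id", "scc"])

    def test_identical_maps(self):
        m = self.map_of([("chr1", 0, 2000, "g1", 0.9)])
        out = linking.intersect_replicate_maps(m, m)
        assert len(out) == 1
        assert (out["replicate_support"] == "both").all()

    def test_disjoint_maps_empty(self):
        m1 = self.map_of([("chr1", 0, 2000, "g1", 0.9)])
        m2 = self.map_of([("chr1", 5000, 7000, "g2", 0.8)])
        assert linking.intersect_replicate_maps(m1, m2).empty


class TestInteractionSupport:
    def test_constructed_counts(self):
        genes = [GeneAnnotation(f"g{i}", "chr1", "+", [i * 50_000 + 25_000])
                 for i in range(4)]
        link_map = pd.DataFrame([
            {"enh_chrom": "chr1", "enh_start": i * 50_000,
             "enh_end": i * 50_000 + 2000, "gene_id": f"g{i}"}
            for i in range(4)])
        # anchors agree with the map for 3 of 4; nearest gene for 2 of 4
        interactions = pd.DataFrame([
            {"chrom": "chr1", "start": 0, "end": 2000, "gene_id": "g0"},
            {"chrom": "chr1", "start": 50_000, "end": 52_000, "gene_id": "g1"},
            {"chrom": "chr1", "start": 100_000, "end": 102_000, "gene_id": "g2"},
            {"chrom": "chr1", "start": 150_000, "end": 152_000, "gene_id": "g0"},
        ])
        # nearest TSS to enhancers 0..3 are g0, g1, g2, g3 except we move
        # two TSSs away so the nearest-gene baseline misses them
        genes[0] = GeneAnnotation("g0", "chr1", "+", [1_000_000])
        genes[3] = GeneAnnotation("g3", "chr1", "+", [1_050_000])
        res = linking.interaction_support(link_map, interactions, genes)
        assert res["n"] == 4
        assert res["map_fraction"] == pytest.approx(0.75)
        assert res["nearest_fraction"] == pytest.approx(0.5)

    def test_empty_interactions_na(self):
        res = linking.interaction_support(
            pd.DataFrame(), pd.DataFrame(columns=["chrom", "start", "end",
                                                  "gene_id"]), [])
        assert np.isnan(res["map_fraction"])

    def test_truth_links_favour_map(self, small_atlas):
        genes, tads, genome = small_atlas
        h3k, _, expr, truth = synthetic.gen_signal_grid(
            genes, tads, n_enhancers=80, n_links=30, link_strength=1.0,
            seed=6, n_reps=1)
        link_map = pd.DataFrame([
            {"enh_chrom": c, "enh_start": s, "enh_end": e, "gene_id": g}
            for c, s, e, g, _ in truth.true_links])
        interactions = synthetic.gen_interaction_fixture(truth, genes)
        res = linking.interaction_support(link_map, interactions, genes)
        assert res["map_fraction"] > res["nearest_fraction"]


class TestMirroredControls:
    def test_reflection_example(self):
        genes = [GeneAnnotation("g1", "chr1", "+", [100_000])]
        m = pd.DataFrame([{"enh_chrom": "chr1", "enh_start": 110_000,
                           "enh_end": 112_000, "gene_id": "g1"}])
        out = linking.mirrored_control_set(m, genes)
        assert out.iloc[0]["control_start"] == 88_000
        assert out.iloc[0]["control_end"] == 90_000

    def test_enhancer_centred_on_tss_degenerate(self):
        genes = [GeneAnnotation("g1", "chr1", "+", [111_000])]
        m = pd.DataFrame([{"enh_chrom": "chr1", "enh_start": 110_000,
                           "enh_end": 112_000, "gene_id": "g1"}])
        out = linking.mirrored_control_set(m, genes)
        assert out.iloc[0]["control_start"] == 110_000
        assert out.iloc[0]["control_end"] == 112_000

    def test_off_chromosome_dropped(self):
        genes = [GeneAnnotation("g1", "chr1", "+", [1_000])]
        m = pd.DataFrame([{"enh_chrom": "chr1", "enh_start": 100_000,
                           "enh_end": 102_000, "gene_id": "g1"}])
        out = linking.mirrored_control_set(m, genes)
        assert out.empty and out.attrs["dropped"] == 1

    def test_distance_invariant(self, rng):
        genes = [GeneAnnotation(f"g{i}", "chr1", "+",
                                [int(rng.integers(400_000, 600_000))])
                 for i in range(30)]
        rows = []
        for i, g in enumerate(genes):
            start = int(rng.integers(50_000, 900_000))
            rows.append({"enh_chrom": "chr1", "enh_start": start,
                         "enh_end": start + 2000, "gene_id": g.gene_id})
        out = linking.mirrored_control_set(pd.DataFrame(rows), genes)
        for r in out.itertuples(index=False):
            enh_mid = (r.enh_start + r.enh_end) // 2
            ctrl_mid = (r.control_start + r.control_end) // 2
            assert abs(enh_mid - r.tss) == abs(ctrl_mid - r.tss)
            assert r.control_end - r.control_start == r.enh_end - r.enh_start


class TestDistanceDecileTest:
    @staticmethod
    def build_controls(truth, genes):
        link_map = pd.DataFrame([
            {"enh_chrom": c, "enh_start": s, "enh_end": e, "gene_id": g}
            for c, s, e, g, _ in truth.true_links])
        return linking.mirrored_control_set(link_map, genes)

    def test_planted_eqtls_enrich_map(self):
        genes, tads = synthetic.gen_annotation_and_tads(
            n_chrom=2, chrom_len=5_000_000, n_genes=150,
            n_tads_per_chrom=8, seed=7)
        *_, truth = synthetic.gen_signal_grid(
            genes, tads, n_enhancers=250, n_links=80, seed=7, n_reps=1)
        controls = self.build_controls(truth, genes)
        eqtl = synthetic.gen_eqtl_fixture(truth, genes, inside_fraction=1.0,
                                          n_pairs=800, seed=1)
        res = linking.distance_decile_test(controls, eqtl)
        assert (res["map_fraction"] >= res["control_fraction"]).all()
        assert (res["fisher_p"] < 0.05).all()

    def test_uniform_eqtls_null(self, small_atlas):
        genes, tads, genome = small_atlas
        *_, truth = synthetic.gen_signal_grid(
            genes, tads, n_enhancers=120, n_links=40, seed=8, n_reps=1)
        controls = self.build_controls(truth, genes)
        eqtl = synthetic.gen_eqtl_fixture(truth, genes, inside_fraction=0.0,
                                          n_pairs=400, genome=genome, seed=2)
        res = linking.distance_decile_test(controls, eqtl)
        assert (res["fisher_p"] > 0.05).mean() >= 0.8

    def test_fisher_closed_form(self):
        # one bin containing the printed toy table (3,1 / 1,3)
        controls = pd.DataFrame([
            {"enh_chrom": "chr1", "enh_start": i * 10_000,
             "enh_end": i * 10_000 + 100, "gene_id": f"g{i}",
             "control_start": 500_000 + i * 10_000,
             "control_end": 500_000 + i * 10_000 + 100,
             "distance": 1000 + i}
            for i in range(4)])
        eqtl_rows = []
        for i in range(3):  # map supported: 3 of 4
            eqtl_rows.append({"chrom": "chr1", "pos": i * 10_000 + 50,
                              "gene_id": f"g{i}"})
        eqtl_rows.append({"chrom": "chr1", "pos": 500_000 + 3 * 10_000 + 50,
                          "gene_id": "g3"})  # control supported: 1 of 4
        res = linking.distance_decile_test(
            controls, pd.DataFrame(eqtl_rows), n_bins=1)
        assert res.iloc[0]["map_supported"] == 3
        assert res.iloc[0]["control_supported"] == 1
        assert res.iloc[0]["fisher_p"] == pytest.approx(0.485714285714, abs=1e-9)

    def test_few_links_fewer_bins(self):
        controls = pd.DataFrame([
            {"enh_chrom": "chr1", "enh_start": 0, "enh_end": 100,
             "gene_id": "g0", "control_start": 200, "control_end": 300,
             "distance": 50}])
        res = linking.distance_decile_test(
            controls, pd.DataFrame(columns=["chrom", "pos", "gene_id"]))
        assert len(res) == 1
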