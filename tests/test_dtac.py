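import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from chromatlas import dtac, synthetic
from chromatlas.core.intervals import GenomicInterval, IntervalSet
from chromatlas.core.matrix import SampleKey, SignalGrid
from chromatlas.states import Segmentation
from conftest import per_base_mask


def counts_grid(values, tissue="t", stages=("E11.5", "E12.5"), n_reps=2):
    values = np.asarray(values, dtype=float)
    regions = IntervalSet.from_tuples(
        [("chr1", i * 3000, i * 3000 + 1000) for i in range(values.shape[0])])
    samples = [SampleKey(tissue, s, str(r + 1))
               for s in stages for r in range(n_reps)]
    return SignalGrid(regions, samples, values, "raw_count")


class TestBuildCatalogue:
    def test_single_sample(self):
        peaks = {("t", "E11.5"): IntervalSet.from_tuples(
            [("chr1", 0, 100), ("chr1", 50, 200), ("chr1", 500, 600)])}
        cat = dtac.build_catalogue(peaks, tss=[])
        assert [(iv.start, iv.end) for iv in cat.regions] == \
            [(0, 200), (500, 600)]
        assert cat.membership["t:E11.5"].all()

    def test_shared_peak_merges_memberships(self):
        peaks = {
            ("a", "E11.5"): IntervalSet.from_tuples([("chr1", 0, 100)]),
            ("b", "E11.5"): IntervalSet.from_tuples([("chr1", 50, 150)]),
        }
        cat = dtac.build_catalogue(peaks, tss=[])
        assert len(cat.regions) == 1
        assert cat.membership.iloc[0].all()

    def test_proximity_classification(self):
        peaks = {("t", "E11.5"): IntervalSet.from_tuples(
            [("chr1", 9500, 9800), ("chr1", 50_000, 50_500)])}
        cat = dtac.build_catalogue(peaks, tss=[("chr1", 10_000)], flank=1000)
        assert cat.proximity == ["proximal", "distal"]

    def test_membership_against_provenance_oracle(self, rng):
        samples = [("a", "E11.5"), ("a", "E12.5"), ("b", "E11.5")]
        peaks = {}
        for t, s in samples:
            n = int(rng.integers(20, 40))
            starts = rng.integers(0, 95_000, n)
            peaks[(t, s)] = IntervalSet.from_tuples(
                [("chr1", int(x), int(x) + int(rng.integers(50, 400)))
                 for x in starts])
        cat = dtac.build_catalogue(peaks, tss=[])
        for i, iv in enumerate(cat.regions.intervals):
            for (t, s), pk in peaks.items():
                expect = any(p.overlaps(iv) for p in pk.intervals)
                assert bool(cat.membership.iloc[i][f"{t}:{s}"]) == expect

    def test_row_sums_at_least_one(self, rng):
        peaks = {("t", "E11.5"): IntervalSet.from_tuples(
            [("chr1", int(x), int(x) + 100)
             for x in rng.integers(0, 90_000, 30)])}
        cat = dtac.build_catalogue(peaks, tss=[])
        assert cat.membership.to_numpy().any(axis=1).all()

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            dtac.build_catalogue({}, tss=[])


def make_consensus(labels, chrom="chr1", bin_bp=1000):
    ivs, labs = [], []
    start, cur = 0, labels[0]
    for i in range(1, len(labels)):
        if labels[i] != cur:
            ivs.append(GenomicInterval(chrom, start * bin_bp, i * bin_bp))
            labs.append(cur)
            start, cur = i, labels[i]
    ivs.append(GenomicInterval(chrom, start * bin_bp, len(labels) * bin_bp))
    labs.append(cur)
    return Segmentation(SampleKey("t", "E11.5", "consensus"),
                        IntervalSet(ivs, labs))


class TestStateEnrichment:
    def test_uniform_catalogue_enrichment_one(self):
        seg = make_consensus(["1"] * 10 + ["2"] * 90)
        peaks = {("t", "E11.5"): IntervalSet.from_tuples([("chr1", 0, 100_000)])}
        cat = dtac.build_catalogue(peaks, tss=[])
        enr = dtac.state_enrichment(cat, seg)
        np.testing.assert_allclose(enr["enrichment"], 1.0)

    def test_concentrated_catalogue(self):
        # state 1 occupies 10% of the genome; all d-TACs inside it
        seg = make_consensus(["1"] * 10 + ["2"] * 90)
        peaks = {("t", "E11.5"): IntervalSet.from_tuples([("chr1", 0, 10_000)])}
        cat = dtac.build_catalogue(peaks, tss=[])
        enr = dtac.state_enrichment(cat, seg)
        assert enr.loc["1", "enrichment"] == pytest.approx(10.0)
        assert enr.loc["2", "enrichment"] == pytest.approx(0.0)

    def test_brute_force_bp_tally(self, rng):
        labels = [str(int(s)) for s in rng.integers(1, 5, 100)]
        seg = make_consensus(labels)
        peaks = {("t", "E11.5"): IntervalSet.from_tuples(
            [("chr1", int(x), int(x) + int(rng.integers(100, 3000)))
             for x in rng.integers(0, 90_000, 20)])}
        cat = dtac.build_catalogue(peaks, tss=[])
        enr = dtac.state_enrichment(cat, seg)
        base_state = np.repeat(labels, 1000)
        cat_mask = per_base_mask(cat.regions, "chr1", 100_000)
        total = cat_mask.sum()
        for state in sorted(set(labels)):
            obs = int((cat_mask & (base_state == state)).sum())
            frac = (base_state == state).mean()
            assert enr.loc[state, "observed_bp"] == obs
            assert enr.loc[state, "enrichment"] == pytest.approx(
                obs / (total * frac))


class TestSensitivitySpecificity:
    def test_constructed_rates(self):
        accessible = IntervalSet.from_tuples(
            [("chr1", i * 1000, i * 1000 + 100) for i in range(8)])
        positives = IntervalSet.from_tuples(
            [("chr1", i * 1000, i * 1000 + 50) for i in range(10)])
        negatives = IntervalSet.from_tuples(
            [("chr1", 500_000 + i * 1000, 500_000 + i * 1000 + 50)
             for i in range(5)])
        rates = dtac.sensitivity_specificity(accessible, positives, negatives)
        assert rates["sensitivity"] == pytest.approx(0.8)
        assert rates["specificity"] == pytest.approx(1.0)

    def test_empty_reference_errors(self):
        s = IntervalSet.from_tuples([("chr1", 0, 100)])
        with pytest.raises(ValueError):
            dtac.sensitivity_specificity(s, IntervalSet(), s)


class TestCallDynamic:
    def test_forced_fold_change_called(self):
        # focal region quadruples; a counterweight keeps library sizes equal
        values = np.array([
            [10, 10, 40, 40],
            [40, 40, 10, 10],
            [1000, 1000, 1000, 1000],
        ])
        calls = dtac.call_dynamic(counts_grid(values), "t")
        focal = calls[calls["region"] == 0]
        assert len(focal) == 1
        assert focal.iloc[0]["log2_fold_change"] == pytest.approx(2.0)
        assert focal.iloc[0]["direction"] == "gain"
        oracle_p = sps.binomtest(20, 100, 0.5).pvalue
        assert focal.iloc[0]["p"] == pytest.approx(oracle_p)

    def test_identical_counts_no_calls(self):
        values = np.tile([[50, 60]], (20, 2)).reshape(20, 4)
        calls = dtac.call_dynamic(counts_grid(values), "t")
        assert calls.empty

    def test_null_type_one_error(self):
        rng = np.random.default_rng(3)
        mus = rng.uniform(100, 400, 4000)
        values = rng.poisson(np.repeat(mus[:, None], 4, axis=1)).astype(float)
        grid = counts_grid(values)
        calls_pool = []
        # p-value calibration irrespective of the fold filter
        stages = grid.stages("t")
        x1 = values[:, :2].sum(axis=1)
        x2 = values[:, 2:].sum(axis=1)
        from chromatlas.core.stats import rate_ratio_test
        ps = np.array([rate_ratio_test(int(a), int(b), x1.sum(), x2.sum())[1]
                       for a, b in zip(x1, x2)])
        rej = float((ps <= 0.05).mean())
        ci = 1.96 * np.sqrt(0.05 * 0.95 / 4000)
        assert rej <= 0.05 + ci

    def test_recovery_on_planted_jumps(self):
        genes, tads = synthetic.gen_annotation_and_tads(seed=4, n_genes=120)
        _, atac, _, truth = synthetic.gen_signal_grid(
            genes, tads, n_enhancers=250, n_links=0,
            dynamics={"n_dynamic": 80, "fold": 2.5},
            profile_amplitude_sd=0.1, profile_wiggle_sd=0.05,
            nb_dispersion=0.01, atac_depth=300, seed=4)
        regions = atac.regions.intervals
        truth_set = {(c, s, e, t, tr) for c, s, e, t, tr, _ in
                     truth.dynamic_regions}
        pred = set()
        for tissue in synthetic.DEFAULT_TISSUES:
            calls = dtac.call_dynamic(atac, tissue)
            for r in calls.itertuples(index=False):
                iv = regions[r.region]
                pred.add((iv.chrom, iv.start, iv.end, tissue, r.transition))
        tp = len(pred & truth_set)
        assert tp / len(truth_set) >= 0.9
        assert 1 - tp / len(pred) <= 0.1

    def test_requires_raw_counts(self):
        grid = counts_grid(np.ones((3, 4)))
        grid.units = "RPKM"
        with pytest.raises(ValueError):
            dtac.call_dynamic(grid, "t")


class TestGainLossEnrichment:
    def test_planted_gainers(self):
        labels_n = ["15"] * 50 + ["5"] * 50
        labels_n1 = ["15"] * 50 + ["5"] * 50
        # gainers move 15 -> 5: plant regions in the first half at stage n
        # whose state at n+1 is 5
        labels_n1[:25] = ["5"] * 25
        seg_n = make_consensus(labels_n)
        seg_n1 = make_consensus(labels_n1)
        peaks = {("t", "E11.5"): IntervalSet.from_tuples(
            [("chr1", i * 1000 + 50, i * 1000 + 950) for i in range(100)])}
        cat = dtac.build_catalogue(peaks, tss=[])
        calls = pd.DataFrame([
            {"region": i, "tissue": "t", "transition": 0,
             "direction": "gain", "log2_fold_change": 2.0}
            for i in range(25)])
        enr = dtac.gain_loss_state_transition_enrichment(
            calls, cat, seg_n, seg_n1, transition=0)
        gain = enr["gain"]
        assert gain.loc["15", "5"] == gain.max().max()
        assert gain.loc["15", "5"] > 1.0

    def test_random_subset_enrichment_near_one(self, rng):
        labels = [str(int(s)) for s in rng.integers(1, 4, 100)]
        seg_n = make_consensus(labels)
        seg_n1 = make_consensus([str(int(s)) for s in rng.integers(1, 4, 100)])
        peaks = {("t", "E11.5"): IntervalSet.from_tuples(
            [("chr1", i * 1000 + 50, i * 1000 + 950) for i in range(100)])}
        cat = dtac.build_catalogue(peaks, tss=[])
        pick = rng.choice(100, 50, replace=False)
        calls = pd.DataFrame([
            {"region": int(i), "tissue": "t", "transition": 0,
             "direction": "gain"} for i in pick])
        enr = dtac.gain_loss_state_transition_enrichment(
            calls, cat, seg_n, seg_n1, transition=0)["gain"]
        vals = enr.to_numpy()
        vals = vals[np.isfinite(vals)]
        assert np.nanmedian(vals) == pytest.approx(1.0, abs=0.5)

    def test_single_dtac_single_cell(self):
        seg = make_consensus(["1"] * 100)
        peaks = {("t", "E11.5"): IntervalSet.from_tuples([("chr1", 0, 500)])}
        cat = dtac.build_catalogue(peaks, tss=[])
        calls = pd.DataFrame([{"region": 0, "tissue": "t", "transition": 0,
                               "direction": "gain"}])
        enr = dtac.gain_loss_state_transition_enrichment(
            calls, cat, seg, seg, transition=0)["gain"]
        assert enr.notna().sum().sum() == 1


class TestOffsetProfile:
    @staticmethod
    def dyn_fixture(lead):
        genes, tads = synthetic.gen_annotation_and_tads(seed=6, n_genes=100)
        _, atac, _, truth = synthetic.gen_signal_grid(
            genes, tads, n_enhancers=300, n_links=0,
            dynamics={"n_dynamic": 150, "fold": 5.0, "lead": lead},
            profile_amplitude_sd=0.1, profile_wiggle_sd=0.05, seed=6)
        return atac, truth

    @staticmethod
    def gain_elements(truth, tissue, lead, n_tr):
        dyn = [(c, s, e, tr) for c, s, e, t, tr, d in truth.dynamic_regions
               if t == tissue and d == "gain" and 0 <= tr + lead < n_tr]
        ivs = IntervalSet.from_tuples([(c, s, e) for c, s, e, _ in dyn])
        return ivs, [tr + lead for _, _, _, tr in dyn]

    def test_accessibility_leads_peak_at_minus_one(self):
        atac, truth = self.dyn_fixture(lead=1)
        n_tr = len(atac.stages("forebrain")) - 1
        ivs, transitions = self.gain_elements(truth, "forebrain", 1, n_tr)
        prof = dtac.offset_profile(ivs, transitions, atac, "forebrain")
        peak = prof.loc[prof["mean_log2_fc"].idxmax(), "offset"]
        assert peak == -1

    def test_simultaneous_peak_at_zero(self):
        atac, truth = self.dyn_fixture(lead=0)
        n_tr = len(atac.stages("forebrain")) - 1
        ivs, transitions = self.gain_elements(truth, "forebrain", 0, n_tr)
        prof = dtac.offset_profile(ivs, transitions, atac, "forebrain")
        peak = prof.loc[prof["mean_log2_fc"].idxmax(), "offset"]
        assert peak == 0

    def test_constant_signal_flat(self):
        regions = IntervalSet.from_tuples(
            [("chr1", i * 3000, i * 3000 + 1000) for i in range(5)])
        stages = ["E11.5", "E12.5", "E13.5"]
        samples = [SampleKey("t", s, str(r)) for s in stages for r in (1, 2)]
        grid = SignalGrid(regions, samples, np.full((5, 6), 3.0), "log2RPKM")
        prof = dtac.offset_profile(regions, [0] * 5, grid, "t")
        np.testing.assert_allclose(prof["mean_log2_fc"], 0.0, atol=1e-12)

    def test_unmatched_elements_counted(self):
        regions = IntervalSet.from_tuples([("chr1", 0, 1000)])
        stages = ["E11.5", "E12.5"]
        samples = [SampleKey("t", s, str(r)) for s in stages for r in (1, 2)]
        grid = SignalGrid(regions, samples, np.ones((1, 4)), "log2RPKM")
        far = IntervalSet.from_tuples([("chr2", 0, 1000)])
        prof = dtac.offset_profile(far, [0], grid, "t")
        assert prof.attrs["skipped"] == 1


class TestCorrelationMap:
    @staticmethod
    def grid_and_tads(rows, tad_bounds):
        n = len(rows)
        regions = IntervalSet.from_tuples(
            [("chr1", i * 10_000, i * 10_000 + 1000) for i in range(n)])
        samples = [SampleKey("t", f"E1{j}.5", "1") for j in range(len(rows[0]))]
        grid = SignalGrid(regions, samples, np.asarray(rows, float), "RPKM")
        tads = IntervalSet.from_tuples([("chr1", a, b) for a, b in tad_bounds])
        return grid, tads

    def test_duplicated_rows_same_tad_retained(self, rng):
        x = rng.random(8) * 10
        grid, tads = self.grid_and_tads([x, x], [(0, 50_000)])
        pairs = dtac.correlation_map(grid, tads)
        assert len(pairs) == 1
        assert pairs.iloc[0]["pcc"] == pytest.approx(1.0)

    def test_duplicated_rows_different_tads_not_retained(self, rng):
        x = rng.random(8) * 10
        grid, tads = self.grid_and_tads([x, x], [(0, 5_000), (5_000, 50_000)])
        assert dtac.correlation_map(grid, tads).empty

    def test_null_false_positive_rate(self):
        rng = np.random.default_rng(11)
        n, m = 60, 66
        rows = rng.random((n, m)) * 10
        grid, tads = self.grid_and_tads(list(rows), [(0, 10_000 * n + 1000)])
        pairs = dtac.correlation_map(grid, tads, threshold=0.7)
        # null PCC at threshold 0.7 with 66 samples is essentially impossible
        n_pairs = n * (n - 1) / 2
        assert len(pairs) <= 0.001 * n_pairs + 1

    def test_column_permutation_invariant(self, rng):
        rows = rng.random((10, 8)) * 5
        grid, tads = self.grid_and_tads(list(rows), [(0, 200_000)])
        pairs1 = dtac.correlation_map(grid, tads)
        perm = rng.permutation(8)
        grid2 = grid.subset_samples(list(perm))
        pairs2 = dtac.correlation_map(grid2, tads)
        pd.testing.assert_frame_equal(
            pairs1.sort_values(["region_a", "region_b"]).reset_index(drop=True),
            pairs2.sort_values(["region_a", "region_b"]).reset_index(drop=True))


class TestDistanceProfile:
    @staticmethod
    def planted_grid(seed, tad_coupling=True):
        rng = np.random.default_rng(seed)
        n_per_chrom, m = 60, 40
        rows, tuples = [], []
        tad_bounds = []
        for chrom in [f"chr{c}" for c in range(1, 9)]:
            for t in range(6):
                tad_bounds.append((chrom, t * 100_000, (t + 1) * 100_000 - 100))
            shared = rng.standard_normal((6, m)) * 2
            for i in range(n_per_chrom):
                pos = i * 10_000 + 2_000
                tad_idx = pos // 100_000
                base = shared[tad_idx] if tad_coupling else \
                    rng.standard_normal(m) * 2
                rows.append(10 + base + rng.standard_normal(m) * 0.8)
                tuples.append((chrom, pos, pos + 1000))
        regions = IntervalSet.from_tuples(tuples)
        samples = [SampleKey("t", f"E{j}", "1") for j in range(m)]
        grid = SignalGrid(regions, samples,
                          np.maximum(np.asarray(rows), 0.01), "RPKM")
        tads = IntervalSet.from_tuples(tad_bounds)
        return grid, tads

    def test_intra_above_inter_with_coupling(self):
        grid, tads = self.planted_grid(1, tad_coupling=True)
        prof = dtac.distance_profile(grid, tads, max_dist=200_000)
        both = prof.dropna(subset=["mean_pcc_intra", "mean_pcc_inter"])
        assert (both["mean_pcc_intra"] > both["mean_pcc_inter"]).all()
        assert (both.loc[both["n_paired"] >= 5, "wilcoxon_p"] < 0.05).any()

    def test_tad_free_null_indistinguishable(self):
        grid, tads = self.planted_grid(2, tad_coupling=False)
        prof = dtac.distance_profile(grid, tads, max_dist=200_000)
        both = prof.dropna(subset=["mean_pcc_intra", "mean_pcc_inter"])
        diff = (both["mean_pcc_intra"] - both["mean_pcc_inter"]).abs()
        assert diff.median() < 0.1
        ps = both.loc[both["n_paired"] >= 5, "wilcoxon_p"].dropna()
        if len(ps):
            assert (ps < 0.01).mean() < 0.5
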