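"""Balanced resampling, cross-validation, model merging and footprints."""

import numpy as np
import pandas as pd
import pytest

import histosplice as hs
from tests.conftest import random_table, table_from_arrays


class TestBalancedResample:
    def test_majority_subsampled_to_minority(self):
        rng = np.random.default_rng(0)
        t = random_table(rng, 100, 4)
        # force 60/40 imbalance
        y = ["spliced_out"] * 40 + ["included"] * 60
        t = hs.DecisionTable(t.attributes, pd.Series(y, index=t.decision.index))
        bal = hs.balanced_resample(t, 1)
        assert bal.class_counts() == {"spliced_out": 40, "included": 40}
        # minority objects all retained
        minority_ids = set(t.decision.index[:40])
        assert minority_ids <= set(bal.decision.index)

    def test_already_balanced_keeps_all_objects(self):
        t = table_from_arrays([[1], [0], [1], [0]],
                              ["spliced_out", "spliced_out",
                               "included", "included"])
        bal = hs.balanced_resample(t, 2)
        assert sorted(bal.decision.index) == sorted(t.decision.index)

    def test_same_seed_reproducible(self):
        rng = np.random.default_rng(3)
        t = random_table(rng, 80, 3)
        a = hs.balanced_resample(t, 42)
        b = hs.balanced_resample(t, 42)
        assert list(a.decision.index) == list(b.decision.index)


class TestFolds:
    def test_partition_properties(self):
        rng = np.random.default_rng(4)
        t = random_table(rng, 95, 3)
        folds = hs.evaluation.stratified_folds(t.decision, 5, 5)
        flat = np.concatenate(folds)
        assert sorted(flat) == list(range(95))
        assert len(set(flat)) == 95
        y = t.decision.to_numpy()
        for fold in folds:
            frac = (y[fold] == "spliced_out").mean()
            overall = (y == "spliced_out").mean()
            assert abs(frac - overall) < 0.15

    def test_more_folds_than_class_objects_rejected(self):
        t = table_from_arrays([[1], [0], [1]],
                              ["spliced_out", "included", "included"])
        with pytest.raises(ValueError):
            hs.evaluation.stratified_folds(t.decision, 2, 0)


class TestCrossValidate:
    def test_all_abstaining_model_has_zero_coverage(self):
        rng = np.random.default_rng(5)
        t = random_table(rng, 60, 4)
        params = hs.InductionParams(min_support=10_000, min_accuracy=0.99)
        results = hs.cross_validate(t, k=3, params=params, rng=1)
        assert all(r.coverage == 0.0 for r in results)
        assert all(np.isnan(r.accuracy) for r in results)

    def test_noise_free_planted_data_classified_accurately(self, planted_table):
        table = planted_table["table"]
        bal = hs.balanced_resample(table, 7)
        params = hs.InductionParams(hitting_fraction=1.0, min_support=5,
                                    min_accuracy=0.6)
        results = hs.cross_validate(bal, k=5, params=params, rng=8)
        accs = [r.accuracy for r in results if np.isfinite(r.accuracy)]
        assert np.mean([r.coverage for r in results]) > 0.5
        assert np.mean(accs) >= 0.9


class TestRepeatAndMerge:
    def test_single_repeat_merge_is_identity(self):
        rng = np.random.default_rng(6)
        t = random_table(rng, 80, 5)
        params = hs.InductionParams(min_support=2, min_accuracy=0.5)
        model = hs.repeat_and_merge(t, repeats=1, cv_folds=4, params=params,
                                    rng=1)
        keys = [(r.conditions, r.decision) for r in model.rules]
        assert len(keys) == len(set(keys))

    def test_merging_is_idempotent(self):
        r1 = hs.Rule((("a1", 1),), "included", 5, 1.0)
        r2 = hs.Rule((("a2", 0),), "spliced_out", 3, 0.8)
        merged = hs.merge_rules([r1, r2], [r2, r1])
        assert len(merged) == 2
        assert len(hs.merge_rules(merged, merged)) == 2

    def test_coverage_matches_direct_counting(self):
        rng = np.random.default_rng(7)
        t = random_table(rng, 120, 5)
        params = hs.InductionParams(min_support=2, min_accuracy=0.5)
        model = hs.repeat_and_merge(t, repeats=2, cv_folds=4, params=params,
                                    rng=2)
        covered = np.zeros(t.n_objects, dtype=bool)
        for rule in model.rules:
            covered |= rule.matches(t.attributes)
        assert model.coverage == pytest.approx(covered.mean())

    def test_merged_rules_reevaluated_on_full_table(self):
        rng = np.random.default_rng(8)
        t = random_table(rng, 100, 4)
        params = hs.InductionParams(min_support=2, min_accuracy=0.5)
        model = hs.repeat_and_merge(t, repeats=2, cv_folds=4, params=params,
                                    rng=3)
        for rule in model.rules:
            n, k = hs.evaluate_on_data(rule, t)
            assert rule.support == n
            if n:
                assert rule.accuracy == pytest.approx(k / n)


class TestFootprint:
    def tiled_track(self, size=30000):
        frags = pd.DataFrame(
            [("chr1", s, s + 150, "+") for s in range(0, size, 150)],
            columns=["chrom", "start", "end", "strand"],
        )
        return hs.build_pileup(frags, {"chr1": size}, 1.0)

    def exon_setup(self):
        table = table_from_arrays([[1]], ["spliced_out"], names=["M.prec"])
        coords = pd.DataFrame(
            [{"exon_id": "x1", "chrom": "chr1", "start": 15000, "end": 15200,
              "strand": "+"}]
        )
        return table, coords

    def test_uniform_track_gives_flat_footprint(self):
        table, coords = self.exon_setup()
        rule = hs.Rule((("M.prec", 1),), "spliced_out")
        fp = hs.footprint(rule, table, coords, {"M": self.tiled_track()},
                          window=500, depth_normalize=False)["M"]
        assert fp.n_exons == 1
        assert np.allclose(fp.five_prime, 1.0)
        assert np.allclose(fp.three_prime, 1.0)

    def test_single_exon_footprint_equals_own_signal(self):
        table, coords = self.exon_setup()
        track = self.tiled_track()
        rule = hs.Rule((("M.prec", 1),), "spliced_out")
        fp = hs.footprint(rule, table, coords, {"M": track}, window=200,
                          depth_normalize=False)["M"]
        cov = track.coverage("chr1")
        assert np.array_equal(fp.five_prime, cov[14800:15200].astype(float))

    def test_planted_preceding_rule_peaks_upstream(self, planted_dataset,
                                                   planted_table):
        table = planted_table["table"]
        tracks = planted_table["tracks"]
        coords = planted_table["internal"]
        rule = hs.Rule((("M01.prec", 1), ("M02.exon", 1)), "spliced_out")
        fp = hs.footprint(rule, table, coords, tracks, window=400)["M01"]
        assert fp.n_exons > 10
        upstream = np.nanmean(fp.five_prime[220:380])    # enriched flank
        downstream = np.nanmean(fp.three_prime[420:580])  # 3' intron, background
        assert upstream > 3 * downstream

    def test_rule_without_support_raises(self):
        table, coords = self.exon_setup()
        rule = hs.Rule((("M.prec", 0),), "included")
        with pytest.raises(ValueError):
            hs.footprint(rule, table, coords, {"M": self.tiled_track()})


def test_pipeline_result_carries_consistent_counts(planted_dataset):
    """End-to-end smoke run on the small planted dataset."""
    res = hs.run_synthetic_pipeline(
        planted_dataset.config,
        mcfs_params=hs.MCFSParams(s=30, m=4, t=2),
        induction=hs.InductionParams(hitting_fraction=1.0, min_support=5,
                                     min_accuracy=0.6),
        repeats=2, cv_folds=4,
    )
    assert res.table.n_objects == res.stage_counts["decision_table_objects"]
    assert res.stage_counts["spliced_out"] + res.stage_counts["included"] \
        == res.table.n_objects
    assert len(res.selected_attributes) <= 20
    assert 0 <= res.model.coverage <= 1
    assert len(res.model.statistics) == len(res.model.rules)
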