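import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

from hrnv.evaluation import (
    LogisticRecipe,
    SelectionRecipe,
    VitalsRecord,
    auc,
    auc_ci,
    compare_models,
    kfold_out_of_fold_scores,
    mews_score,
    news_score,
    qsofa_score,
    roc_points,
    score_column,
)


def make_cohort(seed, n=342, beta=1.0, prevalence=0.19):
    r = np.random.default_rng(seed)
    x1 = r.normal(0, 1, n)
    x2 = r.normal(0, 1, n)
    eta = np.log(prevalence / (1 - prevalence)) + beta * x1
    y = (r.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
    if y.sum() < 2 or y.sum() > n - 2:
        return make_cohort(seed + 1000, n, beta, prevalence)
    return pd.DataFrame({"x1": x1, "x2": x2, "outcome": y})


class TestAuc:
    def test_perfect_separation(self):
        assert auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_hand_pair_count(self):
        assert auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == pytest.approx(0.75)

    def test_null_scores(self, rng):
        scores = rng.random(1000)
        labels = (rng.random(1000) < 0.3).astype(int)
        assert auc(scores, labels) == pytest.approx(0.5, abs=0.05)

    def test_sklearn_oracle(self, rng):
        for _ in range(30):
            scores = rng.normal(0, 1, 200)
            labels = (rng.random(200) < 0.4).astype(int)
            if labels.sum() in (0, 200):
                continue
            assert auc(scores, labels) == pytest.approx(roc_auc_score(labels, scores))

    def test_ties_count_half(self):
        assert auc([0.5, 0.5], [0, 1]) == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc([0.1, 0.2], [1, 1])


class TestRocPoints:
    def test_monotone(self, rng):
        scores = rng.normal(0, 1, 300)
        labels = (rng.random(300) < 0.3).astype(int)
        _, fpr, tpr = roc_points(scores, labels)
        assert np.all(np.diff(fpr) >= 0)
        assert np.all(np.diff(tpr) >= 0)
        assert fpr[0] == 0.0 and fpr[-1] == 1.0
        assert tpr[0] == 0.0 and tpr[-1] == 1.0

    def test_trapezoid_equals_pair_estimator(self, rng):
        """Two AUC computations agree to near machine precision."""
        for _ in range(20):
            scores = np.round(rng.normal(0, 1, 200), 2)  # force some ties
            labels = (rng.random(200) < 0.35).astype(int)
            if labels.sum() in (0, 200):
                continue
            _, fpr, tpr = roc_points(scores, labels)
            trapezoid = np.trapezoid(tpr, fpr)
            assert trapezoid == pytest.approx(auc(scores, labels), abs=1e-10)


class TestAucCi:
    def test_delong_brackets_point(self):
        cohort = make_cohort(0)
        scores = cohort["x1"].to_numpy()
        y = cohort["outcome"].to_numpy()
        lo, hi, method = auc_ci(scores, y)
        assert method == "delong"
        assert lo <= auc(scores, y) <= hi

    def test_delong_bootstrap_agree(self):
        cohort = make_cohort(1, n=342)
        scores, y = cohort["x1"].to_numpy(), cohort["outcome"].to_numpy()
        d_lo, d_hi, _ = auc_ci(scores, y, method="delong")
        b_lo, b_hi, _ = auc_ci(scores, y, method="bootstrap", seed=0)
        assert abs(d_lo - b_lo) < 0.03
        assert abs(d_hi - b_hi) < 0.03

    def test_ci_narrows_with_n(self):
        small = make_cohort(2, n=100)
        large = make_cohort(2, n=342)
        lo_s, hi_s, _ = auc_ci(small["x1"], small["outcome"])
        lo_l, hi_l, _ = auc_ci(large["x1"], large["outcome"])
        assert (hi_s - lo_s) > (hi_l - lo_l)

    def test_perfect_auc_capped(self):
        scores = np.r_[np.zeros(20), np.ones(20)]
        labels = np.r_[np.zeros(20), np.ones(20)].astype(int)
        lo, hi, _ = auc_ci(scores, labels)
        assert hi <= 1.0


class TestKfold:
    def test_fold_structure(self):
        cohort = make_cohort(3, n=342)
        recipe = LogisticRecipe(["x1", "x2"])
        scores, assignment = kfold_out_of_fold_scores(cohort, recipe, k=10, seed=0)
        sizes = np.bincount(assignment)
        assert set(sizes) <= {34, 35}
        assert sizes.sum() == 342
        assert np.all(assignment >= 0)
        assert not np.isnan(scores).any()

    def test_leave_one_out_tiny(self):
        cohort = make_cohort(4, n=40, beta=2.0)
        k = 20
        scores, assignment = kfold_out_of_fold_scores(
            cohort, LogisticRecipe(["x1"]), k=k, seed=1
        )
        assert len(np.unique(assignment)) == k

    def test_deterministic_given_seed(self):
        cohort = make_cohort(5)
        recipe = LogisticRecipe(["x1", "x2"])
        s1, a1 = kfold_out_of_fold_scores(cohort, recipe, k=10, seed=7)
        s2, a2 = kfold_out_of_fold_scores(cohort, recipe, k=10, seed=7)
        assert np.array_equal(s1, s2) and np.array_equal(a1, a2)

    def test_no_leakage_by_construction(self):
        """The recipe records which patients it trained on; no patient may be
        scored by a model trained on them."""
        cohort = make_cohort(6)
        trained_on = {}

        class TracingRecipe(LogisticRecipe):
            def __call__(self, train):
                scorer = super().__call__(train)
                train_ids = set(train.index)

                def traced(test):
                    for idx in test.index:
                        trained_on.setdefault(idx, []).append(train_ids)
                    return scorer(test)

                return traced

        kfold_out_of_fold_scores(cohort, TracingRecipe(["x1"]), k=10, seed=0)
        for idx, train_sets in trained_on.items():
            assert len(train_sets) == 1
            assert idx not in train_sets[0]

    def test_too_small_cohort_rejected(self):
        cohort = make_cohort(7, n=30)
        with pytest.raises(ValueError):
            kfold_out_of_fold_scores(cohort, LogisticRecipe(["x1"]), k=16)


class TestScores:
    def test_normal_vitals_all_zero(self):
        # RR 14 sits in the zero band of every calculator; the published
        # MEWS table assigns 1 point from RR 15 up, unlike NEWS.
        v = VitalsRecord(resp_rate=14, spo2=98, on_oxygen=False, temperature=37.0,
                         sbp=120, heart_rate=70, gcs=15)
        assert news_score(v)[0] == 0
        assert mews_score(v)[0] == 0
        assert qsofa_score(v)[0] == 0

    def test_news_zero_at_rr16_but_mews_one(self):
        v = VitalsRecord(resp_rate=16, spo2=98, on_oxygen=False, temperature=37.0,
                         sbp=120, heart_rate=70, gcs=15)
        assert news_score(v)[0] == 0
        assert mews_score(v)[0] == 1

    def test_qsofa_all_three(self):
        v = VitalsRecord(resp_rate=25, sbp=90, gcs=14)
        assert qsofa_score(v)[0] == 3

    def test_qsofa_sbp_boundary(self):
        assert qsofa_score(VitalsRecord(resp_rate=10, sbp=100, gcs=15))[0] == 1
        assert qsofa_score(VitalsRecord(resp_rate=10, sbp=101, gcs=15))[0] == 0

    def test_qsofa_rr_boundary(self):
        assert qsofa_score(VitalsRecord(resp_rate=22, sbp=120, gcs=15))[0] == 1
        assert qsofa_score(VitalsRecord(resp_rate=21, sbp=120, gcs=15))[0] == 0

    def test_missing_fields_flagged(self):
        score, flags = qsofa_score(VitalsRecord(resp_rate=25))
        assert score == 1
        assert "sbp" in flags and "gcs" in flags

    @pytest.mark.parametrize(
        "rr,expected", [(8, 3), (9, 1), (11, 1), (12, 0), (20, 0), (21, 2), (24, 2), (25, 3)]
    )
    def test_news_rr_bands(self, rr, expected):
        v = VitalsRecord(resp_rate=rr, spo2=98, on_oxygen=False, temperature=37.0,
                         sbp=120, heart_rate=70, gcs=15)
        assert news_score(v)[0] == expected

    @pytest.mark.parametrize(
        "sbp,expected", [(70, 3), (71, 2), (80, 2), (81, 1), (100, 1), (101, 0), (199, 0), (200, 2)]
    )
    def test_mews_sbp_bands(self, sbp, expected):
        v = VitalsRecord(resp_rate=12, sbp=sbp, heart_rate=70, temperature=37.0, gcs=15)
        assert mews_score(v)[0] == expected

    def test_news_component_additivity(self):
        """Total equals the sum of the per-component bands."""
        v = VitalsRecord(resp_rate=25, spo2=91, on_oxygen=True, temperature=34.0,
                         sbp=85, heart_rate=135, gcs=10)
        assert news_score(v)[0] == 3 + 3 + 2 + 3 + 3 + 3 + 3


class TestCompareModels:
    def test_signal_model_beats_null(self):
        wins = 0
        for seed in range(10):
            cohort = make_cohort(seed, n=342, beta=1.2)
            cohort["resp_rate"] = np.random.default_rng(seed).normal(18, 3, len(cohort))
            cohort["sbp"] = np.random.default_rng(seed + 1).normal(110, 25, len(cohort))
            cohort["gcs"] = 15.0
            results = compare_models(
                cohort,
                recipes={"model": LogisticRecipe(["x1", "x2"])},
                score_baselines={"qSOFA": qsofa_score},
                k=10,
                seed=seed,
            )
            wins += results["model"].auc > results["qSOFA"].auc
        assert wins >= 9

    def test_zero_signal_auc_near_half(self):
        cohort = make_cohort(11, n=600, beta=0.0)
        results = compare_models(
            cohort, recipes={"model": LogisticRecipe(["x1", "x2"])}, k=10, seed=0
        )
        assert results["model"].auc == pytest.approx(0.5, abs=0.08)

    def test_deterministic(self):
        cohort = make_cohort(12)
        kwargs = dict(recipes={"m": LogisticRecipe(["x1"])}, k=10, seed=5)
        r1 = compare_models(cohort, **kwargs)
        r2 = compare_models(cohort, **kwargs)
        assert r1["m"].auc == r2["m"].auc
        assert np.array_equal(r1["m"].fold_assignment, r2["m"].fold_assignment)

    def test_failing_entrant_logged(self):
        cohort = make_cohort(13)

        def broken(train):
            raise RuntimeError("boom")

        results = compare_models(cohort, recipes={"bad": broken, "ok": LogisticRecipe(["x1"])})
        assert "bad" in results["_errors"]
        assert "ok" in results


class TestSelectionRecipe:
    def test_in_fold_selection_runs(self):
        cohort = make_cohort(14, n=400, beta=1.0)
        cohort["age"] = np.random.default_rng(0).normal(68, 15, len(cohort))
        scores, _ = kfold_out_of_fold_scores(
            cohort, SelectionRecipe(["x1", "x2"]), k=5, seed=0
        )
        y = cohort["outcome"].to_numpy()
        assert auc(scores, y) > 0.6

    def test_end_to_end_tachogram_features_beat_vitals(self):
        """Full path: group-dependent tachograms -> parameter suite ->
        CV-evaluated model, compared against a vitals-only score."""
        from hrnv.synthetic import TachogramSpec, generate_feature_block

        r = np.random.default_rng(42)
        n = 80
        outcome = (r.random(n) < 0.3).astype(int)
        features = generate_feature_block(
            n,
            outcome,
            (
                TachogramSpec(duration_s=120, mean_hr=75, hf_amp=0.01, noise_sd=3.0),
                TachogramSpec(duration_s=120, mean_hr=75, hf_amp=0.08, noise_sd=15.0),
            ),
            duration_s=120.0,
            seed=9,
        )
        cohort = features[["HRV_rmssd", "HRV_sdnn"]].copy()
        cohort["resp_rate"] = r.normal(18, 3, n)  # vitals carry no signal
        cohort["sbp"] = r.normal(110, 25, n)
        cohort["gcs"] = 15.0
        cohort["outcome"] = outcome
        results = compare_models(
            cohort,
            recipes={"hrnv": LogisticRecipe(["HRV_rmssd", "HRV_sdnn"])},
            score_baselines={"qSOFA": qsofa_score},
            k=5,
            seed=0,
        )
        assert results["hrnv"].auc > results["qSOFA"].auc
        assert results["hrnv"].auc > 0.8

    def test_score_column_vectorizes(self):
        cohort = pd.DataFrame(
            {"resp_rate": [16, 25], "sbp": [120, 90], "gcs": [15, 14]}
        )
        np.testing.assert_array_equal(score_column(cohort, qsofa_score), [0.0, 3.0])
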