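"""Nested-CV splitting, metrics, operating-point and permutation machinery."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from brainage import evaluation as ev
from brainage.synthetic import AgeDistribution, CohortConfig, records_to_frame, sample_cohort


def _cohort_frame(n=200, seed=0):
    cfg = CohortConfig(n_subjects=n, seed=seed)
    return records_to_frame(sample_cohort(cfg))


class TestSplitPlan:
    def test_partition_and_disjointness(self):
        frame = _cohort_frame(200)
        plan = ev.make_split_plan(frame, k=5, seed=1)
        all_test = np.concatenate(plan.outer_test)
        assert len(all_test) == 200
        assert len(np.unique(all_test)) == 200
        for i in range(plan.k):
            tr, va, te = plan.fold(i)
            assert len(np.intersect1d(tr, te)) == 0
            assert len(np.intersect1d(va, te)) == 0
            assert len(np.intersect1d(tr, va)) == 0
            assert len(te) == 40

    def test_female_fraction_balanced_per_fold(self):
        frame = _cohort_frame(200, seed=3)
        plan = ev.make_split_plan(frame, k=5, seed=3)
        sexes = np.asarray(frame.sex)
        overall = sexes.sum() / 5.0
        for te in plan.outer_test:
            assert abs(sexes[te].sum() - overall) <= plan_k_tolerance(frame, 5)

    def test_deterministic(self):
        frame = _cohort_frame(120, seed=5)
        p1 = ev.make_split_plan(frame, k=4, seed=9)
        p2 = ev.make_split_plan(frame, k=4, seed=9)
        for a, b in zip(p1.outer_test, p2.outer_test):
            np.testing.assert_array_equal(a, b)
        for a, b in zip(p1.inner_train, p2.inner_train):
            np.testing.assert_array_equal(a, b)

    @settings(max_examples=10, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), k=st.sampled_from([2, 3, 5]))
    def test_partition_property_random_cohorts(self, seed, k):
        frame = _cohort_frame(90, seed=seed % 100)
        plan = ev.make_split_plan(frame, k=k, seed=seed)
        all_test = np.sort(np.concatenate(plan.outer_test))
        np.testing.assert_array_equal(all_test, np.arange(len(frame)))

    def test_small_k_rejected(self):
        with pytest.raises(ValueError):
            ev.make_split_plan(_cohort_frame(50), k=1)

    def test_json_round_trip(self, tmp_path):
        frame = _cohort_frame(60, seed=2)
        plan = ev.make_split_plan(frame, k=3, seed=2)
        path = tmp_path / "plan.json"
        plan.to_json(list(frame.subject_id), path)
        import json

        payload = json.loads(path.read_text())
        assert set(payload) == {"fold_0", "fold_1", "fold_2"}
        ids = [s for f in payload.values() for s in f["test"]]
        assert sorted(ids) == sorted(frame.subject_id)


def plan_k_tolerance(frame, k):
    # stratification guarantee: within one subject per stratum
    return len(np.unique(frame.sex)) * 15 / k + 1  # loose but scale-aware bound


class TestPredictionR2:
    def test_perfect_prediction(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        assert ev.prediction_r2(y, y) == pytest.approx(1.0)

    def test_mean_predictor_scores_zero(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        assert ev.prediction_r2(y, np.full(4, y.mean())) == pytest.approx(0.0)

    def test_hand_computed_negative_value(self):
        assert ev.prediction_r2([1, 2, 3], [3, 3, 3]) == pytest.approx(-1.5)

    def test_zero_variance_raises(self):
        with pytest.raises(ValueError, match="variance"):
            ev.prediction_r2([2, 2, 2], [1, 2, 3])

    def test_equals_r_squared_for_least_squares_fit(self):
        """q^2 = r^2 exactly when estimates are the LS affine transform of
        the predictor (checked against an independent OLS fit)."""
        rng = np.random.default_rng(4)
        z = rng.normal(size=80)
        y = 2.0 * z + rng.normal(size=80)
        slope, intercept, r, _, _ = stats.linregress(z, y)
        fitted = intercept + slope * z
        assert ev.prediction_r2(y, fitted) == pytest.approx(r**2, abs=1e-12)

    def test_training_mean_baseline_variant(self):
        y = np.array([1.0, 2.0, 3.0])
        est = np.array([1.1, 2.0, 2.9])
        alt = ev.prediction_r2(y, est, baseline_mean=10.0)
        assert alt > ev.prediction_r2(y, est) * 0  # defined and finite
        ss_res = np.sum((y - est) ** 2)
        assert alt == pytest.approx(1 - ss_res / np.sum((y - 10.0) ** 2))


class TestRegressionMetrics:
    def test_shifted_estimates(self):
        y = np.linspace(8, 18, 20)
        rep = ev.regression_metrics(y, y + 1.0)
        assert rep.mae == pytest.approx(1.0)
        assert rep.pearson_r == pytest.approx(1.0)

    def test_anticorrelated(self):
        y = np.array([-1.0, 0.0, 1.0, 2.0])
        rep = ev.regression_metrics(y, -y)
        assert rep.pearson_r == pytest.approx(-1.0)

    def test_r_matches_covariance_formula(self):
        rng = np.random.default_rng(11)
        y = rng.normal(12, 3, size=50)
        est = 0.8 * y + rng.normal(0, 1, size=50)
        rep = ev.regression_metrics(y, est)
        brute = np.mean((y - y.mean()) * (est - est.mean())) / (y.std() * est.std())
        assert rep.pearson_r == pytest.approx(brute, abs=1e-12)

    def test_tiny_sample_rejected(self):
        with pytest.raises(ValueError):
            ev.regression_metrics([1, 2], [1, 2])


class TestSelectCutoff:
    def test_separable_scores(self):
        thr = ev.select_cutoff([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert 0.2 < thr < 0.8
        sens, spec = ev._sens_spec(np.array([0.1, 0.2, 0.8, 0.9]),
                                   np.array([0, 0, 1, 1]), thr)
        assert sens == spec == 1.0

    def test_worked_example(self):
        thr = ev.select_cutoff([0.1, 0.4, 0.6, 0.9], [0, 0, 1, 1])
        assert 0.4 < thr < 0.6

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            ev.select_cutoff([0.1, 0.9], [1, 1])

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_matches_exhaustive_search(self, seed):
        """Harmonic-mean operating point equals brute force over a dense
        threshold grid, for random instances with n <= 50."""
        rng = np.random.default_rng(seed)
        n = rng.integers(4, 50)
        scores = rng.normal(size=n)
        labels = np.zeros(n, dtype=int)
        labels[rng.choice(n, size=max(1, n // 3), replace=False)] = 1
        if labels.sum() in (0, n):
            return
        thr = ev.select_cutoff(scores, labels)
        best_h = brute_force_best_harmonic(scores, labels)
        sens, spec = ev._sens_spec(scores, labels, thr)
        h = 2 * sens * spec / (sens + spec) if sens + spec else 0.0
        assert h == pytest.approx(best_h, abs=1e-12)


def brute_force_best_harmonic(scores, labels):
    grid = np.concatenate([scores - 1e-9, scores + 1e-9])
    best = 0.0
    for thr in grid:
        sens, spec = ev._sens_spec(scores, labels, thr)
        h = 2 * sens * spec / (sens + spec) if sens + spec else 0.0
        best = max(best, h)
    return best


class TestClassificationMetrics:
    def test_balanced_accuracy_identity(self):
        rng = np.random.default_rng(0)
        labels = np.array([0] * 30 + [1] * 20)
        scores = rng.uniform(size=50) + 0.3 * labels
        rep = ev.classification_metrics(scores, labels, 0.5)
        assert rep.balanced_accuracy == pytest.approx(
            (rep.sensitivity + rep.specificity) / 2
        )

    def test_null_auc_near_half(self):
        rng = np.random.default_rng(1)
        labels = np.repeat([0, 1], 500)
        scores = rng.uniform(size=1000)
        rep = ev.classification_metrics(scores, labels, 0.5)
        assert abs(rep.auc - 0.5) < 0.06

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            ev.classification_metrics([0.1, 0.9], [1, 1], 0.5)


class TestPermutationTest:
    @staticmethod
    def _auc(scores, labels):
        from sklearn.metrics import roc_auc_score

        return roc_auc_score(labels, scores)

    def test_perfect_classifier_attains_minimum_p(self):
        labels = np.repeat([0, 1], 10)
        p = ev.permutation_test(labels.astype(float), labels, self._auc,
                                n_perm=200, seed=0)
        assert p == pytest.approx(1 / 201)

    def test_constant_metric_gives_p_one(self):
        labels = np.repeat([0, 1], 10)
        p = ev.permutation_test(np.arange(20, dtype=float), labels,
                                lambda s, l: 0.5, n_perm=100, seed=0)
        assert p == 1.0

    def test_exchangeable_under_joint_reordering(self):
        rng = np.random.default_rng(5)
        scores = rng.normal(size=30)
        labels = rng.integers(0, 2, size=30)
        labels[0], labels[1] = 0, 1  # both classes present
        p1 = ev.permutation_test(scores, labels, self._auc, n_perm=200, seed=3)
        perm = rng.permutation(30)
        p2 = ev.permutation_test(scores[perm], labels[perm], self._auc,
                                 n_perm=200, seed=3)
        assert p1 == p2

    def test_too_few_permutations_rejected(self):
        with pytest.raises(ValueError):
            ev.permutation_test([0.1, 0.9], [0, 1], self._auc, n_perm=10)


class TestSelectBestModel:
    def _rep(self, r=None, mae=None):
        return ev.MetricsReport(n=10, pearson_r=r, mae=mae)

    def test_argmax_r(self):
        reps = [self._rep(0.6, 1.0), self._rep(0.8, 1.0), self._rep(0.7, 1.0)]
        assert ev.select_best_model(reps) == 1

    def test_tie_broken_by_mae(self):
        reps = [self._rep(0.8, 1.5), self._rep(0.8, 1.2)]
        assert ev.select_best_model(reps) == 1

    def test_mae_criterion(self):
        reps = [self._rep(0.5, 1.4), self._rep(0.5, 1.2), self._rep(0.5, 1.6)]
        assert ev.select_best_model(reps, criterion="mae") == 1

    def test_no_finite_values_raises(self):
        with pytest.raises(ValueError):
            ev.select_best_model([self._rep(None, None)])


class TestCrossDatasetEvaluate:
    class LinearStub:
        """Deterministic stand-in model: mean-density readout of channel 0."""

        def predict(self, volumes):
            return volumes.reshape(len(volumes), -1).mean(axis=1)

    def test_consistency_with_direct_metrics(self):
        rng = np.random.default_rng(2)
        vols = rng.uniform(size=(40, 2, 4, 4, 4))
        ages = vols.reshape(40, -1).mean(axis=1) * 100 + rng.normal(0, 0.5, 40)
        rep = ev.cross_dataset_evaluate(self.LinearStub(), vols, ages)
        direct = ev.regression_metrics(ages, self.LinearStub().predict(vols))
        assert rep.pearson_r == direct.pearson_r
        assert rep.mae == direct.mae
        assert "target_sd" in rep.extras

    def test_range_restriction_lowers_r_not_mae(self):
        """On a narrower-age external cohort, |r| drops while MAE can stay
        small: the classic range-restriction signature."""
        rng = np.random.default_rng(3)
        signal = rng.uniform(8, 18, size=400)
        noise = rng.normal(0, 1.0, size=400)
        estimates = signal + noise

        wide = ev.regression_metrics(signal, estimates)
        narrow_mask = np.abs(signal - 13.0) < 1.0
        narrow = ev.regression_metrics(signal[narrow_mask], estimates[narrow_mask])
        assert narrow.pearson_r < wide.pearson_r
        assert narrow.mae == pytest.approx(wide.mae, abs=0.3)
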