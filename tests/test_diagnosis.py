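"""Classifiers, diagnostic metrics, resampling machinery, biomarker screen."""

import itertools

import numpy as np
import pytest
from scipy import stats

from ldims.diagnosis import (ElasticNetDiagnosis, OPLSDA, compute_metrics,
                             cross_validate, fit_elastic_net, fit_oplsda,
                             permutation_test, replicate_ensemble,
                             screen_biomarkers, ReplicateProbabilities)


def mann_whitney_auc(probs, labels):
    """Hand-enumerated pairwise oracle with half credit for ties."""
    probs, labels = np.asarray(probs), np.asarray(labels)
    pos, neg = probs[labels == 1], probs[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestComputeMetrics:
    def test_perfect_classifier(self):
        m = compute_metrics([1, 1, 1, 0, 0, 0], [1, 1, 1, 0, 0, 0],
                            ci_bootstraps=50)
        assert m.auc == 1.0 and m.sensitivity == 1.0 and m.specificity == 1.0
        assert m.auprc == 1.0

    def test_hand_enumerated_toy_sets(self):
        probs = [.9, .8, .7, .4, .3, .2]
        m1 = compute_metrics(probs, [1, 1, 1, 0, 0, 0], ci_bootstraps=0)
        assert m1.auc == 1.0
        m2 = compute_metrics(probs, [1, 1, 0, 1, 0, 0], ci_bootstraps=0)
        assert m2.auc == pytest.approx(8 / 9)

    def test_constant_classifier_auprc_is_prevalence(self):
        y = np.array([1, 1, 0, 0, 0, 0, 0, 0])
        m = compute_metrics(np.full(8, 0.5), y, ci_bootstraps=0)
        assert m.auprc == pytest.approx(y.mean())

    def test_uninformative_probs_near_half(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, 4000)
        y[:2] = [0, 1]
        m = compute_metrics(rng.random(4000), y, ci_bootstraps=0)
        se = np.sqrt(1 / 12) / np.sqrt(min((y == 1).sum(), (y == 0).sum()))
        assert abs(m.auc - 0.5) < 3 * se

    def test_matches_mann_whitney_oracle_with_ties(self):
        rng = np.random.default_rng(1)
        for _ in range(30):
            n = rng.integers(4, 9)
            y = np.zeros(n, int)
            y[rng.choice(n, rng.integers(1, n), replace=False)] = 1
            if y.min() == y.max():
                continue
            probs = np.round(rng.random(n), 1)  # induces ties
            m = compute_metrics(probs, y, ci_bootstraps=0)
            assert m.auc == pytest.approx(mann_whitney_auc(probs, y))

    def test_operating_point_flags(self):
        probs = [.9, .7, .6, .55, .3, .1]
        y = [1, 1, 0, 1, 0, 0]
        ul = compute_metrics(probs, y, ci_bootstraps=0)
        yj = compute_metrics(probs, y, ci_bootstraps=0, operating_point="youden")
        assert 0 <= ul.threshold <= 1 and 0 <= yj.threshold <= 1

    def test_ci_brackets_auc(self):
        rng = np.random.default_rng(2)
        y = np.r_[np.ones(20), np.zeros(20)].astype(int)
        probs = np.clip(y * 0.3 + rng.random(40) * 0.7, 0, 1)
        m = compute_metrics(probs, y, ci_bootstraps=500, seed=1)
        assert m.auc_ci[0] <= m.auc <= m.auc_ci[1]

    def test_input_validation(self):
        with pytest.raises(ValueError):
            compute_metrics([1.2, 0.5], [1, 0])
        with pytest.raises(ValueError):
            compute_metrics([0.5, 0.6], [1, 1])


class TestElasticNet:
    def _cohort(self, seed=0, n=60, p=20, informative=3, beta=2.0):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, p))
        logit = X[:, :informative].sum(axis=1) * beta
        y = (logit + rng.logistic(size=n) > 0).astype(int)
        if y.min() == y.max():
            y[0] = 1 - y[0]
        return X, y

    def test_perfectly_separating_feature_dominates(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(40, 6))
        y = (X[:, 2] > 0).astype(int)
        X[:, 2] = y * 4.0 - 2.0
        m = fit_elastic_net(X, y, cv_folds=3, seed=0)
        assert np.argmax(np.abs(m.coef_)) == 2

    def test_single_class_rejected(self):
        X = np.random.default_rng(4).normal(size=(10, 3))
        with pytest.raises(ValueError):
            ElasticNetDiagnosis().fit(X, np.ones(10))

    def test_sparsity_nondecreasing_in_l1_penalty(self):
        X, y = self._cohort(seed=5)
        nz = []
        for l1 in (0.1, 0.5, 0.9, 1.0):
            m = ElasticNetDiagnosis(cv_folds=None, C=0.1, l1_ratio=l1).fit(X, y)
            nz.append(int(np.sum(np.abs(m.coef_) > 1e-10)))
        assert all(a >= b for a, b in zip(nz, nz[1:]))

    def test_probability_output_shape(self):
        X, y = self._cohort(seed=6)
        m = ElasticNetDiagnosis(cv_folds=None).fit(X, y)
        proba = m.predict_proba(X)
        assert proba.shape == (len(X), 2)
        assert np.allclose(proba.sum(axis=1), 1.0)


class TestOPLSDA:
    def _data(self, seed=0):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(50, 10))
        y = (X[:, 0] - X[:, 1] + rng.normal(size=50) * 0.8 > 0).astype(int)
        if y.min() == y.max():
            y[0] = 1 - y[0]
        return X, y

    def test_orthogonal_scores_uncorrelated_with_labels(self):
        X, y = self._data(7)
        m = fit_oplsda(X, y, n_orthogonal=2)
        scores = m.orthogonal_scores(X)
        yc = y - y.mean()
        for k in range(scores.shape[1]):
            r = scores[:, k] @ yc / (np.linalg.norm(scores[:, k]) * np.linalg.norm(yc))
            assert abs(r) < 1e-6

    def test_zero_orthogonal_reduces_to_pls_component(self):
        X, y = self._data(8)
        m = OPLSDA(n_orthogonal=0).fit(X, y)
        Xc = (X - X.mean(0)) / X.std(0, ddof=1)
        w = Xc.T @ (y - y.mean())
        w /= np.linalg.norm(w)
        assert np.allclose(np.abs(m.weights_), np.abs(w), atol=1e-10)

    def test_excessive_orthogonal_components_rejected(self):
        X = np.random.default_rng(9).normal(size=(12, 4))
        y = np.r_[np.ones(6), np.zeros(6)].astype(int)
        with pytest.raises(ValueError):
            OPLSDA(n_orthogonal=4).fit(X, y)


class TestCrossValidate:
    def test_fold_partition_arithmetic(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(160, 8))
        y = np.r_[np.ones(80), np.zeros(80)].astype(int)
        res = cross_validate(X, y, k=5, seed=0,
                             estimator=ElasticNetDiagnosis(cv_folds=None),
                             ci_bootstraps=0)
        assert len(res["folds"]) == 5
        assert len(res["oof_probs"]) == 160

    def test_duplicated_rows_leave_pooled_auc_stable(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(60, 6))
        y = (X[:, 0] + rng.normal(size=60) * 0.5 > 0).astype(int)
        est = ElasticNetDiagnosis(cv_folds=None)
        a = cross_validate(X, y, k=3, seed=0, estimator=est, ci_bootstraps=0)
        Xd, yd = np.vstack([X, X]), np.r_[y, y]
        b = cross_validate(Xd, yd, k=3, seed=0, estimator=est, ci_bootstraps=0)
        assert abs(a["pooled"].auc - b["pooled"].auc) < 0.05

    def test_k_exceeding_class_size_rejected(self):
        X = np.random.default_rng(12).normal(size=(10, 3))
        y = np.r_[np.ones(3), np.zeros(7)].astype(int)
        with pytest.raises(ValueError):
            cross_validate(X, y, k=5)


class TestPermutationTest:
    def test_informative_cohort_low_p(self):
        rng = np.random.default_rng(13)
        X = rng.normal(size=(50, 10))
        y = (X[:, 0] * 3 + rng.normal(size=50) > 0).astype(int)
        res = permutation_test(X, y, n_perm=49, seed=0)
        assert res["p_value"] <= 0.05

    def test_p_is_one_when_no_null_beats_observed(self):
        # constant features: the observed and every permuted AUC are exactly
        # 0.5, so the counting formula must return p = 1.0 exactly
        y = np.r_[np.ones(15), np.zeros(15)].astype(int)
        X = np.ones((30, 3))
        res = permutation_test(X, y, n_perm=19, seed=1)
        assert res["p_value"] == 1.0
        assert np.all(res["null_auc"] >= res["observed_auc"])

    def test_p_value_matches_counting_formula(self):
        rng = np.random.default_rng(20)
        X = rng.normal(size=(30, 5))
        y = (X[:, 0] + rng.normal(size=30) > 0).astype(int)
        res = permutation_test(X, y, n_perm=19, seed=2)
        expected = (1 + np.sum(res["null_auc"] >= res["observed_auc"])) / 20
        assert res["p_value"] == pytest.approx(expected)

    def test_minimum_permutations_enforced(self):
        with pytest.raises(ValueError):
            permutation_test(np.ones((10, 2)), np.r_[np.ones(5), np.zeros(5)],
                             n_perm=5)


class TestScreenAndEnsemble:
    def test_screen_threshold_boundaries(self):
        rng = np.random.default_rng(15)
        n = 40
        y = np.r_[np.ones(20), np.zeros(20)].astype(int)
        base = rng.normal(30, 1.0, size=(n, 2))
        base[y == 1, 0] += 8.0  # strongly separating, mean > 25
        base[y == 1, 1] += 8.0
        hits = np.array([75, 60])
        rep = screen_biomarkers(base, y, np.array([150.0, 200.0]), hits,
                                n_models=100)
        assert bool(rep.loc[0, "passes_screen"]) is True   # 75 > 60
        assert bool(rep.loc[1, "passes_screen"]) is False  # 60 is not > 60

    def test_screen_intensity_restriction(self):
        rng = np.random.default_rng(16)
        y = np.r_[np.ones(20), np.zeros(20)].astype(int)
        low = rng.normal(5, 0.5, size=(40, 1))
        low[y == 1] += 3.0  # significant but dim
        rep = screen_biomarkers(low, y, np.array([100.0]), np.array([90]),
                                n_models=100)
        assert not rep["passes_screen"].any()

    def test_zero_variance_feature_flagged(self):
        y = np.r_[np.ones(5), np.zeros(5)].astype(int)
        X = np.full((10, 1), 30.0)
        rep = screen_biomarkers(X, y, np.array([100.0]), np.array([100]),
                                n_models=100)
        assert bool(rep.loc[0, "zero_variance_flag"])
        assert rep.loc[0, "p_value"] == 1.0

    def test_replicate_probabilities_validation(self):
        with pytest.raises(ValueError):
            ReplicateProbabilities(np.zeros((3, 1)), np.zeros((2, 1)))
        with pytest.raises(ValueError):
            ReplicateProbabilities(np.full((3, 3), 1.5), np.zeros((2, 3)))

    def test_replicate_ensemble_shapes(self):
        rng = np.random.default_rng(17)
        n_samples, reps, p = 12, 3, 8
        rows = n_samples * reps
        sample_ids = [f"s{i}" for i in range(n_samples) for _ in range(reps)]
        y_ind = np.r_[np.ones(6), np.zeros(6)].astype(int)
        labels = np.repeat(y_ind, reps)
        X = rng.normal(10, 1, size=(rows, p))
        X[labels == 1, 0] += 4
        ens = replicate_ensemble(X, labels, sample_ids, n_models=5, seed=0)
        rp = ens["probabilities"]
        assert rp.n_models == 5
        assert rp.control_probs.shape[0] + rp.patient_probs.shape[0] == n_samples
        assert len(ens["hit_counts"]) == p
        assert ens["auc_per_model"].shape == (5,)
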