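"""DVC/MK surface: thresholds, CV statistic, surface assembly, VUS."""

import numpy as np
import pytest

from ldims.diagnosis import ReplicateProbabilities
from ldims.mk import (MKSurface, build_surface, cv_stat, labels_and_performance,
                      percentile_threshold, select_threshold, vus)


def brute_force_surface(control, patient):
    """Direct loop-based re-derivation of every surface row (oracle)."""
    n_models = control.shape[1]
    rows = []
    for n in range(1, 101):
        thr = [np.percentile(control[:, m], n) for m in range(n_models)]
        labels = np.array([[patient[i, m] > thr[m] for m in range(n_models)]
                           for i in range(patient.shape[0])])
        sens = labels.mean(axis=0)
        spec = np.mean([[control[i, m] <= thr[m] for m in range(n_models)]
                        for i in range(control.shape[0])])
        cvs = []
        for row in labels.astype(float):
            mu = row.mean()
            cvs.append(0.0 if mu == 0 else row.std(ddof=1) / mu)
        rows.append((np.mean(thr), spec, sens.mean(), np.mean(cvs)))
    return rows


def brute_force_vus(surface):
    """Riemann/trapezoid sum computed by explicit loop."""
    order = np.argsort(surface.specificity, kind="stable")
    sp = surface.specificity[order]
    z = surface.cv[order] * surface.mean_sensitivity[order]
    total = 0.0
    for i in range(len(sp) - 1):
        total += 0.5 * (z[i] + z[i + 1]) * (sp[i + 1] - sp[i])
    return total


def _probs(seed=0, nc=6, np_=5, nm=4):
    rng = np.random.default_rng(seed)
    return ReplicateProbabilities(rng.random((nc, nm)),
                                  np.clip(rng.random((np_, nm)) + 0.2, 0, 1))


class TestPercentileThreshold:
    def test_linear_interpolation_oracle(self):
        v = np.arange(0.1, 1.01, 0.1)
        assert percentile_threshold(v, 50) == pytest.approx(0.55)

    def test_hundredth_percentile_is_max(self):
        v = np.random.default_rng(0).random(17)
        assert percentile_threshold(v, 100) == v.max()

    def test_constant_controls(self):
        for n in (1, 37, 100):
            assert percentile_threshold(np.full(9, 0.4), n) == 0.4

    def test_range_validation(self):
        with pytest.raises(ValueError):
            percentile_threshold(np.array([0.5]), 0)
        with pytest.raises(ValueError):
            percentile_threshold(np.array([]), 50)


class TestCvStat:
    def test_constant_vector_zero(self):
        assert cv_stat([1, 1, 1, 1]) == 0.0

    def test_hand_arithmetic(self):
        assert cv_stat([8, 12]) == pytest.approx(np.std([8, 12], ddof=1) / 10)
        assert cv_stat([8, 12]) == pytest.approx(0.2828427, abs=1e-6)

    def test_all_zero_convention(self):
        assert cv_stat([0.0, 0.0, 0.0]) == 0.0

    def test_zero_mean_with_spread_undefined(self):
        with pytest.raises(ValueError):
            cv_stat([-1.0, 1.0])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            cv_stat([])


class TestLabelsAndPerformance:
    def test_separable_cohort(self):
        rp = ReplicateProbabilities(np.zeros((5, 3)), np.ones((4, 3)))
        sens, spec, labels = labels_and_performance(rp, 50)
        assert np.all(sens == 1.0) and spec == 1.0
        assert labels.all()

    def test_identical_model_columns_constant_sensitivity(self):
        rng = np.random.default_rng(1)
        c = np.tile(rng.random((5, 1)), (1, 4))
        p = np.tile(rng.random((6, 1)), (1, 4))
        sens, _, _ = labels_and_performance(ReplicateProbabilities(c, p), 30)
        assert np.all(sens == sens[0])

    def test_tiny_instance_matches_enumeration(self):
        rp = _probs(seed=2, nc=5, np_=4, nm=3)
        for n in (1, 37, 80, 100):
            sens, spec, labels = labels_and_performance(rp, n)
            thr = [np.percentile(rp.control_probs[:, m], n) for m in range(3)]
            expected = np.array([[rp.patient_probs[i, m] > thr[m]
                                  for m in range(3)] for i in range(4)])
            assert np.array_equal(labels, expected)


class TestBuildSurfaceAndVus:
    def test_deterministic_ensemble_gives_zero_cv_and_vus(self):
        rng = np.random.default_rng(3)
        c = np.tile(rng.random((6, 1)), (1, 5))
        p = np.tile(rng.random((5, 1)), (1, 5))
        surf = build_surface(ReplicateProbabilities(c, p))
        assert np.allclose(surf.cv, 0.0)
        assert vus(surf) == 0.0

    def test_matches_brute_force_enumeration(self):
        for seed in range(3):
            rp = _probs(seed=seed)
            surf = build_surface(rp)
            oracle = brute_force_surface(rp.control_probs, rp.patient_probs)
            for k, (thr, spec, sens, cv) in enumerate(oracle):
                assert surf.thresholds[k] == pytest.approx(thr, abs=1e-12)
                assert surf.specificity[k] == pytest.approx(spec, abs=1e-12)
                assert surf.mean_sensitivity[k] == pytest.approx(sens, abs=1e-12)
                assert surf.cv[k] == pytest.approx(cv, abs=1e-12)
            assert vus(surf) == pytest.approx(brute_force_vus(surf), abs=1e-12)

    def test_thresholds_and_specificity_monotone(self):
        surf = build_surface(_probs(seed=5, nc=30, np_=20, nm=6))
        assert np.all(np.diff(surf.thresholds) >= -1e-12)
        assert np.all(np.diff(surf.specificity) >= -1e-12)

    def test_uniform_patients_sensitivity_expectation(self):
        rng = np.random.default_rng(6)
        rp = ReplicateProbabilities(rng.random((300, 4)), rng.random((400, 4)))
        surf = build_surface(rp)
        for n in (10, 50, 90):
            assert surf.mean_sensitivity[n - 1] == pytest.approx(1 - n / 100,
                                                                 abs=0.05)

    def test_vus_invariant_to_orderings(self):
        rp = _probs(seed=7, nc=8, np_=7, nm=5)
        base = vus(build_surface(rp))
        rng = np.random.default_rng(8)
        perm_p = rng.permutation(rp.patient_probs.shape[0])
        perm_m = rng.permutation(rp.n_models)
        shuffled = ReplicateProbabilities(rp.control_probs[:, perm_m],
                                          rp.patient_probs[perm_p][:, perm_m])
        assert vus(build_surface(shuffled)) == pytest.approx(base, abs=1e-12)

    def test_rectangle_closed_form(self):
        ns = np.arange(1, 101)
        surf = MKSurface(ns, np.linspace(0, 1, 100), np.linspace(0, 1, 100),
                         np.ones(100), np.ones((100, 2)), np.full(100, 0.37))
        assert vus(surf) == pytest.approx(0.37)

    def test_model_sensitivity_cv_mode(self):
        surf = build_surface(_probs(seed=9, nc=10, np_=8, nm=5),
                             cv_mode="model_sensitivity")
        assert surf.cv_mode == "model_sensitivity"
        assert np.all(surf.cv >= 0)


class TestSelectThreshold:
    def _surface(self, cv):
        ns = np.arange(1, 101)
        return MKSurface(ns, np.linspace(0.1, 0.9, 100), ns / 100.0,
                         1 - ns / 200.0, np.ones((100, 2)), np.asarray(cv))

    def test_zero_cv_selects_top_percentile(self):
        sel = select_threshold(self._surface(np.zeros(100)))
        assert sel[0] == 100

    def test_linear_cv_arithmetic(self):
        sel = select_threshold(self._surface(np.arange(1, 101) / 100.0))
        assert sel[0] == 9  # largest n with n/100 < 0.10

    def test_no_qualifying_threshold(self):
        assert select_threshold(self._surface(np.full(100, 0.5))) is None
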