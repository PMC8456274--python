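"""Peak extraction, S/N filtering and cross-spectrum alignment."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ldims.preprocessing import (Peak, PeakList, align_features, detect_peaks,
                                 estimate_snr, extract_smp, filter_by_snr,
                                 SNR_CAP)
from ldims.simulate import Spectrum, simulate_spectrum


def brute_force_peaks(x, w):
    """Exhaustive O(n*w) strict-window-maximum scan (independent oracle)."""
    half = w // 2
    med = np.median(x)
    out = []
    for i in range(half, len(x) - half):
        window = x[i - half:i + half + 1]
        if x[i] > med and np.sum(window == x[i]) == 1 and x[i] == window.max():
            out.append(i)
    return out


def _spec(x):
    return Spectrum(np.arange(len(x), dtype=float) + 100.0, np.asarray(x, float))


class TestDetectPeaks:
    def test_matches_exhaustive_scan_on_random_spectra(self):
        rng = np.random.default_rng(0)
        for w in (3, 5, 7):
            for _ in range(5):
                x = rng.gamma(2.0, 1.0, size=400)
                got = [p.index for p in detect_peaks(_spec(x), w).peaks]
                assert got == brute_force_peaks(x, w)

    def test_constant_spectrum_has_no_peaks(self):
        assert len(detect_peaks(_spec(np.full(100, 3.0)))) == 0

    def test_noise_free_planted_peaks_found_exactly(self, panel, quiet_acq, cohort):
        s = cohort.samples[0]
        sp = simulate_spectrum(s, panel, quiet_acq, 1, seed=0)
        pl = detect_peaks(sp)
        assert len(pl) == panel.n_features
        grid_step = sp.mz[1] - sp.mz[0]
        for mz_peak, mz_true in zip(pl.mz, panel.mz):
            assert abs(mz_peak - mz_true) <= grid_step

    @pytest.mark.parametrize("w", [2, 1, 4])
    def test_invalid_window_raises(self, w):
        with pytest.raises(ValueError):
            detect_peaks(_spec(np.ones(50)), w)

    def test_window_larger_than_spectrum_raises(self):
        with pytest.raises(ValueError):
            detect_peaks(_spec(np.ones(5)), 7)


class TestEstimateSnr:
    def test_snr_formula_on_constructed_background(self):
        rng = np.random.default_rng(1)
        x = rng.normal(100.0, 30.0, size=5000)  # positive background
        x[2500] = x.max() + 300.0  # unambiguous apex
        sp = Spectrum(np.linspace(100, 600, 5000), np.maximum(x, 0.0))
        pl = detect_peaks(sp)
        pl = estimate_snr(sp, pl)
        apex = max(pl.peaks, key=lambda p: p.apex_intensity)
        expected = (apex.apex_intensity - 100.0) / 30.0
        assert expected * 0.8 < apex.snr < expected * 1.25

    def test_zero_noise_gives_capped_sentinel(self, panel, quiet_acq, cohort):
        sp = simulate_spectrum(cohort.samples[0], panel, quiet_acq, 1, seed=0)
        pl = estimate_snr(sp, detect_peaks(sp))
        assert all(p.snr == SNR_CAP for p in pl.peaks)

    def test_noise_reference_overrides_noise_floor(self, panel, quiet_acq, cohort):
        # judging a denoised spectrum against a noisy reference floor must
        # lower every S/N value relative to its own (zero) floor
        clean = simulate_spectrum(cohort.samples[0], panel, quiet_acq, 1, seed=0)
        rng = np.random.default_rng(3)
        noisy = Spectrum(clean.mz, np.maximum(
            clean.intensity + rng.normal(0, 2.0, len(clean)), 0))
        pl = detect_peaks(clean)
        snr_ref = estimate_snr(clean, pl, noise_reference=noisy)
        assert all(p.snr < SNR_CAP for p in snr_ref.peaks)
        assert all(p.snr > 3 for p in snr_ref.peaks)  # planted peaks survive


class TestFilterBySnr:
    def test_strict_boundary_at_threshold(self):
        pl = PeakList(tuple(Peak(100 + i, 10.0, s)
                            for i, s in enumerate([2.9, 3.0, 3.1])))
        kept = filter_by_snr(pl, 3.0)
        assert [p.snr for p in kept.peaks] == [3.1]

    def test_empty_input(self):
        assert len(filter_by_snr(PeakList(()))) == 0

    def test_constructed_survivor_count(self):
        rng = np.random.default_rng(2)
        snrs = np.concatenate([rng.uniform(3.01, 50, 40), rng.uniform(0, 2.99, 55)])
        pl = PeakList(tuple(Peak(100 + i, 1.0, s) for i, s in enumerate(snrs)))
        assert len(filter_by_snr(pl, 3.0)) == 40

    @given(st.lists(st.floats(0, 20), min_size=0, max_size=40),
           st.floats(0, 10), st.floats(0, 10))
    @settings(max_examples=50, deadline=None)
    def test_raising_threshold_never_keeps_more(self, snrs, t1, t2):
        lo, hi = min(t1, t2), max(t1, t2)
        pl = PeakList(tuple(Peak(100 + i, 1.0, s) for i, s in enumerate(snrs)))
        assert len(filter_by_snr(pl, hi)) <= len(filter_by_snr(pl, lo))


class TestAlignFeatures:
    def _pl(self, entries, sid="s", rid="r"):
        return PeakList(tuple(Peak(mz, v, 10.0) for mz, v in entries), sid, rid)

    def test_merge_within_tolerance(self):
        fm = align_features([self._pl([(204.10, 5.0)], "a"),
                             self._pl([(204.12, 6.0)], "b")], 0.1)
        assert fm.n_features == 1
        assert fm.values.shape == (2, 1)
        assert np.all(fm.values > 0)

    def test_split_beyond_tolerance(self):
        fm = align_features([self._pl([(204.10, 5.0)], "a"),
                             self._pl([(204.12, 6.0)], "b")], 0.01,
                            min_fraction=0.0)
        assert fm.n_features == 2

    def test_jittered_panel_recovered(self, panel):
        rng = np.random.default_rng(4)
        pls = [self._pl([(mz + rng.normal(0, 0.02), 10 + rng.random())
                         for mz in panel.mz], f"s{i}") for i in range(20)]
        fm = align_features(pls, 0.1)
        assert fm.n_features == panel.n_features
        assert np.all(fm.values > 0)  # present in every row

    def test_order_invariance(self, panel):
        rng = np.random.default_rng(5)
        pls = [self._pl([(mz + rng.normal(0, 0.02), 10.0) for mz in panel.mz],
                        f"s{i}") for i in range(8)]
        fm1 = align_features(pls, 0.1)
        fm2 = align_features(pls[::-1], 0.1)
        assert np.allclose(np.sort(fm1.feature_mz), np.sort(fm2.feature_mz))

    def test_invalid_tolerance(self):
        with pytest.raises(ValueError):
            align_features([self._pl([(100.0, 1.0)])], 0.0)

    def test_empty_input(self):
        with pytest.raises(ValueError):
            align_features([], 0.1)


class TestExtractSmp:
    def test_end_to_end_recovery_on_default_config(self, panel):
        from ldims.simulate import AcquisitionConfig, sample_cohort

        acq = AcquisitionConfig()
        coh = sample_cohort(panel, 3, 3, 0.2, seed=17)
        spectra = [simulate_spectrum(s, panel, acq, 1000, seed=60 + i)
                   for i, s in enumerate(coh.samples)]
        fm = extract_smp(spectra, labels=coh.labels)
        recovered = sum(np.min(np.abs(fm.feature_mz - mz)) < 0.2
                        for mz in panel.mz)
        assert recovered == panel.n_features

    def test_noise_reference_length_mismatch(self, panel, quiet_acq, cohort):
        sp = simulate_spectrum(cohort.samples[0], panel, quiet_acq, 1, seed=0)
        with pytest.raises(ValueError):
            extract_smp([sp], noise_references=[])
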