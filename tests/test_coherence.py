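import numpy as np
import pytest

from emgsyn.coherence import (TFCMap, band_area, compute_tfc,
                              effective_segments, hamming_kernel,
                              significance_threshold, smooth2d,
                              stft_cross_spectra, summarize_cohort)
from emgsyn.synthetic import make_coupled_pair_trial


class TestStftCrossSpectra:
    def test_self_spectrum_identity(self):
        x = np.random.default_rng(0).normal(size=1000)
        Pxy, Pxx, Pyy, _, _ = stft_cross_spectra(x, x, 2000.0)
        np.testing.assert_allclose(Pxy.imag, 0.0, atol=1e-9)
        np.testing.assert_allclose(Pxy.real, Pxx, rtol=1e-12)
        np.testing.assert_allclose(Pxx, Pyy, rtol=1e-12)

    def test_segment_counting(self):
        x = np.zeros(200)
        Pxy, *_ = stft_cross_spectra(x + 1e-3, x + 1e-3, 2000.0)
        assert Pxy.shape[1] == 1
        x = np.random.default_rng(1).normal(size=2000)
        Pxy, *_ = stft_cross_spectra(x, x, 2000.0)
        assert Pxy.shape[1] == (2000 - 200) // 50 + 1 == 37

    def test_too_short_signal(self):
        with pytest.raises(ValueError):
            stft_cross_spectra(np.ones(100), np.ones(100), 2000.0)


class TestSmooth2d:
    def test_identity_kernel(self):
        X = np.random.default_rng(2).normal(size=(6, 8))
        np.testing.assert_array_equal(smooth2d(X, np.ones((1, 1))), X)

    def test_constant_input_unchanged(self):
        X = np.full((10, 10), 3.3)
        np.testing.assert_allclose(smooth2d(X, hamming_kernel(5)), 3.3,
                                   rtol=1e-12)

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(6, 6))
        K = rng.uniform(size=(3, 3))
        K /= K.sum()
        got = smooth2d(X, K)
        # four-nested-loop convolution with reflective (symmetric) boundary
        pad = np.pad(X, 1, mode="symmetric")
        expect = np.zeros_like(X)
        for i in range(6):
            for j in range(6):
                for a in range(3):
                    for b in range(3):
                        expect[i, j] += K[a, b] * pad[i + 2 - a, j + 2 - b]
        np.testing.assert_allclose(got, expect, atol=1e-12)

    def test_even_kernel_rejected(self):
        with pytest.raises(ValueError):
            smooth2d(np.ones((4, 4)), np.ones((2, 2)) / 4)


class TestSignificanceThreshold:
    def test_closed_form_values(self):
        assert significance_threshold(0.05, 2) == pytest.approx(0.95)
        assert significance_threshold(0.05, 21) == pytest.approx(
            1 - 0.05 ** (1 / 20))
        assert significance_threshold(0.05, 21) == pytest.approx(0.1391,
                                                                 abs=5e-4)

    def test_decreasing_in_segment_count(self):
        vals = [significance_threshold(0.05, L) for L in range(2, 30)]
        assert all(b < a for a, b in zip(vals, vals[1:]))

    def test_too_few_segments(self):
        with pytest.raises(ValueError):
            significance_threshold(0.05, 1)

    def test_calibrated_effective_segments_cached_and_sane(self):
        L1 = effective_segments()
        L2 = effective_segments()
        assert L1 == L2 >= 2.0


class TestComputeTfc:
    def test_self_coherence_is_one(self):
        x = np.random.default_rng(4).normal(size=3000)
        tfc = compute_tfc(x, x, 2000.0)
        defined = np.isfinite(tfc.coherence)
        np.testing.assert_allclose(tfc.coherence[defined], 1.0, atol=1e-9)

    def test_range_and_symmetry(self):
        rng = np.random.default_rng(5)
        x, y = rng.normal(size=3000), rng.normal(size=3000)
        a = compute_tfc(x, y, 2000.0).coherence
        b = compute_tfc(y, x, 2000.0).coherence
        assert np.nanmin(a) >= 0 and np.nanmax(a) <= 1
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_scaling_invariance(self):
        rng = np.random.default_rng(6)
        x, y = rng.normal(size=3000), rng.normal(size=3000)
        a = compute_tfc(x, y, 2000.0).coherence
        b = compute_tfc(3.7 * x, 0.2 * y, 2000.0).coherence
        np.testing.assert_allclose(a, b, atol=1e-9)

    def test_single_segment_identity_kernel_is_degenerate_one(self):
        # the regression motivating the smoothing requirement
        rng = np.random.default_rng(7)
        x, y = rng.normal(size=200), rng.normal(size=200)
        Pxy, Pxx, Pyy, _, _ = stft_cross_spectra(x, y, 2000.0)
        ident = np.ones((1, 1))
        coh = np.abs(smooth2d(Pxy, ident)) ** 2 / (
            smooth2d(Pxx, ident) * smooth2d(Pyy, ident))
        np.testing.assert_allclose(coh, 1.0, atol=1e-9)

    def test_zero_power_flagged(self):
        with pytest.raises(ValueError):
            compute_tfc(np.zeros(1000), np.zeros(1000), 2000.0)


class TestBandArea:
    def _map(self, coherence, freqs, thr=0.5):
        c = np.asarray(coherence, float)
        return TFCMap(pair=("A", "B"), times=np.arange(c.shape[1]),
                      freqs=np.asarray(freqs, float), coherence=c,
                      sig_threshold=thr)

    def test_full_and_empty_maps(self):
        freqs = np.linspace(0, 100, 26)
        ones = self._map(np.ones((26, 5)), freqs)
        zeros = self._map(np.zeros((26, 5)), freqs)
        for band in ("alpha", "beta", "gamma"):
            assert band_area(ones, band).az == 1.0
            assert band_area(zeros, band).az == 0.0

    def test_counting_oracle(self):
        # beta rows: freqs 20 and 25 Hz -> 2 x 4 = 8 bins; 3 above threshold
        freqs = [10.0, 20.0, 25.0, 40.0]
        c = np.zeros((4, 4))
        c[1, 0] = c[1, 2] = c[2, 3] = 0.9
        bs = band_area(self._map(c, freqs), "beta")
        assert bs.az == pytest.approx(3 / 8)

    def test_band_edges_half_open(self):
        # 15 Hz belongs to beta, 30 Hz to gamma: no double counting
        freqs = [15.0, 30.0]
        m = self._map(np.ones((2, 3)), freqs)
        assert band_area(m, "beta").az == 1.0        # only the 15 Hz row
        with pytest.raises(ValueError):
            band_area(m, "alpha")                    # no bins in [8, 15)


def test_summarize_cohort_rows_and_determinism(basic_trial):
    trials = [{"recording": basic_trial.recording,
               "events": basic_trial.events,
               "subject": "sub01", "group": "SG"}]
    pairs = [("BB", "LD"), ("DEL", "ABS")]
    t1 = summarize_cohort(trials, pairs)
    t2 = summarize_cohort(trials, pairs)
    assert len(t1) == len(pairs) * 3
    assert t1.equals(t2)
    assert set(t1.columns) >= {"subject", "group", "pair", "band", "az"}


def test_planted_beta_drive_detected(basic_trial):
    tr = make_coupled_pair_trial(("BB", "LD"), "beta", 0.8, seed=21)
    tfc = compute_tfc(
        *(np.asarray(v) for v in _pair_envs(tr)), tr.recording.fs,
        pair=("BB", "LD"))
    means = {b: band_area(tfc, b).mean_coh for b in ("alpha", "beta",
                                                     "gamma")}
    assert means["beta"] > means["alpha"]
    assert means["beta"] > means["gamma"]


def _pair_envs(trial):
    from emgsyn.preprocessing import coherence_input

    env = coherence_input(trial.recording, trial.events)
    return env.channel("BB"), env.channel("LD")
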