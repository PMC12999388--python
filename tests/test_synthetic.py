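import numpy as np
import pytest
from scipy.signal import periodogram
from scipy.stats import spearmanr

from emgsyn.io import MUSCLES
from emgsyn.synergy import compute_vaf
from emgsyn.synthetic import (GroundTruth, GroupSpec, generate_cohort,
                              inject_common_drive, make_activations,
                              make_trial, make_weights, synthesize_envelope,
                              synthesize_raw_emg)


class TestMakeWeights:
    def test_rows_max_normalized(self):
        W = make_weights(14, 4, 3, seed=1)
        assert W.shape == (4, 14)
        np.testing.assert_allclose(W.max(axis=1), 1.0)
        assert (W >= 0).all()

    def test_minimal_case_structure(self):
        W = make_weights(2, 1, 1, seed=7)
        assert W.shape == (1, 2)
        assert np.isclose(W.max(), 1.0)
        assert np.sort(W[0])[0] <= 0.15

    def test_pairwise_cosine_bounded(self):
        W = make_weights(14, 5, 3, seed=3)
        for a in range(5):
            for b in range(a + 1, 5):
                cos = W[a] @ W[b] / (np.linalg.norm(W[a])
                                     * np.linalg.norm(W[b]))
                assert cos < 0.9

    def test_degenerate_request_errors(self):
        with pytest.raises(RuntimeError):
            make_weights(2, 2, 2, seed=0)
        with pytest.raises(ValueError):
            make_weights(3, 4, 2, seed=0)

    def test_determinism(self):
        np.testing.assert_array_equal(make_weights(14, 3, 3, 11),
                                      make_weights(14, 3, 3, 11))

    def test_exclude_dominant(self):
        W = make_weights(14, 4, 3, seed=2, exclude_dominant=[0, 5])
        assert W[:, 0].max() <= 0.15
        assert W[:, 5].max() <= 0.15


class TestMakeActivations:
    def test_peak_at_center(self):
        C = make_activations(1, 100, [0.5], [0.1])
        assert np.argmax(C[0]) == 50
        assert C[0, 50] == 1.0

    def test_two_bumps_argmax(self):
        C = make_activations(2, 100, [0.2, 0.8], [0.05, 0.05])
        assert np.argmax(C[0]) == 20 and np.argmax(C[1]) == 80

    def test_row_sums_match_formula_oracle(self):
        C = make_activations(3, 100, [0.25, 0.5, 0.75], [0.08] * 3)
        t = np.arange(100) / 100
        for i, c in enumerate([0.25, 0.5, 0.75]):
            expected = sum(np.exp(-(tj - c) ** 2 / (2 * 0.08 ** 2))
                           for tj in t)
            assert abs(C[i].sum() - expected) < 1e-9

    def test_baseline_and_nonnegative(self):
        C = make_activations(1, 50, [0.5], [0.1], baseline=0.1)
        assert (C >= 0.1).all() and np.isclose(C.max(), 1.1)


class TestSynthesizeEnvelope:
    def test_rank_one_identity(self):
        truth = GroundTruth(weights_true=np.array([[1.0, 0.0]]),
                            activations_true=np.ones((1, 10)))
        D = synthesize_envelope(truth)
        np.testing.assert_array_equal(D[0], 1.0)
        np.testing.assert_array_equal(D[1], 0.0)

    def test_noise_free_vaf_is_exactly_one(self):
        W = make_weights(14, 3, 3, 2)
        C = make_activations(3, 100, [0.2, 0.5, 0.8], [0.05] * 3)
        D = synthesize_envelope(GroundTruth(weights_true=W,
                                            activations_true=C))
        assert compute_vaf(D, W, C) == 1.0

    def test_matches_loop_oracle_with_seeded_noise(self):
        W = make_weights(14, 3, 3, 11)
        C = make_activations(3, 100, [0.2, 0.5, 0.8], [0.05] * 3)
        truth = GroundTruth(weights_true=W, activations_true=C,
                            noise_sd=0.05, seed=11)
        D = synthesize_envelope(truth)
        expected = np.zeros((14, 100))
        for m in range(14):
            for t in range(100):
                for i in range(3):
                    expected[m, t] += C[i, t] * W[i, m]
        noise = np.random.default_rng(11).normal(0, 0.05, size=(14, 100))
        np.testing.assert_allclose(D, np.clip(expected + noise, 0, None),
                                   atol=1e-12)


class TestSynthesizeRawEMG:
    def test_zero_envelope_zero_output(self):
        rec = synthesize_raw_emg(np.zeros((1, 100)), seed=0)
        assert np.all(rec.data == 0)

    def test_band_power_containment(self):
        rec = synthesize_raw_emg(np.ones((1, 100)), seed=4)
        f, P = periodogram(rec.data[0], fs=2000.0)
        inband = P[(f >= 20) & (f <= 400)].sum()
        assert inband / P.sum() > 0.95

    def test_ramp_envelope_tracked_by_windowed_rms(self):
        ramp = np.linspace(0, 1, 100)[None, :]
        rec = synthesize_raw_emg(ramp, seed=9)
        x = rec.data[0] ** 2
        win = 100
        rms = np.sqrt(np.convolve(x, np.ones(win) / win, mode="valid"))
        smooth = np.convolve(rms, np.ones(200) / 200, mode="valid")
        rho = spearmanr(smooth, np.arange(len(smooth))).statistic
        assert rho > 0.95

    def test_invalid_carrier_band(self):
        with pytest.raises(ValueError):
            synthesize_raw_emg(np.ones((1, 10)), fs=2000.0, carrier_low=20,
                               carrier_high=1100)


class TestInjectCommonDrive:
    def test_zero_coupling_is_identity(self, basic_trial):
        rec = basic_trial.recording
        out = inject_common_drive(rec, ("GM", "PM"), "beta", 0.0, seed=1)
        np.testing.assert_array_equal(out.data, rec.data)

    def test_untouched_channels_bitwise_identical(self, basic_trial):
        rec = basic_trial.recording
        out = inject_common_drive(rec, ("GM", "PM"), "beta", 0.8, seed=1)
        np.testing.assert_array_equal(out.channel("DEL"), rec.channel("DEL"))
        assert not np.array_equal(out.channel("GM"), rec.channel("GM"))

    def test_bad_inputs(self, basic_trial):
        rec = basic_trial.recording
        with pytest.raises(KeyError):
            inject_common_drive(rec, ("GM", "XX"), "beta", 0.5)
        with pytest.raises(ValueError):
            inject_common_drive(rec, ("GM", "PM"), "delta", 0.5)
        with pytest.raises(ValueError):
            inject_common_drive(rec, ("GM", "PM"), "beta", 1.5)


class TestGenerateCohort:
    def test_manifest_counts_and_determinism(self, tmp_path):
        a, b = tmp_path / "a", tmp_path / "b"
        groups = [GroupSpec("SG", 3), GroupSpec("ESG", 2)]
        m1 = generate_cohort(a, n_subjects=2, groups=groups,
                             trials_per_subject=2, seed=5)
        m2 = generate_cohort(b, n_subjects=2, groups=groups,
                             trials_per_subject=2, seed=5)
        assert len(m1["trials"]) == 2 * 2 * 2
        for f1 in sorted(a.iterdir()):
            f2 = b / f1.name
            assert f1.read_bytes() == f2.read_bytes(), f1.name

    def test_trial_channels_are_standard_montage(self, tmp_path):
        from emgsyn.io import read_trial

        m = generate_cohort(tmp_path, n_subjects=1, trials_per_subject=1,
                            seed=3)
        rec = read_trial(tmp_path / m["trials"][0]["path"])
        assert rec.channels == list(MUSCLES)


def test_make_trial_events_strictly_increasing(basic_trial):
    ev = basic_trial.events.as_tuple()
    assert all(b > a for a, b in zip(ev, ev[1:]))
    assert ev[-1] <= basic_trial.recording.n_samples - 1
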