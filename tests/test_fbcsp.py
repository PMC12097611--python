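"""Filter bank construction and common-spatial-pattern identities."""

import numpy as np
import pytest
import scipy.linalg
from hypothesis import given, strategies as st

from neurofuse.containers import TrialTensor
from neurofuse.fbcsp import (
    apply_filter_bank,
    build_filter_bank,
    class_mean_covariance,
    csp_log_variance,
    fbcsp_fit,
    fbcsp_transform,
    fit_csp,
    trial_covariance,
)


def _random_spd_pair(rng, n):
    A = rng.standard_normal((n, n))
    B = rng.standard_normal((n, n))
    sp = A @ A.T + 1e-3 * np.eye(n)
    sn = B @ B.T + 1e-3 * np.eye(n)
    return sp / np.trace(sp), sn / np.trace(sn)


class TestFilterBank:
    @pytest.mark.parametrize(
        "args, expected",
        [
            ((2.0, 60.0, 9, 6.5), [(2.0, 8.5), (54.0, 60.0)]),  # first/last, clipped
            ((1.0, 9.0, 2, 4.0), [(1.0, 5.0), (5.0, 9.0)]),
        ],
    )
    def test_band_edges(self, args, expected):
        spec = build_filter_bank(*args)
        assert spec.n_bands == args[2]
        assert spec.band_edges[0] == expected[0]
        assert spec.band_edges[-1] == expected[-1]

    def test_degenerate_band_count_rejected(self):
        with pytest.raises(ValueError):
            build_filter_bank(2.0, 60.0, 0, 6.5)

    def test_tone_passes_matching_band_only(self):
        fs = 256.0
        t = np.arange(int(fs * 4)) / fs
        tone = np.sin(2 * np.pi * 10 * t)
        trials = TrialTensor(np.tile(tone, (1, 2, 1)), fs=fs)
        spec = build_filter_bank(8.5, 34.5, 4, 6.5)
        out = apply_filter_bank(trials, spec)
        p_in = out[0].data[0, 0].var()  # [8.5, 15] contains 10 Hz
        p_out = out[-1].data[0, 0].var()  # [28, 34.5] does not
        assert p_in >= 0.9 * tone.var()
        assert p_out <= 0.01 * tone.var()

    def test_zero_signal_and_shapes(self, small_bank):
        trials = TrialTensor(np.zeros((3, 2, 256)), fs=128.0)
        out = apply_filter_bank(trials, small_bank)
        assert len(out) == small_bank.n_bands
        for tensor in out:
            assert tensor.data.shape == trials.data.shape
            assert np.allclose(tensor.data, 0.0)

    def test_band_above_nyquist_rejected(self):
        trials = TrialTensor(np.random.default_rng(0).standard_normal((1, 2, 64)), fs=32.0)
        spec = build_filter_bank(2.0, 30.0, 4, 7.0)
        with pytest.raises(ValueError, match="Nyquist"):
            apply_filter_bank(trials, spec)


class TestTrialCovariance:
    def test_hand_computed_example(self):
        C = trial_covariance(np.array([[1.0, 1.0], [1.0, -1.0]]))
        assert np.allclose(C, [[0.5, 0.0], [0.0, 0.5]])

    def test_zero_trial_rejected(self):
        with pytest.raises(ValueError, match="zero-trace"):
            trial_covariance(np.zeros((2, 10)))

    @given(st.integers(0, 1000), st.floats(0.1, 50.0))
    def test_unit_trace_and_scale_invariance(self, seed, k):
        E = np.random.default_rng(seed).standard_normal((3, 40))
        C = trial_covariance(E)
        assert abs(np.trace(C) - 1.0) < 1e-12
        assert np.allclose(C, trial_covariance(k * E), atol=1e-12)

    def test_class_mean_is_arithmetic_mean(self):
        rng = np.random.default_rng(1)
        data = rng.standard_normal((4, 3, 50))
        labels = np.array(["a", "a", "b", "b"])
        expected = (trial_covariance(data[0]) + trial_covariance(data[1])) / 2
        got = class_mean_covariance(data, labels, "a")
        assert np.allclose(got, expected)
        single = class_mean_covariance(data[2:3], labels[2:3], "b")
        assert np.allclose(single, trial_covariance(data[2]))

    def test_absent_class_rejected(self):
        data = np.random.default_rng(0).standard_normal((2, 3, 20))
        with pytest.raises(ValueError, match="absent"):
            class_mean_covariance(data, np.array(["a", "a"]), "b")


class TestCSP:
    def test_commuting_diagonal_closed_form(self):
        m = fit_csp(np.diag([0.8, 0.2]), np.diag([0.2, 0.8]))
        assert np.allclose(m.eigvals_pos, [0.8, 0.2], atol=1e-10)
        # identity filters up to sign/permutation
        assert np.allclose(np.abs(m.W), np.eye(2), atol=1e-8)

    def test_equal_covariances_are_indiscriminate(self):
        S = _random_spd_pair(np.random.default_rng(0), 4)[0]
        m = fit_csp(S, S)
        assert np.allclose(m.eigvals_pos, 0.5, atol=1e-10)

    def test_whitening_and_complementarity_sweep(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            n = int(rng.integers(2, 7))
            sp, sn = _random_spd_pair(rng, n)
            m = fit_csp(sp, sn)
            assert np.abs(m.W.T @ (sp + sn) @ m.W - np.eye(n)).max() < 1e-8
            lam_n = np.array([w @ sn @ w for w in m.W.T])
            assert np.abs(m.eigvals_pos + lam_n - 1.0).max() < 1e-8
            assert np.all(np.diff(m.eigvals_pos) <= 1e-12)  # sorted descending

    def test_matches_explicit_whitening_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            n = int(rng.integers(2, 7))
            sp, sn = _random_spd_pair(rng, n)
            m = fit_csp(sp, sn)
            vals, U = scipy.linalg.eigh(sp + sn)
            white = U @ np.diag(vals**-0.5) @ U.T
            oracle = np.sort(scipy.linalg.eigh(white @ sp @ white.T)[0])[::-1]
            assert np.abs(m.eigvals_pos - oracle).max() < 1e-8

    def test_class_swap_symmetry(self):
        sp, sn = _random_spd_pair(np.random.default_rng(3), 5)
        m = fit_csp(sp, sn)
        swapped = fit_csp(sn, sp)
        assert np.allclose(np.sort(swapped.eigvals_pos), np.sort(1 - m.eigvals_pos), atol=1e-9)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(9)
        sp, sn = _random_spd_pair(rng, 5)
        perm = rng.permutation(5)
        P = np.eye(5)[perm]
        m = fit_csp(sp, sn)
        mp = fit_csp(P @ sp @ P.T, P @ sn @ P.T)
        assert np.allclose(mp.eigvals_pos, m.eigvals_pos, atol=1e-9)
        assert np.allclose(np.abs(mp.W), np.abs(P @ m.W), atol=1e-7)

    def test_asymmetric_input_rejected(self):
        bad = np.array([[1.0, 0.5], [0.0, 1.0]])
        with pytest.raises(ValueError, match="symmetric"):
            fit_csp(bad, np.eye(2))


class TestLogVariance:
    def test_feature_count_and_scaling(self):
        rng = np.random.default_rng(0)
        sp, sn = _random_spd_pair(rng, 6)
        m = fit_csp(sp, sn)
        E = rng.standard_normal((6, 500))
        f = csp_log_variance(E, m, 3)
        assert f.shape == (6,)
        f_scaled = csp_log_variance(7.0 * E, m, 3)
        assert np.allclose(f_scaled - f, 2 * np.log(7.0), atol=1e-10)

    def test_white_noise_through_orthonormal_filters_near_zero(self):
        rng = np.random.default_rng(1)
        m = fit_csp(np.eye(4) / 8, np.eye(4) / 8)  # W orthonormal up to scale
        W = m.W / np.linalg.norm(m.W, axis=0)
        m.W = W
        E = rng.standard_normal((4, 20000))
        f = csp_log_variance(E, m, 2)
        assert np.abs(f).max() < 0.05

    def test_too_many_pairs_rejected(self):
        m = fit_csp(np.eye(2) / 4, np.eye(2) / 4)
        with pytest.raises(ValueError, match="n_pairs"):
            csp_log_variance(np.random.default_rng(0).standard_normal((2, 50)), m, 2)


class TestFBCSP:
    def test_feature_width_is_bands_times_pairs(self, small_bank):
        rng = np.random.default_rng(5)
        trials = TrialTensor(rng.standard_normal((8, 6, 256)), fs=128.0,
                             labels=np.array(["a"] * 4 + ["b"] * 4))
        model = fbcsp_fit(trials, bank=small_bank, n_pairs=2)
        X = fbcsp_transform(trials, model)
        assert X.shape == (8, small_bank.n_bands * 4)
        # deterministic transform
        assert np.array_equal(X, fbcsp_transform(trials, model))

    def test_ssvep_band_carries_discriminative_filter(self):
        from neurofuse.synthetic import EEGSimConfig, generate_eeg_trials

        cfg = EEGSimConfig(
            n_trials_per_class=15, n_channels=8, fs=128.0, trial_len=2.0,
            paradigm="MRWG", snr_db=10.0, seed=2, classes=("mr", "wg"),
        )
        trials = generate_eeg_trials(cfg)
        bank = build_filter_bank(2.0, 30.0, 4, 7.0)
        model = fbcsp_fit(trials, bank=bank, n_pairs=2, positive_class="mr")
        # band 0 ([2, 9]) contains the 7 Hz component driven by class "mr"
        assert model.per_band[0].eigvals_pos[0] >= 0.7

    def test_channel_mismatch_rejected(self, small_bank):
        rng = np.random.default_rng(5)
        trials = TrialTensor(rng.standard_normal((6, 6, 256)), fs=128.0,
                             labels=np.array(["a"] * 3 + ["b"] * 3))
        model = fbcsp_fit(trials, bank=small_bank, n_pairs=1)
        other = TrialTensor(rng.standard_normal((2, 4, 256)), fs=128.0)
        with pytest.raises(ValueError, match="channel count"):
            fbcsp_transform(other, model)

    def test_single_class_rejected(self, small_bank):
        trials = TrialTensor(np.random.default_rng(0).standard_normal((4, 4, 256)),
                             fs=128.0, labels=np.array(["a"] * 4))
        with pytest.raises(ValueError, match="2 classes"):
            fbcsp_fit(trials, bank=small_bank)
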