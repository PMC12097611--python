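"""Evidence projection, KDE densities, fusion rule and CV engine."""

import math

import numpy as np
import pytest
import scipy.integrate
import scipy.stats
from hypothesis import given, strategies as st

from neurofuse.fusion import (
    CVConfig,
    ClassConditionalDensity,
    alpha_grid_search,
    alpha_median_test,
    fit_evidence_projector,
    fit_fusion_model,
    fuse_decide,
    kde_density,
    run_cross_validation,
    scott_bandwidth,
    signed_rank_compare,
)


class TestEvidenceProjector:
    def test_separable_data_classified_on_training_set(self):
        X = np.r_[np.full((10, 1), -2.0), np.full((10, 1), 2.0)]
        X += np.random.default_rng(0).normal(0, 0.1, X.shape)
        y = np.array(["neg"] * 10 + ["pos"] * 10)
        m = fit_evidence_projector(X, y)
        assert np.all(m.predict(X) == y)
        assert np.all((m.score(X) > 0) == (y == "pos"))

    def test_boundary_point_scores_zero(self):
        X = np.array([[-1.0], [1.0]])
        y = np.array(["a", "b"])
        m = fit_evidence_projector(X, y, regularization=1e6)
        assert abs(m.score(np.array([[0.0]]))[0]) < 1e-9

    def test_duplicating_training_points_leaves_margin_unchanged(self):
        rng = np.random.default_rng(2)
        X = np.r_[rng.normal(-2, 0.3, (12, 2)), rng.normal(2, 0.3, (12, 2))]
        y = np.array(["a"] * 12 + ["b"] * 12)
        m1 = fit_evidence_projector(X, y, regularization=1e4)
        m2 = fit_evidence_projector(np.r_[X, X], np.r_[y, y], regularization=1e4)
        assert np.allclose(m1.weights, m2.weights, atol=1e-6)
        assert math.isclose(m1.bias, m2.bias, abs_tol=1e-6)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="2 classes"):
            fit_evidence_projector(np.ones((4, 2)), np.array(["a"] * 4))


class TestScottBandwidth:
    def test_closed_form_n32(self):
        rng = np.random.default_rng(0)
        s = rng.standard_normal(32)
        s = (s - s.mean()) / s.std(ddof=1)  # exact unit sample sd
        assert math.isclose(scott_bandwidth(s), 32 ** (-0.2), rel_tol=1e-12)

    @given(st.floats(0.5, 20.0), st.integers(0, 100))
    def test_scale_equivariance(self, k, seed):
        s = np.random.default_rng(seed).standard_normal(40)
        assert math.isclose(scott_bandwidth(k * s), k * scott_bandwidth(s), rel_tol=1e-9)

    def test_sample_growth_shrinks_bandwidth(self):
        rng = np.random.default_rng(1)
        s = rng.standard_normal(100)
        s4 = np.tile(s, 4)  # same sd, 4n points (sd nearly identical)
        ratio = scott_bandwidth(s4) / scott_bandwidth(s)
        assert math.isclose(ratio, 4 ** (-0.2), rel_tol=1e-2)

    def test_zero_spread_rejected(self):
        with pytest.raises(ValueError, match="spread"):
            scott_bandwidth(np.ones(10))


class TestKDE:
    def test_single_support_point_is_gaussian(self):
        d = ClassConditionalDensity(support_points=[3.0, 3.0], bandwidth=0.7)
        x = 3.9
        expected = scipy.stats.norm.pdf(x, 3.0, 0.7)
        assert math.isclose(kde_density(d, x), expected, rel_tol=1e-9)

    def test_integrates_to_one(self):
        rng = np.random.default_rng(0)
        d = ClassConditionalDensity.fit(rng.standard_normal(50))
        lo = d.support_points.min() - 10 * d.bandwidth
        hi = d.support_points.max() + 10 * d.bandwidth
        total, _ = scipy.integrate.quad(lambda x: kde_density(d, x), lo, hi, limit=200)
        assert abs(total - 1.0) < 1e-3

    def test_symmetric_support_gives_symmetric_density(self):
        d = ClassConditionalDensity.fit(np.array([-2.0, -1.0, 1.0, 2.0]))
        for x in (0.5, 1.3, 2.7):
            assert math.isclose(kde_density(d, x), kde_density(d, -x), rel_tol=1e-12)

    def test_matches_scipy_gaussian_kde(self):
        rng = np.random.default_rng(5)
        s = rng.standard_normal(64)
        d = ClassConditionalDensity.fit(s)
        ref = scipy.stats.gaussian_kde(s, bw_method="scott")
        xs = np.linspace(-3, 3, 11)
        assert np.allclose(d.pdf(xs), ref(xs), rtol=1e-6)

    def test_far_tail_density_floored_not_zero(self):
        d = ClassConditionalDensity.fit(np.array([0.0, 0.1, -0.1, 0.05]))
        assert kde_density(d, 1e6) >= 1e-300


class TestFuseDecide:
    @staticmethod
    def _gaussian_model(alpha):
        rng = np.random.default_rng(0)
        y = np.array([0] * 200 + [1] * 200)
        e = np.where(y == 1, 1.0, -1.0) + rng.standard_normal(400)
        f = np.where(y == 1, 1.0, -1.0) + rng.standard_normal(400)
        return fit_fusion_model(e, f, y, alpha=alpha), e, f, y

    def test_alpha_one_ignores_ftcd_stream(self):
        m, e, f, y = self._gaussian_model(1.0)
        rng = np.random.default_rng(1)
        for e_k in rng.normal(0, 2, 20):
            tag_a, _ = fuse_decide(e_k, 99.0, m)
            tag_b, _ = fuse_decide(e_k, -99.0, m)
            assert tag_a == tag_b

    def test_alpha_zero_ignores_eeg_stream(self):
        m, e, f, y = self._gaussian_model(0.0)
        rng = np.random.default_rng(2)
        for f_k in rng.normal(0, 2, 20):
            tag_a, _ = fuse_decide(99.0, f_k, m)
            tag_b, _ = fuse_decide(-99.0, f_k, m)
            assert tag_a == tag_b

    def test_symmetric_gaussians_follow_bayes_rule_at_test_point(self):
        m, *_ = self._gaussian_model(0.5)
        tag, ratio = fuse_decide(0.6, 0.6, m)
        assert tag == 1  # closed-form Bayes: e + f > 0 -> positive class
        assert ratio > 1.0

    def test_unfitted_model_rejected(self):
        with pytest.raises(ValueError, match="missing fitted density"):
            from neurofuse.fusion import FusionModel

            FusionModel(eeg_densities={}, ftcd_densities={}, alpha=0.5,
                        class_order=(0, 1))


class TestAlphaGridSearch:
    @staticmethod
    def _scores(rng, n, informative_e=True, informative_f=True):
        y = np.array([0] * n + [1] * n)
        mu = np.where(y == 1, 1.2, -1.2)
        e = (mu if informative_e else 0.0) + rng.standard_normal(2 * n)
        f = (mu if informative_f else 0.0) + rng.standard_normal(2 * n)
        return e, f, y

    def test_grid_has_101_candidates(self):
        rng = np.random.default_rng(0)
        e, f, y = self._scores(rng, 40)
        _, curve = alpha_grid_search(e, f, y, e, f, y)
        assert curve.size == 101

    def test_identical_streams_tie_break_to_zero(self):
        rng = np.random.default_rng(1)
        e, _, y = self._scores(rng, 40)
        best, curve = alpha_grid_search(e, e, y, e, e, y)
        assert np.allclose(curve, curve[0])
        assert best == 0.0

    def test_noise_ftcd_selection_keeps_eeg_performance(self):
        # with label-independent fTCD scores the accuracy curve plateaus once
        # the EEG term dominates; the selected alpha must sit on that plateau
        # (EEG-equivalent accuracy), far above the fTCD-only end
        rng = np.random.default_rng(2)
        for _ in range(10):
            e_tr, f_tr, y_tr = self._scores(rng, 60, informative_f=False)
            e_va, f_va, y_va = self._scores(rng, 60, informative_f=False)
            a, curve = alpha_grid_search(e_tr, f_tr, y_tr, e_va, f_va, y_va)
            chosen = curve[int(round(a * 100))]
            assert chosen == curve.max()
            assert chosen >= curve[-1]           # at least EEG-only accuracy
            assert chosen >= curve[0] + 0.15     # far above the noise stream

    def test_empty_validation_rejected(self):
        rng = np.random.default_rng(0)
        e, f, y = self._scores(rng, 10)
        with pytest.raises(ValueError, match="empty validation"):
            alpha_grid_search(e, f, y, e[:0], f[:0], y[:0])


class TestCrossValidation:
    def test_separable_dataset_reaches_full_accuracy(self, separable_dataset, quick_cv):
        report = run_cross_validation(separable_dataset, quick_cv)
        assert report.mean_accuracy == 100.0

    def test_dominance_and_limits_on_fixed_folds(self, separable_dataset, quick_cv):
        report = run_cross_validation(separable_dataset, quick_cv)
        curve = report.alpha_curve
        assert curve is not None
        # alpha = 1 end equals the EEG-only accuracy at the selected n_pairs;
        # best fused >= both single-modality accuracies (grid contains 0 and 1)
        assert report.mean_accuracy >= report.eeg_accuracy - 1e-9
        assert report.mean_accuracy >= report.ftcd_accuracy - 1e-9
        assert math.isclose(curve[0], report.ftcd_accuracy, abs_tol=1e-9)

    def test_same_seed_reproduces_report(self, separable_dataset, quick_cv):
        r1 = run_cross_validation(separable_dataset, quick_cv)
        r2 = run_cross_validation(separable_dataset, quick_cv)
        assert r1.to_dict() == r2.to_dict()
        assert r1.fold_model_hashes == r2.fold_model_hashes

    def test_null_dataset_stays_near_chance(self, null_dataset, quick_cv):
        report = run_cross_validation(null_dataset, quick_cv)
        # paper-mode maximum over 202 hyper-parameter combinations is
        # optimistic, so allow the optimism margin above the binomial band
        assert report.mean_accuracy <= 90.0

    def test_fitted_models_ignore_test_labels(self, separable_dataset, small_bank):
        labels = separable_dataset.labels.copy()
        rng = np.random.default_rng(0)
        folds = []
        idx = np.arange(len(labels))
        test = idx[::4]
        train = np.setdiff1d(idx, test)
        folds.append((train, test))
        cfg = CVConfig(n_pairs_sweep=(1, 2), bank=small_bank, mode="paper",
                       seed=0, folds=folds)
        r1 = run_cross_validation(separable_dataset, cfg)
        shuffled = separable_dataset
        shuffled.labels = labels.copy()
        shuffled.labels[test] = rng.permutation(labels[test])
        shuffled.eeg.labels = shuffled.labels
        shuffled.ftcd_raw.labels = shuffled.labels
        r2 = run_cross_validation(shuffled, cfg)
        shuffled.labels = labels
        shuffled.eeg.labels = labels
        shuffled.ftcd_raw.labels = labels
        assert r1.fold_model_hashes == r2.fold_model_hashes

    def test_too_few_trials_rejected(self, separable_dataset, quick_cv):
        idx = np.array([0, 1, 2, 12, 13, 14])  # 3 trials of each class
        from neurofuse.synthetic import PairedDataset

        ds = PairedDataset(
            eeg=separable_dataset.eeg.select(idx),
            ftcd_raw=separable_dataset.ftcd_raw.select(idx),
            labels=separable_dataset.labels[idx],
        )
        with pytest.raises(ValueError, match="at least 4 trials"):
            run_cross_validation(ds, quick_cv)


class TestSignificance:
    def test_uniformly_positive_differences_exact_p(self):
        a = np.linspace(90, 99, 10)
        b = a - np.linspace(1, 3, 10)
        assert math.isclose(signed_rank_compare(a, b, "greater"), 2.0 ** -10, rel_tol=1e-9)

    def test_swapping_sides_and_alternative_is_symmetric(self):
        rng = np.random.default_rng(0)
        a = rng.normal(90, 3, 8)
        b = a + rng.normal(1, 2, 8)
        p1 = signed_rank_compare(a, b, "greater")
        p2 = signed_rank_compare(b, a, "less")
        assert math.isclose(p1, p2, rel_tol=1e-12)

    def test_short_lists_rejected(self):
        with pytest.raises(ValueError, match="5"):
            signed_rank_compare([1, 2, 3, 4], [0, 1, 2, 3])

    def test_identical_lists_warn_p_one(self):
        with pytest.warns(UserWarning):
            p = signed_rank_compare(np.ones(6), np.ones(6))
        assert p == 1.0

    def test_alpha_median_all_high_exact_p(self):
        p = alpha_median_test(np.full(10, 0.9), alternative="greater")
        assert math.isclose(p, 2.0 ** -10, rel_tol=1e-9)

    def test_alpha_median_symmetric_sample_not_significant(self):
        alphas = np.array([0.3, 0.4, 0.45, 0.55, 0.6, 0.7])
        assert alpha_median_test(alphas, alternative="greater") >= 0.5

    def test_alpha_median_small_sample_rejected(self):
        with pytest.raises(ValueError, match="5"):
            alpha_median_test([0.4, 0.5, 0.6])

    def test_ranksum_backend_available(self):
        p = alpha_median_test(np.full(10, 0.9), alternative="greater", backend="ranksum")
        assert 0 < p < 0.05
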