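"""Elastic-net GLM fitting, imbalanced CV, and encoding statistics."""

import numpy as np
import pytest
from scipy.special import expit, logit

from levercode import encoding as enc
from levercode.encoding import (
    CVEstimate,
    InsufficientPositives,
    _assemble_estimates,
    category_models,
    cv_estimate,
    extract_kernels,
    fit_glm,
    fit_null,
    fit_null_and_classify,
    kernel_consistency,
    plan_folds,
    prediction_accuracy,
    unique_contribution,
)

RATE = 30.0


def _sparse_row(n=20_000, n_pos=100, seed=0):
    rng = np.random.default_rng(seed)
    r = np.zeros(n, dtype=np.int8)
    r[rng.choice(n, n_pos, replace=False)] = 1
    return r


class TestPlanFolds:
    def test_positives_partitioned_in_order(self):
        r = _sparse_row(n_pos=100)
        plan = plan_folds(r, seed=1)
        pos = np.flatnonzero(r)
        tested = np.sort(np.concatenate([f.test_pos for f in plan.folds]))
        assert np.array_equal(tested, pos)
        for f in plan.folds:
            assert len(f.train_pos) == 90 and len(f.test_pos) == 10
            # held-out block is contiguous in the ordered positive sequence
            idx = np.searchsorted(pos, f.test_pos)
            assert np.array_equal(np.diff(idx), np.ones(9))

    def test_one_percent_of_negatives_trained(self):
        r = _sparse_row(n=10_100, n_pos=100)
        plan = plan_folds(r, seed=2)
        for f in plan.folds:
            assert len(f.train_neg) == 100  # 1% of 10,000 negatives
            assert len(np.unique(f.train_neg)) == 100  # without replacement

    def test_guard_excludes_near_training_positives(self):
        r = _sparse_row(seed=3)
        plan = plan_folds(r, seed=3)
        g = plan.guard_frames
        assert g == 60
        for f in plan.folds:
            d = np.abs(f.test_neg[:, None] - f.train_pos[None, :]).min(axis=1)
            assert d.min() > g
            if len(f.guarded):
                dg = np.abs(f.guarded[:, None] - f.train_pos[None, :]).min(axis=1)
                assert dg.max() <= g

    def test_full_guard_scope_covers_training_negatives_too(self):
        r = _sparse_row(seed=3)
        plan = plan_folds(r, seed=3, guard_scope="all")
        plan.check()
        for f in plan.folds:
            d = np.abs(f.test_neg[:, None] - f.train[None, :]).min(axis=1)
            assert d.min() > plan.guard_frames

    def test_structural_invariants(self):
        plan = plan_folds(_sparse_row(seed=4), seed=4)
        plan.check()  # raises on any hygiene violation

    def test_too_few_positives_skips_neuron(self):
        with pytest.raises(InsufficientPositives):
            plan_folds(_sparse_row(n_pos=5), seed=5)

    def test_valid_mask_excludes_frames(self):
        r = _sparse_row(seed=6)
        mask = np.ones(len(r), bool)
        mask[:5000] = False
        plan = plan_folds(r, seed=6, valid_mask=mask)
        for f in plan.folds:
            assert f.train.min() >= 5000 and f.test.min() >= 5000


class TestFitGLM:
    def test_degenerate_labels_rejected(self):
        X = np.random.default_rng(0).standard_normal((20, 3))
        with pytest.raises(ValueError):
            fit_glm(X, np.zeros(20))

    def test_full_shrinkage_limit(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((200, 5))
        y = (rng.random(200) < 0.3).astype(int)
        fit = fit_glm(X, y, alpha=0.2, lam=100.0)
        assert np.abs(fit.weights).max() < 1e-6
        assert fit.intercept == pytest.approx(float(logit(y.mean())), abs=1e-3)

    def test_matches_reference_convex_solver(self):
        """The fitted optimum agrees with an independent solver (sklearn saga
        run to high precision with the equivalently scaled objective) on a
        small well-conditioned instance."""
        from sklearn.linear_model import LogisticRegression

        rng = np.random.default_rng(2)
        n, p = 300, 5
        X = rng.standard_normal((n, p))
        eta = 1.5 * X[:, 0] - 1.0
        y = (rng.random(n) < expit(eta)).astype(int)
        alpha, lam = 0.2, 1e-3
        fit = fit_glm(X, y, alpha=alpha, lam=lam)
        mu, sd = X.mean(0), X.std(0)
        Xs = (X - mu) / sd
        ref = LogisticRegression(
            penalty="elasticnet", solver="saga", C=1.0 / (n * lam),
            l1_ratio=alpha, tol=1e-10, max_iter=200_000,
        ).fit(Xs, y)
        w_ref = ref.coef_[0] / sd
        b_ref = float(ref.intercept_[0] - np.dot(ref.coef_[0], mu / sd))
        assert fit.weights[0] > 0
        assert np.allclose(fit.weights, w_ref, atol=1e-4)
        assert fit.intercept == pytest.approx(b_ref, abs=1e-4)

    def test_constant_columns_get_zero_weight(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((100, 3))
        X[:, 1] = 7.0
        y = (rng.random(100) < 0.4).astype(int)
        fit = fit_glm(X, y)
        assert fit.weights[1] == 0.0


class TestCVEstimate:
    def test_median_assigned_on_multiply_estimated_frames(self):
        r = np.zeros(10)
        per_fold = [
            (np.array([4]), np.array([0.1])),
            (np.array([4]), np.array([0.2])),
            (np.array([4, 5]), np.array([0.9, 0.3])),
        ]
        cv = _assemble_estimates(r, per_fold, 10, None)
        assert cv.prob[4] == pytest.approx(0.2)
        assert cv.prob[5] == pytest.approx(0.3)
        assert np.isnan(cv.prob[0])

    def test_perfect_estimate_has_unit_likelihood(self):
        r = np.array([0.0, 1.0, 0.0, 1.0])
        per_fold = [(np.arange(4), r.copy())]
        cv = _assemble_estimates(r, per_fold, 4, None)
        assert cv.mean_likelihood == pytest.approx(1.0)

    def test_constant_half_estimate(self):
        r = np.array([0.0, 1.0, 0.0, 1.0])
        per_fold = [(np.arange(4), np.full(4, 0.5))]
        cv = _assemble_estimates(r, per_fold, 4, None)
        assert cv.mean_likelihood == pytest.approx(0.5)

    def test_every_unguarded_frame_estimated(self):
        r = _sparse_row(n=6000, n_pos=40, seed=7)
        X = np.random.default_rng(7).standard_normal((6000, 8))
        plan = plan_folds(r, seed=7)
        cv = cv_estimate(r, X, plan, keep_fits=False)
        scored_somewhere = np.zeros(6000, bool)
        for f in plan.folds:
            scored_somewhere[f.test] = True
        assert np.isfinite(cv.prob[np.flatnonzero(r)]).all()
        assert np.isfinite(cv.prob[scored_somewhere]).all()
        assert np.isnan(cv.prob[~scored_somewhere]).all()


class TestNullModel:
    def test_null_constant_is_calibrated_training_rate(self):
        r = _sparse_row(n=20_000, n_pos=100, seed=8)
        plan = plan_folds(r, seed=8)
        null = fit_null(r, plan)
        vals = null.prob[np.isfinite(null.prob)]
        # corrected constant sits near the session rate, not near the ~33%
        # positive fraction of the rebalanced training sample
        assert 0.001 < np.median(vals) < 0.02

    def test_classification_compares_mean_likelihoods(self):
        r = _sparse_row(n=6000, n_pos=60, seed=9)
        plan = plan_folds(r, seed=9)
        null = fit_null(r, plan)
        better = CVEstimate(
            prob=null.prob, likelihood=null.likelihood,
            mean_likelihood=null.mean_likelihood + 0.01,
        )
        worse = CVEstimate(
            prob=null.prob, likelihood=null.likelihood,
            mean_likelihood=null.mean_likelihood - 0.01,
        )
        assert not fit_null_and_classify(r, plan, better)[0]
        assert fit_null_and_classify(r, plan, worse)[0]


class TestEncodingClassification:
    def test_driven_neurons_mostly_modelable(self, encoded_ls13):
        t = encoded_ls13.truth
        driven = [i for i in range(t.n_neurons) if t.labels[i] != "noise"]
        modelable = sum(not encoded_ls13.elusive[i] for i in driven)
        assert modelable / len(driven) > 0.5

    def test_noise_neurons_mostly_elusive(self, encoded_ls13):
        t = encoded_ls13.truth
        noise = [i for i in range(t.n_neurons) if t.labels[i] == "noise"]
        elusive = sum(encoded_ls13.elusive[i] for i in noise)
        assert elusive / len(noise) > 0.5


class TestPredictionAccuracy:
    def _cv_from(self, prob, n):
        p = np.asarray(prob, float)
        return CVEstimate(prob=p, likelihood=np.ones(n), mean_likelihood=1.0)

    def test_exact_estimate_scores_one(self):
        rng = np.random.default_rng(10)
        r = (rng.random(3000) < 0.2).astype(float)
        events = np.arange(200, 2800, 400)
        cv = self._cv_from(r, 3000)
        assert prediction_accuracy(cv, r, events, RATE) == pytest.approx(1.0)

    def test_affine_transform_invariance(self):
        rng = np.random.default_rng(11)
        r = (rng.random(3000) < 0.2).astype(float)
        events = np.arange(200, 2800, 400)
        cv = self._cv_from(0.3 * r + 0.1, 3000)
        assert prediction_accuracy(cv, r, events, RATE) == pytest.approx(1.0)

    def test_independent_estimate_scores_near_zero(self):
        rng = np.random.default_rng(12)
        r = (rng.random(30_000) < 0.2).astype(float)
        events = np.arange(200, 29_800, 150)
        cv = self._cv_from(rng.random(30_000), 30_000)
        assert prediction_accuracy(cv, r, events, RATE) < 0.05

    def test_constant_average_flagged_as_zero(self, caplog):
        cv = self._cv_from(np.full(3000, 0.5), 3000)
        r = np.zeros(3000)
        with caplog.at_level("WARNING"):
            out = prediction_accuracy(cv, r, np.array([500, 1500]), RATE)
        assert out == 0.0


class TestContributions:
    def test_unique_contribution_subtracts(self):
        assert unique_contribution(0.5, 0.3) == pytest.approx(0.2)

    def test_negative_contribution_clipped(self):
        assert unique_contribution(0.3, 0.5) == 0.0

    def test_category_models_use_subset_designs(self, basis):
        from levercode.behavior import BehaviorMatrix
        from levercode.design import expand_design

        rng = np.random.default_rng(13)
        n = 6000
        data = np.zeros((n, 20))
        data[:, 0] = rng.standard_normal(n).cumsum() * 0.01
        bm = BehaviorMatrix(data, np.zeros(n, bool), 30.0)
        design = expand_design(bm, basis)
        r = _sparse_row(n=n, n_pos=40, seed=14)
        plan = plan_folds(r, seed=14)
        single, loo = category_models(r, design, "lever", plan)
        assert np.isfinite(single.mean_likelihood)
        assert np.isfinite(loo.mean_likelihood)

    def test_unknown_category_rejected(self, basis):
        with pytest.raises(ValueError):
            category_models(None, None, "whiskers", None)


class TestKernels:
    def _fit(self, weights, basis):
        return enc.EncodingFit(
            intercept=0.0, weights=weights, alpha=0.2, lam=1e-4,
            objective=0.0, n_iter=1,
        )

    def test_zero_weights_give_zero_kernel(self, basis):
        fits = [self._fit(np.zeros(420), basis) for _ in range(10)]
        ks = extract_kernels(fits, basis)
        assert np.all(ks.kernels == 0)

    def test_unit_weight_reproduces_basis_function(self, basis):
        w = np.zeros(420)
        w[10] = 1.0  # lever_pos, center 0
        ks = extract_kernels([self._fit(w, basis)], basis)
        _, B = basis.sample()
        assert np.allclose(ks.kernels[0], B[10])
        assert np.all(ks.kernels[1:] == 0)

    def test_session_kernel_is_fold_median(self, basis):
        fits = []
        for scale in (1.0, 2.0, 10.0):
            w = np.zeros(420)
            w[10] = scale
            fits.append(self._fit(w, basis))
        ks = extract_kernels(fits, basis)
        _, B = basis.sample()
        assert np.allclose(ks.kernels[0], 2.0 * B[10])

    def test_consistency_of_identical_kernels(self):
        rng = np.random.default_rng(15)
        k = rng.standard_normal((1, 3, 4, 50))
        sessions = np.concatenate([k, k], axis=0)
        corr, n_excl = kernel_consistency(sessions)
        assert np.allclose(corr, 1.0)
        assert n_excl == 0

    def test_sign_flip_gives_minus_one(self):
        rng = np.random.default_rng(16)
        k = rng.standard_normal((1, 2, 4, 50))
        sessions = np.concatenate([k, -k], axis=0)
        corr, _ = kernel_consistency(sessions)
        assert np.allclose(corr, -1.0)

    def test_zero_kernels_excluded_with_count(self):
        rng = np.random.default_rng(17)
        k = rng.standard_normal((2, 2, 3, 50))
        k[:, 0, 1] = 0.0  # neuron 0, variable 1 identically zero
        corr, n_excl = kernel_consistency(k)
        assert np.isnan(corr[0, 1])
        assert n_excl == 1

    def test_stable_neurons_more_consistent_than_unstable(
        self, study, encoded_ls13, basis
    ):
        """Fit a second session for a few stable and unstable neurons and
        compare the cross-session consistency of their lever kernels."""
        bundles, truth = study
        stable = [i for i in range(truth.n_neurons)
                  if truth.labels[i] == "stable" and not encoded_ls13.elusive[i]][:3]
        unstable = [i for i in range(truth.n_neurons)
                    if truth.labels[i] == "unstable" and not encoded_ls13.elusive[i]][:3]
        assert stable and unstable
        from levercode.design import expand_design

        b2 = bundles[3]  # TS2
        design2 = expand_design(b2.behavior, basis)
        chosen = stable + unstable
        lags, _ = basis.sample()
        kern = np.zeros((2, len(chosen), 20, len(lags)))
        for j, i in enumerate(chosen):
            kern[0, j] = extract_kernels(encoded_ls13.cvs[i].fits, basis).kernels
            plan = plan_folds(b2.activity[i], seed=900 + i)
            cv2 = cv_estimate(b2.activity[i], design2.X, plan)
            kern[1, j] = extract_kernels(cv2.fits, basis).kernels
        corr, _ = kernel_consistency(kern)
        lever_cols = [0, 1, 2]
        c_stable = np.nanmean(corr[: len(stable)][:, lever_cols])
        c_unstable = np.nanmean(corr[len(stable):][:, lever_cols])
        assert c_stable > c_unstable
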