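"""Per-neuron Bernoulli elastic-net encoding models with imbalanced CV.

Each neuron's binarized activity train r_i is modeled as
P(r_i = 1 | behavior) = logistic(b + w . design_row) with an elastic-net
penalty on the basis-expanded weights,

    mean Bernoulli NLL + lambda * (alpha * ||w||_1 + (1 - alpha)/2 * ||w||_2^2),

intercept unpenalized, columns standardized before fitting and weights
mapped back to the original scale (alpha = 0.2, lambda = 1e-4).

Because positive frames are rare (~0.6% of frames), training sets are
rebalanced: each of 10 folds trains on nine-tenths of the positive frames
(contiguous in temporal order) plus 1% of the negative frames sampled
without replacement, and is scored on the held-out tenth of positives plus
the remaining negatives.  Negative test frames within 2 s of any same-fold
training frame are excluded from scoring (data-leakage guard); held-out
positives are always scored so that the union of test positives over folds
covers every positive frame.  Negative frames scored in several folds take
the median estimate; the concatenated probability train is the
cross-validated estimate every downstream statistic (and the decoder's
likelihood library) consumes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .behavior import CANONICAL_COLUMNS, CATEGORIES, TrialAverage, trial_average

logger = logging.getLogger(__name__)

ALPHA = 0.2
LAMBDA = 1e-4
N_FOLDS = 10
NEG_FRACTION = 0.01
GUARD_SECONDS = 2.0


class InsufficientPositives(ValueError):
    """Raised when a neuron has too few positive frames to plan folds."""


@dataclass
class Fold:
    train_pos: np.ndarray
    train_neg: np.ndarray
    test_pos: np.ndarray
    test_neg: np.ndarray  # scored negatives (guard already applied)
    guarded: np.ndarray  # negative test frames dropped by the 2 s guard
    strict_test_neg: np.ndarray = None  # scored negatives also clear of the
    # conservative guard (2 s from *any* training frame); the set the
    # full-vs-null likelihood comparison is evaluated on

    @property
    def train(self) -> np.ndarray:
        return np.sort(np.concatenate([self.train_pos, self.train_neg]))

    @property
    def test(self) -> np.ndarray:
        return np.sort(np.concatenate([self.test_pos, self.test_neg]))


@dataclass
class FoldPlan:
    folds: list[Fold]
    n_frames: int
    seed: int
    guard_frames: int
    n_pos: int = 0  # positive frames available to the plan
    n_neg: int = 0  # negative frames available to the plan
    guard_scope: str = "positives"

    def sampling_correction(self, fold: Fold) -> float:
        """Case-control intercept correction log(s_pos / s_neg) for one fold.

        Training on ~90% of positives but only ~1% of negatives fits a model
        whose intercept reflects the rebalanced sample, not the session; the
        standard prior correction subtracts the log ratio of the class
        sampling fractions, restoring calibrated probabilities.
        """
        s_pos = len(fold.train_pos) / self.n_pos
        s_neg = len(fold.train_neg) / self.n_neg
        return float(np.log(s_pos / s_neg))

    def check(self) -> None:
        """Assert the structural CV-hygiene invariants."""
        all_test_pos: list[np.ndarray] = []
        for f in self.folds:
            if np.intersect1d(f.train, f.test).size:
                raise AssertionError("train and test frames overlap within a fold")
            guard_src = f.train if self.guard_scope == "all" else f.train_pos
            if f.test_neg.size:
                d = np.abs(f.test_neg[:, None] - guard_src[None, :]).min(axis=1)
                if d.min() <= self.guard_frames:
                    raise AssertionError("guard violated: scored negative near training frame")
            all_test_pos.append(f.test_pos)
        cat = np.concatenate(all_test_pos)
        if len(cat) != len(np.unique(cat)):
            raise AssertionError("a positive frame is tested in more than one fold")


def plan_folds(
    activity_row: np.ndarray,
    seed: int = 0,
    frame_rate: float = 30.0,
    n_folds: int = N_FOLDS,
    neg_fraction: float = NEG_FRACTION,
    guard: float = GUARD_SECONDS,
    valid_mask: np.ndarray | None = None,
    guard_scope: str = "positives",
) -> FoldPlan:
    """Build the imbalanced 10-fold plan for one neuron.

    Positive frames are split in temporal order into ``n_folds`` contiguous
    blocks; fold f holds out block f and trains on the rest plus
    ``neg_fraction`` of the negative frames sampled without replacement
    (independently per fold, seeded).  Frames excluded by ``valid_mask``
    (e.g. omitted design rows) enter neither training nor scoring.

    ``guard_scope`` controls which training frames project the 2 s
    data-leakage guard: ``"positives"`` (default) guards the neighborhoods
    of training positives — the frames whose temporally autocorrelated
    activity can leak — while ``"all"`` also guards around the randomly
    sampled training negatives.  The latter blankets ~70% of the session
    per fold (1% of negatives x 121 frames exceeds the session length), so
    joint coverage across a population, which the decoding library needs,
    only exists under the default.
    """
    if guard_scope not in ("positives", "all"):
        raise ValueError("guard_scope must be 'positives' or 'all'")
    r = np.asarray(activity_row).astype(int)
    n = len(r)
    if valid_mask is None:
        valid_mask = np.ones(n, dtype=bool)
    pos = np.flatnonzero((r == 1) & valid_mask)
    neg = np.flatnonzero((r == 0) & valid_mask)
    if len(pos) < n_folds:
        raise InsufficientPositives(
            f"{len(pos)} positive frames < {n_folds} folds; neuron skipped"
        )
    guard_frames = int(round(guard * frame_rate))
    rng = np.random.default_rng(seed)
    blocks = np.array_split(pos, n_folds)
    n_train_neg = max(1, int(round(neg_fraction * len(neg))))

    folds: list[Fold] = []
    for f in range(n_folds):
        test_pos = blocks[f]
        train_pos = np.concatenate([blocks[g] for g in range(n_folds) if g != f])
        train_neg = np.sort(rng.choice(neg, size=n_train_neg, replace=False))
        test_neg_all = np.setdiff1d(neg, train_neg, assume_unique=True)
        def _near(src: np.ndarray, q: np.ndarray) -> np.ndarray:
            # distance of each query frame to the nearest source frame
            idx = np.searchsorted(src, q)
            left = src[np.clip(idx - 1, 0, len(src) - 1)]
            right = src[np.clip(idx, 0, len(src) - 1)]
            return np.minimum(np.abs(q - left), np.abs(q - right)) <= guard_frames

        near_pos = _near(train_pos, test_neg_all)
        near_all = near_pos | _near(train_neg, test_neg_all)
        near = near_all if guard_scope == "all" else near_pos
        folds.append(
            Fold(
                train_pos=train_pos,
                train_neg=train_neg,
                test_pos=test_pos,
                test_neg=test_neg_all[~near],
                guarded=test_neg_all[near],
                strict_test_neg=test_neg_all[~near_all],
            )
        )
    return FoldPlan(
        folds=folds, n_frames=n, seed=seed, guard_frames=guard_frames,
        n_pos=len(pos), n_neg=len(neg), guard_scope=guard_scope,
    )


@dataclass
class EncodingFit:
    """One penalized GLM fit (original-scale weights)."""

    intercept: float
    weights: np.ndarray
    alpha: float
    lam: float
    objective: float
    n_iter: int

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return expit(self.intercept + X @ self.weights)


def _objective(
    X: np.ndarray, y: np.ndarray, w: np.ndarray, b: float, alpha: float, lam: float
) -> float:
    eta = b + X @ w
    nll = np.mean(np.logaddexp(0.0, eta) - y * eta)
    pen = lam * (alpha * np.abs(w).sum() + 0.5 * (1 - alpha) * (w @ w))
    return float(nll + pen)


def fit_glm(
    X: np.ndarray,
    y: np.ndarray,
    alpha: float = ALPHA,
    lam: float = LAMBDA,
    tol: float = 1e-10,
    max_iter: int = 3000,
) -> EncodingFit:
    """Fit the Bernoulli elastic-net GLM on (already subsetted) training rows.

    Columns are standardized internally and the weights mapped back; constant
    columns get weight zero.  The L1 kink is handled exactly by the
    split-variable reformulation w = u - v with u, v >= 0, which turns the
    penalized objective into a smooth box-constrained problem solved with
    L-BFGS-B; the intercept is the single unbounded, unpenalized coordinate.
    """
    from scipy.optimize import minimize

    y = np.asarray(y).astype(float)
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("training set needs at least one positive and one negative")
    X = np.asarray(X, dtype=float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    keep = sd > 0
    Xs = (X[:, keep] - mu[keep]) / sd[keep]
    n, p = Xs.shape
    l1 = lam * alpha
    l2 = lam * (1.0 - alpha)

    def fun_grad(z: np.ndarray) -> tuple[float, np.ndarray]:
        b, u, v = z[0], z[1 : 1 + p], z[1 + p :]
        w = u - v
        eta = b + Xs @ w
        nll = float(np.mean(np.logaddexp(0.0, eta) - y * eta))
        val = nll + l1 * (u.sum() + v.sum()) + 0.5 * l2 * float(w @ w)
        s = expit(eta) - y
        gb = float(s.mean())
        gw = Xs.T @ s / n + l2 * w
        g = np.concatenate([[gb], gw + l1, -gw + l1])
        return val, g

    z0 = np.zeros(1 + 2 * p)
    z0[0] = float(np.log(y.mean() / (1.0 - y.mean())))
    bounds = [(None, None)] + [(0.0, None)] * (2 * p)
    res = minimize(
        fun_grad,
        z0,
        jac=True,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": max_iter, "ftol": tol, "gtol": 1e-9},
    )
    if not res.success and "ABNORMAL" in str(res.message):
        raise RuntimeError(
            f"elastic-net GLM failed to converge: {res.message} "
            f"(n={n}, p={p}, positives={int(y.sum())}, nit={res.nit})"
        )
    ws = res.x[1 : 1 + p] - res.x[1 + p :]
    w = np.zeros(X.shape[1])
    w[keep] = ws / sd[keep]
    b = float(res.x[0] - np.dot(ws, mu[keep] / sd[keep]))
    return EncodingFit(
        intercept=b,
        weights=w,
        alpha=alpha,
        lam=lam,
        # objective in the standardized space the penalty is defined in
        objective=_objective(Xs, y, ws, float(res.x[0]), alpha, lam),
        n_iter=int(res.nit),
    )


@dataclass
class CVEstimate:
    """Concatenated cross-validated probability train for one neuron.

    ``mean_likelihood`` (the statistic compared between full and null
    models) is evaluated over the conservatively guarded frames — held-out
    positives plus negatives at least 2 s from any same-fold training frame
    — a maximally leakage-free set shared by both models; the probability
    train itself covers every scored frame.
    """

    prob: np.ndarray  # (n_frames,), NaN where no fold scored the frame
    likelihood: np.ndarray  # (n_frames,), 1 - |r - p|, NaN where unscored
    mean_likelihood: float
    fits: list[EncodingFit] | None = None

    @property
    def scored(self) -> np.ndarray:
        return np.isfinite(self.prob)


def _assemble_estimates(
    r: np.ndarray,
    per_fold: list[tuple[np.ndarray, np.ndarray]],
    n: int,
    fits: list[EncodingFit] | None,
    strict: np.ndarray | None = None,
) -> CVEstimate:
    """Merge per-fold (frames, probabilities) into one train (median on ties)."""
    frames_all = np.concatenate([f for f, _ in per_fold])
    vals_all = np.concatenate([p for _, p in per_fold])
    order = np.argsort(frames_all, kind="stable")
    fs, vs = frames_all[order], vals_all[order]
    starts = np.flatnonzero(np.r_[True, fs[1:] != fs[:-1]])
    counts = np.diff(np.r_[starts, len(fs)])
    prob = np.full(n, np.nan)
    for c in np.unique(counts):
        sel = starts[counts == c]
        block = vs[sel[:, None] + np.arange(c)[None, :]]
        prob[fs[sel]] = block[:, 0] if c == 1 else np.median(block, axis=1)
    like = np.where(np.isfinite(prob), 1.0 - np.abs(r - prob), np.nan)
    # geometric mean per frame (= exp of the mean Bernoulli log-likelihood);
    # a proper score, under which the calibrated null sits at exp(-H(rate))
    scored = like if strict is None else np.where(strict, like, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        mean_like = float(np.exp(np.nanmean(np.log(np.clip(scored, 1e-300, None)))))
    return CVEstimate(prob=prob, likelihood=like, mean_likelihood=mean_like, fits=fits)


def _strict_mask(plan: FoldPlan) -> np.ndarray:
    strict = np.zeros(plan.n_frames, dtype=bool)
    for f in plan.folds:
        strict[f.test_pos] = True
        strict[f.strict_test_neg] = True
    return strict


def cv_estimate(
    activity_row: np.ndarray,
    X: np.ndarray,
    plan: FoldPlan,
    alpha: float = ALPHA,
    lam: float = LAMBDA,
    keep_fits: bool = True,
) -> CVEstimate:
    """Fit the 10 fold models and concatenate their test-frame estimates."""
    r = np.asarray(activity_row).astype(float)
    per_fold = []
    fits = []
    for fold in plan.folds:
        train = fold.train
        fit = fit_glm(X[train], r[train].astype(int), alpha=alpha, lam=lam)
        fits.append(fit)
        test = fold.test
        corr = plan.sampling_correction(fold)
        p = expit(fit.intercept - corr + X[test] @ fit.weights)
        per_fold.append((test, p))
    return _assemble_estimates(
        r, per_fold, plan.n_frames, fits if keep_fits else None,
        strict=_strict_mask(plan),
    )


def fit_null(activity_row: np.ndarray, plan: FoldPlan) -> CVEstimate:
    """Intercept-only model under the same CV.

    The constant is the training-positive fraction of the fold's rebalanced
    sample, mapped back through the case-control correction — i.e. the
    calibrated estimate of the session's positive rate.
    """
    r = np.asarray(activity_row).astype(float)
    per_fold = []
    for fold in plan.folds:
        train = fold.train
        p0 = float(r[train].mean())
        corr = plan.sampling_correction(fold)
        p0 = float(expit(np.log(p0 / (1.0 - p0)) - corr))
        test = fold.test
        per_fold.append((test, np.full(len(test), p0)))
    return _assemble_estimates(
        r, per_fold, plan.n_frames, None, strict=_strict_mask(plan)
    )


def fit_null_and_classify(
    activity_row: np.ndarray, plan: FoldPlan, full_cv: CVEstimate
) -> tuple[bool, CVEstimate]:
    """Return (elusive, null estimate): elusive iff the full model's mean
    cross-validated per-frame likelihood does not exceed the null's."""
    null_cv = fit_null(activity_row, plan)
    elusive = full_cv.mean_likelihood <= null_cv.mean_likelihood
    return elusive, null_cv


def prediction_accuracy(
    cv: CVEstimate,
    activity_row: np.ndarray,
    events: np.ndarray,
    frame_rate: float = 30.0,
    window: tuple[float, float] = (-1.0, 3.0),
) -> float:
    """Cross-validated R^2 of the trial-averaged activity.

    Square of the Pearson correlation between the trial-averaged binarized
    activity and the trial-averaged estimated probability within the
    task-related window around successful pull initiations.  A constant
    trial average makes the correlation undefined; such neurons get 0 with a
    logged flag.
    """
    rec = trial_average(np.asarray(activity_row, float), events, frame_rate, window)
    est = trial_average(cv.prob, events, frame_rate, window)
    a, b = rec.mean, est.mean
    ok = np.isfinite(a) & np.isfinite(b)
    a, b = a[ok], b[ok]
    if len(a) < 3 or a.std() == 0 or b.std() == 0:
        logger.warning("constant trial average; prediction accuracy set to 0")
        return 0.0
    rho = float(np.corrcoef(a, b)[0, 1])
    return rho * rho


def unique_contribution(full_r2: float, reduced_r2: float) -> float:
    """Encoding unique contribution: ``max(full - reduced, 0)``."""
    return max(full_r2 - reduced_r2, 0.0)


def category_models(
    activity_row: np.ndarray,
    design,
    category: str,
    plan: FoldPlan,
    alpha: float = ALPHA,
    lam: float = LAMBDA,
) -> tuple[CVEstimate, CVEstimate]:
    """Single-category and leave-one-category-out CV estimates for a neuron."""
    if category not in CATEGORIES:
        raise ValueError(f"unknown category {category!r}")
    single = design.subset(category, leave_out=False)
    loo = design.subset(category, leave_out=True)
    return (
        cv_estimate(activity_row, single.X, plan, alpha, lam, keep_fits=False),
        cv_estimate(activity_row, loo.X, plan, alpha, lam, keep_fits=False),
    )


@dataclass
class KernelSet:
    """Per-variable temporal kernels reconstructed from fitted weights."""

    kernels: np.ndarray  # (n_variables, n_lags), median across folds
    per_fold: np.ndarray  # (n_folds, n_variables, n_lags)
    lags: np.ndarray  # s
    variables: tuple[str, ...]


def extract_kernels(fits: list[EncodingFit], basis) -> KernelSet:
    """Reconstruct per-variable temporal kernels; session kernel = fold median.

    Each variable's kernel is the weight-weighted sum of the sampled basis
    functions, evaluated on the basis lag grid.
    """
    lags, B = basis.sample()  # (n_bases, n_lags)
    n_vars = len(CANONICAL_COLUMNS)
    per_fold = np.stack(
        [f.weights.reshape(n_vars, basis.n_bases) @ B for f in fits]
    )
    return KernelSet(
        kernels=np.median(per_fold, axis=0),
        per_fold=per_fold,
        lags=lags,
        variables=CANONICAL_COLUMNS,
    )


def kernel_consistency(
    kernels_by_session: np.ndarray,
) -> tuple[np.ndarray, int]:
    """Between-session kernel correlations per neuron and variable.

    ``kernels_by_session`` has shape (n_sessions, n_neurons, n_variables,
    n_lags).  Returns ``(corr, n_excluded)`` where ``corr[i, v]`` is the mean
    Pearson correlation of neuron i's variable-v kernel over all session
    pairs; pairs where either kernel is identically zero (or constant) are
    undefined and excluded (NaN, counted).  Callers average ``corr`` within
    a neuron group.
    """
    K = np.asarray(kernels_by_session, dtype=float)
    s, n, v, L = K.shape
    if s < 2:
        raise ValueError("need kernels from at least two sessions")
    flat = K.reshape(s, n * v, L)
    from .behavior import _pearson_rows

    pair_vals = []
    for a in range(s):
        for b in range(a + 1, s):
            pair_vals.append(_pearson_rows(flat[a].copy(), flat[b].copy()))
    stacked = np.stack(pair_vals)  # (pairs, n*v)
    n_excluded = int(np.isnan(stacked).sum())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(stacked, axis=0)
    return mean.reshape(n, v), n_excluded
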