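"""Bayesian marginalization decoding of the lever trajectory.

The decoder inverts the per-neuron encoding models without an explicit
behavioral prior over unobserved states: the library of realized behavioral
states is the session itself, each library frame s carrying the lever value
x_s and the cross-validated per-neuron encoding probabilities
P(r_i | x_s, x~_s).  For a query frame t the population likelihood is

    P(rbar_t | x_s, x~_s) = prod_i (1 - |rbar_{i,t} - P(r_i | x_s, x~_s)|),

extended over seven temporal offsets (t-6, t-4, t-2, t, t+2, t+4, t+6
frames, library probabilities taken at s + offset), and the decoded lever
position is the likelihood-weighted average of library lever values

    xhat_t = sum_s x_s P(rbar_t | s) / sum_s P(rbar_t | s),

with library frames within 3.3 s of t excluded to prevent self-decoding
leakage.  The uniform prior constant cancels in the ratio.  Likelihood
products are accumulated in log space with factors floored at a small
epsilon to avoid underflow.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

OFFSETS = (-6, -4, -2, 0, 2, 4, 6)
EXCLUSION_SECONDS = 3.3
EPS = 1e-12


@dataclass
class LikelihoodLibrary:
    """Per-frame encoding probabilities and lever values of one session."""

    probs: np.ndarray  # (n_neurons, n_frames), NaN where no CV estimate exists
    lever: np.ndarray  # (n_frames,), mm
    frame_rate: float

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        self.lever = np.asarray(self.lever, dtype=float)
        if self.probs.shape[1] != len(self.lever):
            raise ValueError("library probabilities and lever length mismatch")
        finite = self.probs[np.isfinite(self.probs)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValueError("library probabilities must lie in [0, 1]")

    @property
    def n_frames(self) -> int:
        return self.probs.shape[1]


def build_library(
    cv_probs: np.ndarray, lever: np.ndarray, frame_rate: float
) -> LikelihoodLibrary:
    """Assemble the library from stacked per-neuron CV probability trains."""
    return LikelihoodLibrary(probs=cv_probs, lever=lever, frame_rate=frame_rate)


def frame_likelihood(
    observed: np.ndarray, library_point: np.ndarray, eps: float = EPS
) -> float:
    """Single-frame population likelihood prod_i (1 - |r_i - p_i|).

    Computed in log space with per-factor flooring at ``eps``.
    """
    r = np.asarray(observed, dtype=float)
    p = np.asarray(library_point, dtype=float)
    if r.shape != p.shape:
        raise ValueError("observed activity and library point sizes differ")
    factors = np.maximum(1.0 - np.abs(r - p), eps)
    return float(np.exp(np.log(factors).sum()))


@dataclass
class DecodeResult:
    """Decoded lever trajectory and the frames/neurons that produced it."""

    x_hat: np.ndarray  # (n_frames,), NaN where not decoded
    decoded: np.ndarray  # (n_frames,) bool
    neuron_set: np.ndarray
    offsets: tuple[int, ...]
    exclusion_frames: int


def _offset_frames(offsets: tuple[int, ...], frame_rate: float) -> np.ndarray:
    """Offsets are stated in 30 Hz frames; scale by the rate ratio otherwise."""
    off = np.asarray(offsets, dtype=float)
    if abs(frame_rate - 30.0) > 1e-9:
        off = np.round(off * frame_rate / 30.0)
    return off.astype(int)


def decode_lever(
    activity: np.ndarray,
    library: LikelihoodLibrary,
    neuron_set: np.ndarray | None = None,
    offsets: tuple[int, ...] = OFFSETS,
    exclusion: float = EXCLUSION_SECONDS,
    eps: float = EPS,
    query_stride: int = 1,
) -> DecodeResult:
    """Decode the lever trajectory from population binarized activity.

    ``activity`` is the (n_neurons, n_frames) binary matrix of the session
    being decoded; the library must come from the same session's CV
    estimates so decoding inherits the encoding cross-validation.  Library
    frames lacking an estimate for any used neuron are dropped; query and
    library frames whose offset window exits the session are skipped; library
    frames with |s - t| <= exclusion seconds are excluded per query frame.
    """
    R = np.asarray(activity, dtype=float)
    if R.shape[1] != library.n_frames:
        raise ValueError("activity and library frame counts differ")
    if neuron_set is None:
        neuron_set = np.arange(R.shape[0])
    neuron_set = np.asarray(neuron_set, dtype=int)
    if neuron_set.size == 0:
        raise ValueError("empty neuron set")
    lib_valid = np.all(np.isfinite(library.probs[neuron_set]), axis=0)
    return _decode_subset(
        R, library, neuron_set, lib_valid, offsets, exclusion, eps,
        query_stride=query_stride,
    )


def _prepare_frames(
    library: LikelihoodLibrary,
    lib_valid: np.ndarray,
    offsets: tuple[int, ...],
    query_stride: int = 1,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Query frames, admissible library frames, and integer offsets."""
    off = _offset_frames(offsets, library.frame_rate)
    n = library.n_frames
    lo, hi = -int(off.min()), int(off.max())
    tq = np.arange(max(lo, 0), n - max(hi, 0), max(int(query_stride), 1))
    ok = np.ones(n, dtype=bool)
    for o in off:  # library frame usable iff every offset frame has estimates
        shifted = np.zeros(n, dtype=bool)
        src = lib_valid[max(o, 0) : n + min(o, 0)]
        shifted[max(-o, 0) : n - max(o, 0)] = src
        ok &= shifted
    sq = np.flatnonzero(ok)
    sq = sq[(sq >= max(lo, 0)) & (sq < n - max(hi, 0))]
    if sq.size == 0:
        raise ValueError("library is empty after validity filtering")
    return tq, sq, off


def _accumulate_loglik(
    R: np.ndarray,
    library: LikelihoodLibrary,
    neuron_set: np.ndarray,
    tq: np.ndarray,
    sq: np.ndarray,
    off: np.ndarray,
    eps: float,
) -> np.ndarray:
    """Offset-summed log-likelihood A[t, s] over the chosen neuron set.

    A is additive over neurons, so removal analyses can subtract the matrix
    of the removed subset from the full set's matrix.
    """
    Rn = R[neuron_set]
    P = library.probs[neuron_set]
    Pc = np.clip(np.where(np.isfinite(P), P, 0.5), eps, 1.0 - eps)
    logP = np.log(Pc)
    log1mP = np.log1p(-Pc)
    A = np.zeros((len(tq), len(sq)))
    for o in off:
        Rt = Rn[:, tq + o]
        A += Rt.T @ logP[:, sq + o] + (1.0 - Rt).T @ log1mP[:, sq + o]
    return A


def _decode_subset(
    R: np.ndarray,
    library: LikelihoodLibrary,
    neuron_set: np.ndarray,
    lib_valid: np.ndarray,
    offsets: tuple[int, ...],
    exclusion: float,
    eps: float,
    A: np.ndarray | None = None,
    frames: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None,
    query_stride: int = 1,
) -> DecodeResult:
    tq, sq, off = frames or _prepare_frames(
        library, lib_valid, offsets, query_stride
    )
    if A is None:
        A = _accumulate_loglik(R, library, neuron_set, tq, sq, off, eps)
    else:
        A = A.copy()
    n = library.n_frames
    excl = int(round(exclusion * library.frame_rate))
    mask = np.abs(tq[:, None] - sq[None, :]) <= excl
    A[mask] = -np.inf
    if np.any(np.all(mask, axis=1)):
        raise ValueError("library empty after the temporal exclusion window")

    A -= A.max(axis=1, keepdims=True)
    W = np.exp(A)
    x_hat_q = (W @ library.lever[sq]) / W.sum(axis=1)

    x_hat = np.full(n, np.nan)
    x_hat[tq] = x_hat_q
    decoded = np.zeros(n, dtype=bool)
    decoded[tq] = True
    return DecodeResult(
        x_hat=x_hat,
        decoded=decoded,
        neuron_set=neuron_set,
        offsets=tuple(int(o) for o in off),
        exclusion_frames=excl,
    )


def decoding_accuracy(result: DecodeResult, lever: np.ndarray) -> float:
    """Square of the Pearson correlation between decoded and recorded lever."""
    lever = np.asarray(lever, dtype=float)
    d = result.decoded
    if d.sum() < 100:
        raise ValueError("need at least 100 decoded frames")
    x, y = result.x_hat[d], lever[d]
    if x.std() == 0 or y.std() == 0:
        logger.warning("constant decoded trace; decoding accuracy set to 0")
        return 0.0
    rho = float(np.corrcoef(x, y)[0, 1])
    return rho * rho


@dataclass
class DecodingContribution:
    """Unique decoding contribution of a neuron subset with its control draws."""

    delta_r2: float
    controls: np.ndarray  # (n_controls,) control delta R^2 values
    r2_full: float
    r2_reduced: float
    seed: int


def decoding_unique_contribution(
    activity: np.ndarray,
    library: LikelihoodLibrary,
    full_set: np.ndarray,
    subset: np.ndarray,
    control_pool: np.ndarray,
    n_controls: int = 100,
    seed: int = 0,
    offsets: tuple[int, ...] = OFFSETS,
    exclusion: float = EXCLUSION_SECONDS,
    query_stride: int = 1,
) -> DecodingContribution:
    """Delta R^2 of removing ``subset``, against same-size random removals.

    ``control_pool`` holds the neurons control populations may be drawn from
    (the full set minus the group of interest); each of ``n_controls`` seeded
    draws removes a random same-size population and records its delta R^2.
    """
    full_set = np.asarray(full_set, dtype=int)
    subset = np.asarray(subset, dtype=int)
    control_pool = np.asarray(control_pool, dtype=int)
    if not np.isin(subset, full_set).all():
        raise ValueError("subset must be contained in full_set")
    if len(subset) == len(full_set):
        raise ValueError("subset must be a proper subset of full_set")
    lever = library.lever
    R = np.asarray(activity, dtype=float)

    # the log-likelihood matrix is additive over neurons: removing a subset
    # only needs the subset's own matrix subtracted from the full one; the
    # full set's library-validity is shared so all removals are scored over
    # identical frames
    valid_full = np.all(np.isfinite(library.probs[full_set]), axis=0)
    frames = _prepare_frames(library, valid_full, offsets, query_stride)
    tq, sq, off = frames
    A_full = _accumulate_loglik(R, library, full_set, tq, sq, off, EPS)

    def r2_without(removed: np.ndarray) -> float:
        keep = np.setdiff1d(full_set, removed)
        A_rm = _accumulate_loglik(R, library, removed, tq, sq, off, EPS)
        res = _decode_subset(
            R, library, keep, valid_full, offsets, exclusion, EPS,
            A=A_full - A_rm, frames=frames,
        )
        return decoding_accuracy(res, lever)

    res_full = _decode_subset(
        R, library, full_set, valid_full, offsets, exclusion, EPS,
        A=A_full, frames=frames,
    )
    r2_full = decoding_accuracy(res_full, lever)
    r2_reduced = r2_without(subset)
    delta = r2_full - r2_reduced

    rng = np.random.default_rng(seed)
    controls = np.empty(n_controls)
    for k in range(n_controls):
        ctrl = rng.choice(control_pool, size=len(subset), replace=False)
        controls[k] = r2_full - r2_without(ctrl)
    return DecodingContribution(
        delta_r2=float(delta),
        controls=controls,
        r2_full=r2_full,
        r2_reduced=r2_reduced,
        seed=seed,
    )
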