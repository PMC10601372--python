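"""Behavioral preprocessing into the canonical 20-variable scheme.

The encoding/decoding analysis describes every session by 20 frame-wise
behavioral variables on the imaging clock: lever position and its two
directional velocities; the lever-independent right-forepaw trace
(RF_lever(-)) in x/y with four directional velocities; left-forepaw x/y with
four directional velocities; jaw position with two directional velocities;
a binary lick train; and a binary reward train.  This module builds that
matrix from raw traces and provides the trial-level analytics (trial
detection, trial averaging, trial-to-trial correlation, cross-session
stability classification, trajectory error).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Canonical column order of the behavior matrix.  ``rf_*`` columns refer to
#: the lever-independent right-forepaw trace RF_lever(-) (see
#: :func:`remove_lever_component`).
CANONICAL_COLUMNS: tuple[str, ...] = (
    "lever_pos",
    "lever_vel_pull",
    "lever_vel_return",
    "rf_x",
    "rf_y",
    "rf_vel_x_pos",
    "rf_vel_x_neg",
    "rf_vel_y_pos",
    "rf_vel_y_neg",
    "lf_x",
    "lf_y",
    "lf_vel_x_pos",
    "lf_vel_x_neg",
    "lf_vel_y_pos",
    "lf_vel_y_neg",
    "jaw_pos",
    "jaw_vel_open",
    "jaw_vel_close",
    "lick",
    "reward",
)

#: Variable categories used for single-category and leave-one-category-out
#: encoding models (sizes 3/6/6/3/1/1).
CATEGORIES: dict[str, tuple[str, ...]] = {
    "lever": ("lever_pos", "lever_vel_pull", "lever_vel_return"),
    "rf_lever_minus": (
        "rf_x", "rf_y",
        "rf_vel_x_pos", "rf_vel_x_neg", "rf_vel_y_pos", "rf_vel_y_neg",
    ),
    "lf": (
        "lf_x", "lf_y",
        "lf_vel_x_pos", "lf_vel_x_neg", "lf_vel_y_pos", "lf_vel_y_neg",
    ),
    "jaw": ("jaw_pos", "jaw_vel_open", "jaw_vel_close"),
    "lick": ("lick",),
    "reward": ("reward",),
}

BINARY_COLUMNS = ("lick", "reward")


@dataclass
class TrackedPoint:
    """A video-tracked body-part trace with per-frame tracking likelihood."""

    position: np.ndarray  # (frames,) or (frames, n_axes), mm
    likelihood: np.ndarray  # (frames,), in [0, 1]

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        self.likelihood = np.asarray(self.likelihood, dtype=float)
        if self.likelihood.ndim != 1:
            raise ValueError("likelihood must be one value per frame")
        if len(self.likelihood) != self.position.shape[0]:
            raise ValueError("position and likelihood length mismatch")
        if np.any(self.likelihood < 0) or np.any(self.likelihood > 1):
            raise ValueError("likelihood values must lie in [0, 1]")


@dataclass
class BehaviorMatrix:
    """Frames x 20 behavior matrix with named columns and an omitted mask."""

    data: np.ndarray  # (frames, 20)
    omitted: np.ndarray  # (frames,) bool, True = frame unusable
    frame_rate: float  # Hz
    columns: tuple[str, ...] = CANONICAL_COLUMNS

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.omitted = np.asarray(self.omitted, dtype=bool)
        if tuple(self.columns) != CANONICAL_COLUMNS:
            raise ValueError("behavior matrix must use the canonical columns")
        if self.data.ndim != 2 or self.data.shape[1] != len(CANONICAL_COLUMNS):
            raise ValueError(
                f"expected {len(CANONICAL_COLUMNS)} columns, got {self.data.shape}"
            )
        if len(self.omitted) != self.n_frames:
            raise ValueError("omitted mask length mismatch")
        for name in BINARY_COLUMNS:
            col = self.data[:, self.column_index(name)]
            if not np.isin(col, (0.0, 1.0)).all():
                raise ValueError(f"column {name!r} must be binary")
        for name in self.columns:
            if "vel_" in name:
                col = self.data[:, self.column_index(name)]
                if np.any(col < 0):
                    raise ValueError(f"directional velocity {name!r} is negative")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    def column_index(self, name: str) -> int:
        return CANONICAL_COLUMNS.index(name)

    def column(self, name: str) -> np.ndarray:
        return self.data[:, self.column_index(name)]

    @classmethod
    def from_traces(
        cls,
        *,
        lever: np.ndarray,
        rf_lever_minus: np.ndarray,  # (frames, 2)
        lf: np.ndarray,  # (frames, 2)
        jaw: np.ndarray,  # (frames,)
        lick: np.ndarray,  # (frames,), binary
        reward: np.ndarray,  # (frames,), binary
        frame_rate: float,
        omitted: np.ndarray | None = None,
    ) -> "BehaviorMatrix":
        """Assemble the canonical matrix, deriving directional velocities.

        Velocities are first-order finite differences on the frame clock
        (prepended with 0 so lengths match), rectified into a non-negative
        forward/backward pair by :func:`split_velocity`.
        """
        lever = np.asarray(lever, dtype=float)
        n = len(lever)

        def vel(x: np.ndarray) -> np.ndarray:
            return np.diff(np.asarray(x, float), prepend=x[0]) * frame_rate

        lv_f, lv_b = split_velocity(vel(lever))
        rf = np.asarray(rf_lever_minus, dtype=float).reshape(n, 2)
        lf = np.asarray(lf, dtype=float).reshape(n, 2)
        rfx_f, rfx_b = split_velocity(vel(rf[:, 0]))
        rfy_f, rfy_b = split_velocity(vel(rf[:, 1]))
        lfx_f, lfx_b = split_velocity(vel(lf[:, 0]))
        lfy_f, lfy_b = split_velocity(vel(lf[:, 1]))
        jaw = np.asarray(jaw, dtype=float)
        jv_f, jv_b = split_velocity(vel(jaw))
        cols = [
            lever, lv_f, lv_b,
            rf[:, 0], rf[:, 1], rfx_f, rfx_b, rfy_f, rfy_b,
            lf[:, 0], lf[:, 1], lfx_f, lfx_b, lfy_f, lfy_b,
            jaw, jv_f, jv_b,
            np.asarray(lick, float), np.asarray(reward, float),
        ]
        if omitted is None:
            omitted = np.zeros(n, dtype=bool)
        return cls(np.column_stack(cols), omitted, frame_rate)


def split_velocity(signed_velocity: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rectify a signed velocity into non-negative (forward, backward) channels.

    ``forward = max(v, 0)``, ``backward = max(-v, 0)``; the two channels are
    mutually exclusive and ``forward - backward`` reconstructs the input.
    """
    v = np.asarray(signed_velocity, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("signed velocity contains non-finite values")
    return np.maximum(v, 0.0), np.maximum(-v, 0.0)


def clean_tracking(
    point: TrackedPoint,
    likelihood_threshold: float = 0.99,
    native_rate: float = 70.0,
    target_rate: float = 30.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Clean a tracked trace and resample it onto the imaging clock.

    Frames with tracking likelihood below ``likelihood_threshold`` are treated
    as ambiguous.  Isolated single ambiguous frames are linearly interpolated
    from the frames before and after; runs of two or more consecutive
    ambiguous frames (and ambiguous frames at the trace boundary) are marked
    omitted.  The cleaned trace is then resampled from ``native_rate`` to
    ``target_rate`` by linear interpolation, and a target-clock frame is
    omitted whenever its interpolation interval touches an omitted native
    frame.

    Returns ``(positions, omitted)`` on the target clock.
    """
    if native_rate < target_rate:
        raise ValueError("native_rate must be >= target_rate")
    pos = np.atleast_2d(point.position.T).T.astype(float).copy()  # (n, k)
    n = pos.shape[0]
    low = point.likelihood < likelihood_threshold
    if low.all():
        raise ValueError("all frames fall below the likelihood threshold")

    good = ~low
    isolated = low.copy()
    isolated[0] = isolated[-1] = False
    if n >= 3:
        isolated[1:-1] &= good[:-2] & good[2:]
    omitted_native = low & ~isolated
    for i in np.flatnonzero(isolated):
        pos[i] = 0.5 * (pos[i - 1] + pos[i + 1])
    # fill omitted runs by interpolation so the resampled trace is continuous;
    # the omitted mask, not the filled values, is what downstream stages use
    if omitted_native.any():
        ok = np.flatnonzero(~omitted_native)
        for k in range(pos.shape[1]):
            pos[omitted_native, k] = np.interp(
                np.flatnonzero(omitted_native), ok, pos[ok, k]
            )

    t_native = np.arange(n) / native_rate
    n_target = int(np.floor(t_native[-1] * target_rate)) + 1
    t_target = np.arange(n_target) / target_rate
    out = np.column_stack(
        [np.interp(t_target, t_native, pos[:, k]) for k in range(pos.shape[1])]
    )
    bad = np.interp(t_target, t_native, omitted_native.astype(float)) > 0.0
    if point.position.ndim == 1:
        out = out[:, 0]
    return out, bad


def remove_lever_component(
    rf: np.ndarray, lever: np.ndarray
) -> tuple[np.ndarray, float]:
    """Subtract the lever-proportional component from a forepaw trace.

    The gain ``g`` minimizing the variance of ``rf - g * lever`` is the
    closed-form least-squares gain cov(rf, lever)/var(lever); the residual is
    uncorrelated with the lever by construction.  Returns
    ``(residual, gain)``.
    """
    rf = np.asarray(rf, dtype=float)
    lever = np.asarray(lever, dtype=float)
    if rf.shape != lever.shape:
        raise ValueError("rf and lever must have the same length")
    lc = lever - lever.mean()
    var = float(lc @ lc)
    if var == 0.0:
        raise ValueError("lever trace is constant; subtraction gain undefined")
    gain = float((rf - rf.mean()) @ lc) / var
    return rf - gain * lever, gain


def binarize_activity(deconvolved: np.ndarray, threshold: float = 0.005) -> np.ndarray:
    """Binarize deconvolved calcium traces: 1 iff the value exceeds ``threshold``."""
    x = np.asarray(deconvolved)
    if np.any(x < 0):
        raise ValueError("deconvolved traces must be non-negative")
    return (x > threshold).astype(np.int8)


def detect_trials(lever: np.ndarray, config) -> pd.DataFrame:
    """Run the self-initiated lever-pull state machine over a lever trace.

    A trial opens at an upward crossing of ``config.pull_threshold`` after the
    lever has stayed at or below threshold for ``config.set_wait_duration``
    (the session starts armed).  The trial is a success iff the lever stays
    strictly above threshold continuously for ``config.hold_duration``; the
    reward command is issued at the frame completing the hold and the reward
    is delivered ``config.reward_delay`` later.  Returning below threshold
    even briefly before the hold completes makes the trial a failure.

    Returns a table with columns ``init_frame`` (int), ``outcome``
    ("success"/"failure"), ``command_frame`` and ``reward_frame`` (float, NaN
    for failures or rewards falling beyond the recording).
    """
    lever = np.asarray(lever, dtype=float)
    n = len(lever)
    rate = config.frame_rate
    hold_frames = int(round(config.hold_duration * rate))
    wait_frames = int(round(config.set_wait_duration * rate))
    delay_frames = int(round(config.reward_delay * rate))
    thr = config.pull_threshold

    rows: list[dict] = []
    below_run = wait_frames  # session starts armed
    state = "idle"  # idle | trial | cooldown
    init = above_run = 0
    for t in range(n):
        above = lever[t] > thr
        if state == "trial":
            if above:
                above_run += 1
                if above_run >= hold_frames:
                    cmd = float(t)
                    rew = cmd + delay_frames
                    rows.append(
                        {
                            "init_frame": init,
                            "outcome": "success",
                            "command_frame": cmd,
                            "reward_frame": rew if rew < n else np.nan,
                        }
                    )
                    state = "cooldown"
            else:
                rows.append(
                    {
                        "init_frame": init,
                        "outcome": "failure",
                        "command_frame": np.nan,
                        "reward_frame": np.nan,
                    }
                )
                state = "idle"
                below_run = 1
        elif state == "cooldown":
            if not above:
                state = "idle"
                below_run = 1
        else:  # idle
            if above:
                if below_run >= wait_frames:
                    state = "trial"
                    init = t
                    above_run = 1
                    if above_run >= hold_frames:  # degenerate sub-frame hold
                        rows.append(
                            {
                                "init_frame": init,
                                "outcome": "success",
                                "command_frame": float(t),
                                "reward_frame": float(t + delay_frames)
                                if t + delay_frames < n
                                else np.nan,
                            }
                        )
                        state = "cooldown"
                else:
                    state = "cooldown"  # unqualified pull: wait it out
                below_run = 0
            else:
                below_run += 1
    # a trial still open at the end of the trace is dropped (unresolved)
    return pd.DataFrame(
        rows, columns=["init_frame", "outcome", "command_frame", "reward_frame"]
    ).astype({"init_frame": int})


def trajectory_error(
    trajectory: np.ndarray,
    reference: np.ndarray,
    frame_rate: float,
    window: float = 0.6,
) -> float:
    """Mean absolute lever-trajectory error over the first ``window`` seconds.

    Both inputs must start at the pull initiation and cover the window.
    """
    w = int(round(window * frame_rate))
    trajectory = np.asarray(trajectory, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if len(trajectory) < w or len(reference) < w:
        raise ValueError("window exceeds trajectory length")
    return float(np.mean(np.abs(trajectory[:w] - reference[:w])))


@dataclass
class TrialAverage:
    """Event-aligned trial average with bookkeeping of dropped events."""

    mean: np.ndarray  # (..., window frames)
    lags: np.ndarray  # seconds relative to the event
    n_events: int
    n_dropped: int


def trial_average(
    signal: np.ndarray,
    events: np.ndarray,
    frame_rate: float,
    window: tuple[float, float] = (-1.0, 3.0),
) -> TrialAverage:
    """Average ``signal`` in windows aligned to event frames.

    ``signal`` is (frames,) or (channels, frames).  Events whose window exits
    the recording are dropped and counted.  NaN samples (e.g. guarded frames
    of an estimated-probability train) are ignored via nanmean.
    """
    signal = np.asarray(signal, dtype=float)
    one_d = signal.ndim == 1
    sig = signal[None, :] if one_d else signal
    n = sig.shape[1]
    lo = int(round(window[0] * frame_rate))
    hi = int(round(window[1] * frame_rate))
    lags = np.arange(lo, hi + 1)
    events = np.asarray(events, dtype=int)
    usable = [e for e in events if e + lo >= 0 and e + hi < n]
    if not usable:
        raise ValueError("no event window fits inside the recording")
    stack = np.stack([sig[:, e + lo : e + hi + 1] for e in usable])  # (ev, ch, w)
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(stack, axis=0)
    if one_d:
        mean = mean[0]
    return TrialAverage(
        mean=mean,
        lags=lags / frame_rate,
        n_events=len(usable),
        n_dropped=len(events) - len(usable),
    )


def _pearson_rows(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise Pearson correlation of two equally shaped 2-D arrays (NaN if constant)."""
    a = a - a.mean(axis=1, keepdims=True)
    b = b - b.mean(axis=1, keepdims=True)
    na = np.linalg.norm(a, axis=1)
    nb = np.linalg.norm(b, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.einsum("ij,ij->i", a, b) / (na * nb)
    r[(na == 0) | (nb == 0)] = np.nan
    return r


@dataclass
class TrialCorrelation:
    """Mean trial-to-trial correlation with its time-shifted null."""

    mean_correlation: float
    null: np.ndarray  # (n_pairs,) time-shifted control correlations
    null_95: float
    significant: bool
    n_pairs: int
    n_excluded: int  # pairs dropped because a trial was constant


def trial_to_trial_correlation(
    aligned_trials: np.ndarray,
    n_pairs: int = 1000,
    seed: int = 0,
    frame_rate: float = 30.0,
    min_shift: float = 0.5,
) -> TrialCorrelation:
    """Mean Pearson correlation over random distinct trial pairs, with a null.

    The null repeats the same pairs with the second trial of each pair
    circularly time-shifted by a random offset uniform over
    ``[min_shift, window_length - min_shift]``.  Pairs involving a constant
    trial have undefined correlation and are excluded (counted).  The
    observed mean is flagged significant when it exceeds the null's 95th
    percentile.
    """
    trials = np.asarray(aligned_trials, dtype=float)
    if trials.ndim != 2 or trials.shape[0] < 2:
        raise ValueError("need at least two aligned trials")
    n_trials, w = trials.shape
    rng = np.random.default_rng(seed)
    i = rng.integers(0, n_trials, size=n_pairs)
    j = rng.integers(0, n_trials - 1, size=n_pairs)
    j[j >= i] += 1  # distinct trials within a pair
    obs = _pearson_rows(trials[i], trials[j])

    lo = int(round(min_shift * frame_rate))
    hi = max(w - lo, lo + 1)
    shifts = rng.integers(lo, hi, size=n_pairs)
    col = (np.arange(w)[None, :] - shifts[:, None]) % w
    shifted = trials[j][np.arange(n_pairs)[:, None], col]
    null = _pearson_rows(trials[i], shifted)

    keep = np.isfinite(obs) & np.isfinite(null)
    if not keep.any():
        raise ValueError("all trial pairs had undefined correlation")
    mean_corr = float(obs[keep].mean())
    null_vals = null[keep]
    p95 = float(np.percentile(null_vals, 95))
    return TrialCorrelation(
        mean_correlation=mean_corr,
        null=null_vals,
        null_95=p95,
        significant=mean_corr > p95,
        n_pairs=int(keep.sum()),
        n_excluded=int((~keep).sum()),
    )


@dataclass
class StabilityResult:
    """Cross-session stability classification against a shuffle null."""

    stable: np.ndarray  # (n_neurons,) bool
    observed: np.ndarray  # (n_neurons,) mean cross-session correlation
    threshold: float  # 95th percentile of the shuffle null
    null: np.ndarray  # (n_shuffles,) null statistics


def _mean_cross_session_corr(traces: np.ndarray) -> np.ndarray:
    """traces (S, N, w) -> per-neuron mean Pearson correlation over session pairs."""
    s = traces.shape[0]
    pair_corrs = []
    for a in range(s):
        for b in range(a + 1, s):
            pair_corrs.append(_pearson_rows(traces[a], traces[b]))
    return np.nanmean(np.stack(pair_corrs), axis=0)


def classify_stable_neurons(
    trial_avg_by_session: np.ndarray,
    n_shuffles: int = 1000,
    seed: int = 0,
    scheme: str = "repair",
) -> StabilityResult:
    """Classify neurons as stable across sessions against a shuffle null.

    A neuron is stable iff the mean Pearson correlation of its trial-averaged
    traces across all session pairs exceeds the 95th percentile of a shuffle
    null.  ``scheme="repair"`` builds each null sample by drawing an
    independent random neuron per session (re-pairing identities);
    ``scheme="circular_shift"`` instead circularly shifts each session's
    trace of a random neuron by a random lag.

    ``trial_avg_by_session`` has shape (n_sessions, n_neurons, window).
    """
    traces = np.asarray(trial_avg_by_session, dtype=float)
    if traces.ndim != 3 or traces.shape[0] < 2:
        raise ValueError("need trial-averaged traces from at least two sessions")
    s, n, w = traces.shape
    rng = np.random.default_rng(seed)

    observed = _mean_cross_session_corr(traces)

    if scheme == "repair":
        idx = rng.integers(0, n, size=(s, n_shuffles))
        shuffled = np.stack([traces[a, idx[a]] for a in range(s)])
    elif scheme == "circular_shift":
        idx = rng.integers(0, n, size=(s, n_shuffles))
        shifts = rng.integers(0, w, size=(s, n_shuffles))
        cols = (np.arange(w)[None, None, :] + shifts[:, :, None]) % w
        shuffled = np.stack(
            [traces[a, idx[a][:, None], cols[a]] for a in range(s)]
        )
    else:
        raise ValueError(f"unknown shuffle scheme {scheme!r}")
    null = _mean_cross_session_corr(shuffled)
    null = null[np.isfinite(null)]
    if null.size == 0:
        raise ValueError("shuffle null is empty (all-constant traces?)")
    threshold = float(np.percentile(null, 95))
    stable = np.where(np.isfinite(observed), observed > threshold, False)
    return StabilityResult(
        stable=stable, observed=observed, threshold=threshold, null=null
    )
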