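"""Synthetic lever-pull sessions with known ground-truth encoding kernels.

The generator emulates the statistical structure of a head-fixed mouse
lever-pull experiment recorded on a 30 Hz imaging clock: self-initiated
lever pulls rewarded after a 2.5 mm threshold is held for 0.6 s (reward
delivered ~176 ms after the success command), uninstructed forepaw, jaw and
lick dynamics partially coupled to the reward, and sparse binary neuronal
activity drawn from a Bernoulli generative twin of the encoding model
(known intercepts and 20 x 21 basis-weight kernels).  Four sessions (two
late learning, two test) are simulated with stable, unstable and pure-noise
neuron subpopulations and a pursued mask held constant across sessions.

The target-zone task variant (adaptive zone half-width ``k^n * 3.5 mm`` plus
a wait-time relaxation) is implemented as a second state machine.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from scipy.optimize import brentq
from scipy.special import expit, logit

from .behavior import (
    BehaviorMatrix,
    detect_trials,
    remove_lever_component,
)

SESSION_IDS = ("LS13", "LS14", "TS1", "TS2")


@dataclass(frozen=True)
class TaskConfig:
    """Task and device constants of the lever-pull experiment."""

    frame_rate: float = 30.0  # Hz, imaging frame clock
    pull_threshold: float = 2.5  # mm, reward threshold from the natural position
    hold_duration: float = 0.6  # s, continuous hold required past threshold
    travel_limit: float = 5.0  # mm, mechanical pull limit
    reward_delay: float = 0.176  # s, command-to-water delay
    set_wait_duration: float = 0.6  # s, sub-threshold wait arming a new trial
    zone_center: float = 5.0  # mm, target-zone center (target-zone variant)
    zone_k: float = 0.995  # per-success decay of the zone half-width
    zone_w0: float = 3.5  # mm, initial zone half-width
    zone_wait_gain: float = 0.004  # mm/s, widening per second of waiting
    t_target: float = 0.2  # s, required continuous in-zone time
    seed: int = 0

    def __post_init__(self) -> None:
        positive = (
            self.frame_rate, self.pull_threshold, self.hold_duration,
            self.travel_limit, self.reward_delay, self.set_wait_duration,
            self.zone_center, self.zone_w0, self.zone_wait_gain, self.t_target,
        )
        if any(v <= 0 for v in positive):
            raise ValueError("all durations and distances must be strictly positive")
        if not 0.0 < self.zone_k < 1.0:
            raise ValueError("zone_k must lie in (0, 1)")


@dataclass
class GroundTruth:
    """Per-neuron generative parameters behind the simulated activity."""

    session_ids: tuple[str, ...]
    kernels: np.ndarray  # (n_sessions, n_neurons, 20, n_bases), log-odds weights
    intercepts: np.ndarray  # (n_sessions, n_neurons), log-odds
    labels: np.ndarray  # (n_neurons,) in {"stable", "unstable", "noise"}
    basis: object  # BasisSet the kernels are expressed in

    def __post_init__(self) -> None:
        noise = self.labels == "noise"
        if noise.any() and np.any(self.kernels[:, noise] != 0):
            raise ValueError("noise-labelled neurons must have all-zero kernels")
        stable = self.labels == "stable"
        if stable.any():
            ref = self.kernels[0, stable]
            for s in range(1, self.kernels.shape[0]):
                if not np.array_equal(self.kernels[s, stable], ref):
                    raise ValueError("stable neurons must keep identical kernels")

    @property
    def n_neurons(self) -> int:
        return self.kernels.shape[1]

    def session_index(self, session_id: str) -> int:
        return self.session_ids.index(session_id)


@dataclass
class SessionBundle:
    """One session: behavior matrix, binary activity, trial table, metadata."""

    behavior: BehaviorMatrix
    activity: np.ndarray | None  # (n_neurons, frames), entries in {0, 1}
    trials: pd.DataFrame
    frame_rate: float
    session_id: str
    pursued: np.ndarray | None = None  # (n_neurons,) bool

    @property
    def n_frames(self) -> int:
        return self.behavior.n_frames

    def validate(self) -> list[str]:
        """Check bundle invariants; returns a list of violations (empty = OK)."""
        problems: list[str] = []
        n = self.n_frames
        if self.activity is not None:
            if not np.isin(self.activity, (0, 1)).all():
                problems.append("activity entries are not all in {0, 1}")
            if self.activity.shape[1] != n:
                problems.append("activity frame count does not match behavior")
        init = self.trials["init_frame"].to_numpy()
        if len(init) and np.any(np.diff(init) <= 0):
            problems.append("trial initiation frames are not strictly increasing")
        for col in ("init_frame", "command_frame", "reward_frame"):
            v = self.trials[col].to_numpy(dtype=float)
            v = v[np.isfinite(v)]
            if len(v) and (v.min() < 0 or v.max() >= n):
                problems.append(f"{col} outside [0, n_frames)")
        if self.pursued is not None and self.activity is not None:
            if len(self.pursued) != self.activity.shape[0]:
                problems.append("pursued mask length does not match neuron count")
        return problems


def target_zone_half_width(n_success: int, t_wait: float, config: TaskConfig) -> float:
    """Adaptive target-zone half-width: ``k^n * w0 + t_wait * gain`` (mm)."""
    if n_success < 0 or t_wait < 0:
        raise ValueError("n_success and t_wait must be non-negative")
    return config.zone_k**n_success * config.zone_w0 + t_wait * config.zone_wait_gain


def _smooth_noise(rng: np.random.Generator, n: int, sigma_frames: float, sd: float) -> np.ndarray:
    x = gaussian_filter1d(rng.standard_normal(n), sigma_frames)
    s = x.std()
    return x * (sd / s) if s > 0 else x


def _generate_lever(
    config: TaskConfig,
    n: int,
    skill: float,
    rng: np.random.Generator,
    success_iti: float = 2.5,
    retry_iti: float = 0.4,
) -> np.ndarray:
    """Smoothed pulse train of lever pulls whose hold statistics follow ``skill``.

    ``success_iti``/``retry_iti`` are the means (s) of the exponential
    component of the gap after rewarded pulls and aborted pulls — the
    session's pace, which varies widely across animals.
    """
    rate = config.frame_rate
    lever = np.zeros(n)
    t = int(rng.uniform(1.0, 3.0) * rate)
    rise = int(round(0.15 * rate))
    fall = int(round(0.25 * rate))
    while t < n - rise - fall - 2:
        success_intent = rng.random() < skill
        if success_intent:
            hold = config.hold_duration + rng.exponential(0.4)
        else:
            hold = rng.uniform(0.15, 0.8 * config.hold_duration)
        hold_frames = int(round(hold * rate))
        amp = rng.uniform(
            config.pull_threshold + 0.7, min(config.travel_limit, config.pull_threshold + 2.2)
        )
        seg = np.concatenate(
            [
                np.linspace(0.0, amp, rise, endpoint=False),
                amp + 0.08 * rng.standard_normal(hold_frames),
                np.linspace(amp, 0.0, fall, endpoint=False),
            ]
        )
        end = min(n, t + len(seg))
        lever[t:end] = np.maximum(lever[t:end], seg[: end - t])
        if success_intent:
            gap = config.set_wait_duration + rng.exponential(success_iti) + 0.5
        else:  # mice retry quickly after an aborted pull
            gap = config.set_wait_duration + rng.exponential(retry_iti) + 0.2
        t = end + int(gap * rate)
    # sub-threshold lever flicks between trials (baseline fidgeting)
    n_flicks = rng.poisson(6.0 * n / rate / 60.0)
    for t0 in rng.integers(0, n - int(rate), size=n_flicks):
        dur = int(rng.uniform(0.3, 0.7) * rate)
        amp = rng.uniform(0.5, 0.95 * config.pull_threshold)
        bump = amp * np.sin(np.linspace(0.0, np.pi, dur)) ** 2
        lever[t0 : t0 + dur] = np.maximum(lever[t0 : t0 + dur], bump[: n - t0])
    lever = gaussian_filter1d(lever, 1.5)
    lever += 0.02 * rng.standard_normal(n)
    return np.clip(lever, 0.0, config.travel_limit)


def simulate_behavior(
    config: TaskConfig,
    duration: float,
    skill: float = 0.7,
    seed: int = 0,
    success_iti: float = 2.5,
    retry_iti: float = 0.4,
) -> SessionBundle:
    """Simulate one session's behavior and trial table (no activity).

    Lever pulls are smoothed random pulses whose hold-duration distribution
    depends on ``skill`` (the probability that a pull is held long enough to
    qualify).  The trial table is derived by running the task state machine
    (:func:`levercode.behavior.detect_trials`) over the generated trace, so
    generator and detector agree by construction.  Jaw and lick bursts follow
    rewards with jittered latency; forepaw traces are a lever-proportional
    component plus independent smooth noise; the right-forepaw columns of the
    behavior matrix are the lever-subtracted residual RF_lever(-).
    """
    if duration < 60.0:
        raise ValueError("duration must be at least 60 s")
    rate = config.frame_rate
    n = int(round(duration * rate))
    rng = np.random.default_rng(seed)

    lever = _generate_lever(config, n, skill, rng, success_iti, retry_iti)
    trials = detect_trials(lever, config)
    reward_frames = (
        trials.loc[trials["outcome"] == "success", "reward_frame"]
        .dropna()
        .to_numpy(dtype=int)
    )
    reward = np.zeros(n)
    reward[reward_frames] = 1.0

    # orofacial dynamics: jaw oscillation bursts and lick trains, partially
    # coupled to reward (bursts follow most rewards with jittered latency,
    # and also occur spontaneously)
    jaw = _smooth_noise(rng, n, 25.0, 0.15)
    lick_p = np.full(n, 0.002)  # rare isolated licks; licking otherwise comes in bouts
    tt = np.arange(n) / rate
    burst_starts = []
    for rf in reward_frames:
        if rng.random() < 0.8:  # partial coupling: some rewards go unlicked
            lat = max(0.0, rng.normal(0.25, 0.12))
            burst_starts.append(rf + int(lat * rate))
    n_spont = rng.poisson(3.0 * n / rate / 60.0)  # ~3 spontaneous bursts/min
    burst_starts.extend(rng.integers(0, n, size=n_spont).tolist())
    for t0 in burst_starts:
        dur = int(rng.uniform(1.0, 2.0) * rate)
        t1 = min(n, t0 + dur)
        if t0 >= n:
            continue
        local = tt[t0:t1] - tt[t0]
        amp = rng.uniform(0.5, 1.1)
        jaw[t0:t1] += amp * np.exp(-local / 0.6) * np.sin(2 * np.pi * 6.0 * local)
        lick_p[t0:t1] = np.maximum(lick_p[t0:t1], 0.25 * np.exp(-local / 0.8))
    lick = (rng.random(n) < lick_p).astype(float)

    rf_raw = np.column_stack(
        [
            0.9 * lever + _smooth_noise(rng, n, 25.0, 0.35),
            0.3 * lever + _smooth_noise(rng, n, 25.0, 0.35),
        ]
    )
    lf = np.column_stack(
        [
            0.05 * lever + _smooth_noise(rng, n, 25.0, 0.30),
            _smooth_noise(rng, n, 25.0, 0.30),
        ]
    )
    rf_minus = np.column_stack(
        [remove_lever_component(rf_raw[:, k], lever)[0] for k in range(2)]
    )

    behavior = BehaviorMatrix.from_traces(
        lever=lever,
        rf_lever_minus=rf_minus,
        lf=lf,
        jaw=jaw,
        lick=lick,
        reward=reward,
        frame_rate=rate,
    )
    return SessionBundle(
        behavior=behavior,
        activity=None,
        trials=trials,
        frame_rate=rate,
        session_id="sim",
    )


def calibrate_intercept(
    eta: np.ndarray, target_rate: float, noise_sd: float = 0.0
) -> float:
    """Intercept such that the mean activation probability equals ``target_rate``.

    With ``noise_sd`` > 0 the marginal probability is the Gaussian mixture
    ``E_z[expit(eta + b + z)]``, evaluated by Gauss-Hermite quadrature.
    """
    if not 0.0 < target_rate < 1.0:
        raise ValueError("target_rate must lie in (0, 1)")
    if noise_sd > 0:
        nodes, weights = np.polynomial.hermite_e.hermegauss(21)
        shifts = noise_sd * nodes
        wts = weights / weights.sum()

        def mean_p(b: float) -> float:
            return float(
                (expit(eta[:, None] + b + shifts[None, :]) @ wts).mean()
            )

    else:

        def mean_p(b: float) -> float:
            return float(expit(eta + b).mean())

    return float(brentq(lambda b: mean_p(b) - target_rate, -40.0, 40.0, xtol=1e-10))


def simulate_activity(
    bundle: SessionBundle,
    truth: GroundTruth,
    design,
    seed: int = 0,
    private_noise: float = 0.6,
) -> np.ndarray:
    """Draw binary activity from the generative twin of the encoding model.

    Each neuron-frame is an independent Bernoulli draw with probability
    ``expit(intercept + kernel . design_row + noise)``, using the session's
    entry in ``truth`` (matched by ``bundle.session_id``).  ``private_noise``
    is the standard deviation (log-odds units) of per-frame Gaussian noise
    private to each neuron; it emulates the overdispersion of real event
    trains relative to any behavioral model (without it the simulated
    activity is exactly realizable by the fitted model family and training
    sets become separable, which no real recording is).
    """
    if design.n_frames != bundle.n_frames:
        raise ValueError("design and behavior frame counts differ")
    # a standalone bundle (not yet assigned a study session id) uses session 0
    s = (
        truth.session_index(bundle.session_id)
        if bundle.session_id in truth.session_ids
        else 0
    )
    rng = np.random.default_rng(seed)
    w = truth.kernels[s].reshape(truth.n_neurons, -1)  # (N, 420)
    eta = truth.intercepts[s][:, None] + w @ design.X.T
    if private_noise > 0:
        eta = eta + private_noise * rng.standard_normal(eta.shape)
    p = expit(eta)
    return (rng.random(p.shape) < p).astype(np.int8)


def _draw_kernel(
    rng: np.random.Generator,
    basis,
    lever_bias: float = 0.7,
    variable_pool: tuple[str, ...] | None = None,
) -> np.ndarray:
    """Random smooth single-variable kernel on the (20, n_bases) weight grid.

    The driven variable is lever position or pull velocity with probability
    ``lever_bias``, otherwise a non-lever continuous variable (or drawn
    uniformly from ``variable_pool`` when given); the weight profile is a
    Gaussian bump over basis centers in the behavioral past (0 to 1.2 s
    before activity).
    """
    from .behavior import CANONICAL_COLUMNS

    w = np.zeros((len(CANONICAL_COLUMNS), basis.n_bases))
    if variable_pool is not None:
        var = rng.choice(list(variable_pool))
    elif rng.random() < lever_bias:
        var = rng.choice(["lever_pos", "lever_vel_pull"])
    else:
        var = rng.choice(["jaw_pos", "lick", "rf_x", "lf_x"])
    vi = CANONICAL_COLUMNS.index(var)
    center = rng.uniform(0.0, 1.2)
    width = rng.uniform(0.3, 0.6)
    profile = np.exp(-0.5 * ((basis.centers - center) / width) ** 2)
    sign = 1.0 if rng.random() < 0.85 else -1.0
    w[vi] = sign * profile
    return w


def make_ground_truth(
    n_neurons: int,
    basis,
    reference_design,
    seed: int = 0,
    stable_frac: float = 0.45,
    noise_frac: float = 0.2,
    target_rate: float = 0.006,
    signal_swing: float = 5.0,
    session_ids: tuple[str, ...] = SESSION_IDS,
    variable_pool: tuple[str, ...] | None = None,
    private_noise: float = 0.6,
) -> GroundTruth:
    """Draw ground-truth kernels and intercepts for a four-session study.

    Stable neurons keep identical kernels (and intercepts) across sessions;
    unstable neurons get an independently resampled kernel per session; noise
    neurons have all-zero kernels.  Kernels are scaled so the linear
    predictor's 99th-percentile excursion above its median on the reference
    session is ``signal_swing`` log-odds units, and intercepts are calibrated
    so the mean activation probability equals ``target_rate``.
    """
    rng = np.random.default_rng(seed)
    n_sessions = len(session_ids)
    labels = np.array(
        ["noise"] * int(round(noise_frac * n_neurons))
        + ["stable"] * int(round(stable_frac * n_neurons)),
        dtype=object,
    )
    labels = np.concatenate([labels, ["unstable"] * (n_neurons - len(labels))])
    rng.shuffle(labels)
    labels = labels.astype("U8")

    X = reference_design.X
    kernels = np.zeros((n_sessions, n_neurons, X.shape[1] // basis.n_bases, basis.n_bases))
    intercepts = np.zeros((n_sessions, n_neurons))

    def scaled(w_raw: np.ndarray) -> np.ndarray:
        eta = X @ w_raw.ravel()
        swing = np.percentile(eta, 99) - np.median(eta)
        if swing <= 0:
            swing = eta.std() + 1e-12
        return w_raw * (signal_swing / swing)

    for i in range(n_neurons):
        if labels[i] == "noise":
            intercepts[:, i] = calibrate_intercept(
                np.zeros(1), target_rate, private_noise
            )
            continue
        if labels[i] == "stable":
            w = scaled(_draw_kernel(rng, basis, variable_pool=variable_pool))
            b = calibrate_intercept(X @ w.ravel(), target_rate, private_noise)
            kernels[:, i] = w
            intercepts[:, i] = b
        else:  # unstable: fresh kernel each session
            for s in range(n_sessions):
                w = scaled(_draw_kernel(rng, basis, variable_pool=variable_pool))
                kernels[s, i] = w
                intercepts[s, i] = calibrate_intercept(
                    X @ w.ravel(), target_rate, private_noise
                )
    return GroundTruth(
        session_ids=tuple(session_ids),
        kernels=kernels,
        intercepts=intercepts,
        labels=labels,
        basis=basis,
    )


def simulate_study(
    config: TaskConfig,
    n_neurons: int,
    seeds: tuple[int, ...],
    duration: float = 1800.0,
    skill: float = 0.8,
    stable_frac: float = 0.45,
    noise_frac: float = 0.2,
    target_rate: float = 0.006,
    signal_swing: float = 5.0,
    pursued_frac: float = 0.3,
    private_noise: float = 0.6,
    variable_pool: tuple[str, ...] | None = None,
) -> tuple[list[SessionBundle], GroundTruth]:
    """Simulate the four-session study (LS13, LS14, TS1, TS2).

    ``seeds`` provides one integer per session; ground-truth and pursued-mask
    randomness derive from the first seed.  The pursued mask is constant
    across sessions.
    """
    from .design import expand_design, gaussian_basis

    if n_neurons < 10:
        raise ValueError("n_neurons must be at least 10")
    if len(seeds) < len(SESSION_IDS):
        raise ValueError(f"need {len(SESSION_IDS)} session seeds")
    basis = gaussian_basis(config.frame_rate)

    bundles = [
        simulate_behavior(config, duration, skill=skill, seed=seeds[k])
        for k in range(len(SESSION_IDS))
    ]
    designs = [expand_design(b.behavior, basis) for b in bundles]
    truth = make_ground_truth(
        n_neurons,
        basis,
        designs[0],
        seed=seeds[0] + 10_000,
        stable_frac=stable_frac,
        noise_frac=noise_frac,
        target_rate=target_rate,
        signal_swing=signal_swing,
        variable_pool=variable_pool,
        private_noise=private_noise,
    )
    meta_rng = np.random.default_rng(seeds[0] + 20_000)
    pursued = meta_rng.random(n_neurons) < pursued_frac

    out = []
    for k, (bundle, dsg) in enumerate(zip(bundles, designs)):
        bundle.session_id = SESSION_IDS[k]
        bundle.activity = simulate_activity(
            bundle, truth, dsg, seed=seeds[k] + 30_000, private_noise=private_noise
        )
        bundle.pursued = pursued
        out.append(bundle)
    return out, truth


def target_zone_trials(
    lever: np.ndarray,
    config: TaskConfig,
    ready_threshold: float = 0.5,
    iti_hold: float = 1.0,
    response_period: float = 1.0,
    outcome_hold: float = 2.0,
) -> pd.DataFrame:
    """Run the target-zone task state machine over a lever trace.

    States: ITI (hold below ``ready_threshold`` for ``iti_hold``; pulls reset
    the timer) -> Ready -> Go on threshold crossing (``response_period`` to
    hold the lever continuously inside the adaptive target zone for
    ``config.t_target``) -> Success (immediate reward) or Failure; both
    outcome states last ``outcome_hold`` with lever ignored.  The zone
    half-width follows :func:`target_zone_half_width` with ``n`` the
    cumulative successes and ``t_wait`` the time since the last reward.
    """
    lever = np.asarray(lever, dtype=float)
    n = len(lever)
    rate = config.frame_rate
    iti_frames = int(round(iti_hold * rate))
    resp_frames = int(round(response_period * rate))
    tgt_frames = int(round(config.t_target * rate))
    out_frames = int(round(outcome_hold * rate))

    rows: list[dict] = []
    state = "iti"
    below_run = 0
    n_success = 0
    last_reward_frame: int | None = None
    go_start = in_zone_run = state_until = 0
    half_width = config.zone_w0
    for t in range(n):
        if state == "iti":
            if lever[t] > ready_threshold:
                below_run = 0
            else:
                below_run += 1
                if below_run >= iti_frames:
                    state = "ready"
        elif state == "ready":
            if lever[t] > ready_threshold:
                t_wait = (
                    (t - last_reward_frame) / rate if last_reward_frame is not None else 0.0
                )
                half_width = target_zone_half_width(n_success, t_wait, config)
                state = "go"
                go_start = t
                in_zone_run = 0
        if state == "go":
            lo = config.zone_center - half_width
            hi = config.zone_center + half_width
            if lo <= lever[t] <= hi:
                in_zone_run += 1
            else:
                in_zone_run = 0
            if in_zone_run >= tgt_frames:
                n_success += 1
                last_reward_frame = t
                rows.append(
                    {
                        "init_frame": go_start,
                        "outcome": "success",
                        "reward_frame": float(t),
                        "half_width": half_width,
                    }
                )
                state = "outcome"
                state_until = t + out_frames
            elif t - go_start + 1 >= resp_frames:
                rows.append(
                    {
                        "init_frame": go_start,
                        "outcome": "failure",
                        "reward_frame": np.nan,
                        "half_width": half_width,
                    }
                )
                state = "outcome"
                state_until = t + out_frames
        elif state == "outcome":
            if t >= state_until:
                state = "iti"
                below_run = 0
    return pd.DataFrame(
        rows, columns=["init_frame", "outcome", "reward_frame", "half_width"]
    )
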