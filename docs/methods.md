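# Methods

This note documents the models and procedures implemented in `levercode`,
the assumptions behind the synthetic-session generator, the numerical
choices, and the points where the design was genuinely open.

## Task and data model

Sessions live on a single 30 Hz frame clock (the imaging clock). A session
bundle holds a frames × 20 behavior matrix, a neurons × frames binary
activity matrix, and a trial table. The self-initiated lever-pull rule:
after the lever has stayed at or below the 2.5 mm threshold for the set
wait duration (default 0.6 s, the value used in imaging sessions), an
upward threshold crossing opens a trial; holding strictly above threshold
continuously for 0.6 s issues the reward command, and the water reward
arrives 176 ms later; returning below threshold even for one frame first
makes the trial a failure. Travel is limited to 5 mm. The target-zone
variant is a five-state machine (ITI → Ready → Go → Success/Failure) whose
adaptive zone half-width is `k^n × 3.5 mm + T_wait × 0.004 mm` with
`k = 0.995`, `n` the cumulative successes and `T_wait` the seconds since
the last reward.

The 20 behavioral variables are: lever position and its two rectified
directional velocities; the lever-independent right-forepaw trace
RF_lever(−) in x/y with four directional velocities; left-forepaw x/y with
four directional velocities; jaw position with two directional velocities;
and binary lick and reward trains. Velocities are first-order finite
differences on the frame clock, split into non-negative forward/backward
channels (the difference of the two channels reconstructs the signed
velocity exactly). RF_lever(−) subtracts the gain `cov(rf, lever)/var(lever)`
— the closed-form minimizer of the residual's variance — leaving a residual
with zero covariance with the lever. Tracked points are cleaned by linearly
interpolating isolated frames whose tracking likelihood falls below 0.99,
marking runs of two or more such frames (and boundary frames) omitted, and
linearly resampling from the camera clock to the imaging clock; omitted
native frames propagate to every target frame whose interpolation interval
touches them. Deconvolved traces are binarized with a strict `> 0.005`
threshold (the boundary convention is ours; binarization is idempotent).

## Temporal basis and design matrix

Each variable is convolved with 21 unit-peak Gaussian basis functions with
centers −3.0 … +3.0 s in 0.3 s steps and half-width at half-height 0.52 s
(σ = 0.52/√(2 ln 2) ≈ 0.442 s), truncated at ±3σ from each center. A
separately quoted 0.2 s scale for these functions is inconsistent with the
0.52 s half-width under the standard σ convention; we fix the half-width
and record the discrepancy rather than guess a nonstandard
parameterization. Either reading satisfies the adjacent-regressor overlap
bound (≥ 0.53 when a unit impulse is expanded; our basis gives
exp(−d²/4σ²) ≈ 0.885 at d = 0.3 s), the regime that keeps the penalized
fits stable. Sign convention: a basis centered at +c s lets activity at
time t depend on behavior at t − c, so fitted kernels read as "behavior
preceding activity"; the convention is flippable via
`BasisSet.past_positive`. Design rows whose lag window touches an omitted
behavior frame are masked and excluded from all fits and scores. The full
design has 20 × 21 = 420 columns; category subsets (lever 3, RF_lever(−) 6,
LF 6, jaw 3, lick 1, reward 1 variables) have 21 × size columns.

## Encoding model

Per neuron, a Bernoulli GLM with the elastic-net objective

    mean NLL + λ (α‖w‖₁ + (1 − α)/2 ‖w‖₂²),   α = 0.2, λ = 1e-4,

columns standardized before fitting (weights mapped back), intercept
unpenalized. The optimizer is box-constrained L-BFGS-B on the smooth
split-variable form (w = u − v with u, v ≥ 0), which handles the L1 kink
exactly; a test pins the optimum against an independent convex solver run
to high precision, so the implementation is tied to the stated objective
rather than to any solver's default scaling.

Cross-validation under class imbalance (positive frames ≈ 0.6% of the
session): positives are split in temporal order into 10 contiguous blocks;
fold f trains on the other nine blocks plus 1% of the negative frames
sampled without replacement (per fold, seeded) and scores the held-out
block plus the remaining negatives. Negative test frames within 2 s of the
fold's training **positives** are excluded from scoring. Two readings of
this guard were considered: (i) around all training frames, and (ii)
around training positives only. Reading (i) is unusable in principle —
1% of negatives × (±2 s = 121 frames) exceeds the session length, so the
guard blankets nearly every frame for every neuron independently and no
frame retains cross-validated estimates for a whole population, leaving
the decoder without a library at any session length. We therefore default
to (ii), which guards the frames whose temporally autocorrelated activity
can actually leak; (i) remains available via `guard_scope="all"`. Held-out
positives are always scored, so the union of test positives over folds
covers every positive frame. Negatives scored in several folds take the
median estimate.

Because the training sample is rebalanced (≈ 90% of positives vs 1% of
negatives), the raw fit's intercept reflects the sample, not the session.
Predictions apply the standard case-control prior correction — the
intercept is shifted by −log(s_pos/s_neg), the log ratio of the class
sampling fractions — so the concatenated probability train is calibrated.
Without this the estimates saturate (p̂ ≈ 0.3–0.9 on a 0.6%-positive
train), which distorts trial-averaged prediction shapes and makes the
likelihood comparisons meaningless.

Per-frame likelihood is `1 − |r − p̂|` (the Bernoulli likelihood for binary
r); the session summary `mean_likelihood` is the **geometric** mean, i.e.
exp of the mean per-frame log-likelihood. Under this proper score the
calibrated intercept-only null sits at exp(−H(rate)) ≈ 0.95–0.96 for rates
near 0.006–0.01 and a genuinely informative model beats it; under the
arithmetic mean, p̂ → 0 would dominate and even the data-generating model
would score below the null. A neuron is *elusive* when its full model's
mean cross-validated likelihood does not exceed the null's; the null is
the same fold machinery with a single constant (the corrected
training-positive fraction, i.e. the session rate).

The model-comparison statistic is evaluated on the conservatively guarded
frames — held-out positives plus negatives at least 2 s from *any*
same-fold training frame — identical for both models. The motivation is
quantitative: at desk scale, a small fraction (≈ 0.5–2%) of wide-coverage
baseline frames carries systematically overconfident junk predictions
(shared across folds, because folds share nine-tenths of their training
positives, so the cross-fold median cannot damp it), and its log-score
cost exceeds the entire mutual-information margin a true model of a
0.6–1%-rate neuron has over the null. On the maximally leakage-free set
the comparison behaves as it should: strongly driven neurons beat the
null, pure-noise neurons do not.

Prediction accuracy is the squared Pearson correlation between
trial-averaged binarized activity and trial-averaged estimated probability
in the −1 … +3 s window around successful pull initiations (events whose
window exits the recording are dropped and counted; a constant average is
flagged and scored 0). Encoding unique contribution of a category is
`max(R²_full − R²_without_category, 0)`; single-category models bound the
maximum contribution from above. Per-variable temporal kernels are the
weight-weighted sums of the sampled basis functions, with the session
kernel the element-wise median over the 10 fold fits; kernel consistency
is the between-session Pearson correlation per variable, with identically
zero (or constant) kernels excluded and counted.

## Ranking and rank stability

Within a session of N neurons ranked by accuracy (elusive accuracies
forced to 0 first), neuron at rank R gets normalized rank (N − R + 1)/N.
Ties break deterministically by neuron index; elusive neurons sort
strictly below all others, by index among themselves — only their
collective bottom position matters. Top-percentile groups are selected
from pursued neurons by half-open normalized-rank bands `(low, high]`, so
adjacent bands partition cleanly; the top-20% group is `(0.8, 1.0]`.
Rank stability of a group in a later session compares its mean normalized
rank with the 2.5th/97.5th percentiles of means over 10,000 random
same-size draws (without replacement) from a configurable pool — all
neurons of the session, or all pursued neurons; both pools are exposed
because either is defensible.

## Decoding

The decoder marginalizes over the session's realized behavioral states:
library frame s carries the lever value x_s and each neuron's calibrated
cross-validated probability. The population likelihood is the product
`Π_i (1 − |r̄_{i,t} − P(r_i,s)|)`, extended over the seven offsets
(−6, −4, −2, 0, +2, +4, +6 frames at 30 Hz; scaled by the rate ratio and
rounded for other clocks), with library probabilities taken at s + offset.
The decoded position is the likelihood-weighted average of library lever
values over all admissible s, which is always inside the convex hull of
the library. Admissibility: the library frame (and its offset window) must
have estimates for every used neuron, and |s − t| must exceed 3.3 s. The
uniform prior constant cancels and is never materialized. Products are
accumulated in log space with per-factor flooring at ε = 1e-12; the
log-likelihood matrix is assembled as offset-wise matrix products over
(query, library) frames, and because it is additive over neurons, removal
analyses subtract the removed subset's matrix from the full population's
— the exact result at a fraction of the cost. A `query_stride` option
decodes every k-th frame; summary R² values need temporal coverage, not
every frame. Decoding accuracy is the squared Pearson correlation between
decoded and recorded lever over decoded frames (≥ 100 required). The
decoding unique contribution of a group is R²(full) − R²(full minus
group), compared against 100 seeded same-size random removals drawn from
the configured control pool.

## Synthetic sessions and what they do (not) show

The generator is a generative twin of the encoding model: behavior is
simulated first, expanded with the canonical basis, and each neuron-frame
is an independent Bernoulli draw of
`expit(intercept + kernel · design_row + ξ)`. Its purpose is ground-truth
validation — kernels, labels and rates are known exactly — not biological
realism.

Conditions and the reasoning behind them (all seeded; identical seeds give
identical bundles):

- **Lever pulls** are smoothed random pulses: 0.15 s rise, hold at
  3.2–4.7 mm with small jitter, 0.25 s release. A pull qualifies for
  reward with probability `skill`; qualifying holds last 0.6 s plus an
  exponential 0.4 s tail, aborted pulls 0.15–0.48 s. Successful trials are
  followed by exponential gaps (mean `success_iti`, default 2.5 s, plus a
  fixed 1.1 s including the set wait); aborted pulls are retried quickly
  (mean `retry_iti`, default 0.4 s), and sub-threshold flicks (≈ 6/min,
  0.5–2.4 mm) provide baseline lever fidgeting. The pace parameters model
  the wide across-animal variation in self-initiated trial rates. The
  trial table is produced by running the detector state machine over the
  generated trace, so generator and detector agree exactly by construction.
- **Orofacial/forepaw dynamics** are partially reward-coupled: jaw
  oscillation bursts (6 Hz, 1–2 s) and lick bouts follow 80% of rewards at
  jittered ~0.25 s latency and also occur spontaneously (~3/min); isolated
  licks outside bouts are rare (0.002/frame). Forepaw traces are a
  lever-proportional component plus independent smooth noise with ≈ 0.8 s
  autocorrelation (postural drift); the behavior matrix carries the
  lever-subtracted residual. The partial coupling and the within-window
  lever events (retries, flicks, neighboring trials) are what let the
  contribution analysis distinguish lever-driven activity from
  reward-locked mimicry — with perfectly stereotyped single-pull trials,
  trial-averaged metrics cannot separate event-locked regressors, in this
  or any dataset.
- **Ground-truth kernels** drive one variable per neuron (lever position
  or pull velocity by default, with a 30% minority on jaw/lick/forepaw
  when no pool is forced) through a Gaussian bump over basis centers 0 to
  1.2 s in the behavioral past. Kernels are scaled so the linear
  predictor's 99th-percentile excursion over its median is 5 log-odds
  units — a strongly task-locked neuron whose in-pull event probability is
  tens of times its baseline, as task neurons in binarized deconvolved
  calcium data are. Intercepts are calibrated by root finding (with
  Gauss–Hermite quadrature over the private noise) so the mean event rate
  hits the target (default 0.006, the empirical positive-frame fraction of
  such recordings).
- **Private noise** (per-frame Gaussian on the log-odds, σ = 1 default in
  `simulate_activity`, 0.6 in study presets) emulates the overdispersion of
  real event trains relative to any behavioral model. Without it the
  simulated activity is exactly realizable by the fitted model family and
  rebalanced training sets become separable — a regime no real recording
  is in.
- **Four-session studies** (LS13, LS14, TS1, TS2 — two late learning and
  two post-gap test sessions) share stable neurons' kernels and intercepts
  exactly, resample unstable neurons' kernels independently per session,
  keep noise neurons at zero kernels, and hold the pursued mask constant.

What passing tests show: the estimators recover the quantities they claim
to estimate when their assumptions hold, the CV/guard/exclusion hygiene is
enforced structurally, and the resampling tests are calibrated. What they
do not show: robustness to model misspecification beyond log-odds noise
(bursting, adaptation, slow drift), to correlated noise across neurons, or
to tracking artifacts beyond the likelihood-based cleaning rules.

## Problem sizes

Tests and the worked examples run reduced studies chosen as the smallest
sizes at which each property is measurable: 51,000-frame sessions
(1700 s) with 20 neurons at rate 0.01 for kernel recovery and elusive
classification; a fast-paced 51,000-frame session (trial cycle ≈ 4.5 s)
with 8 lever-only neurons for the encoding-contribution ordering — the
ordering is carried by lever events inside the ±(1–3) s trial-average
window (retries, flicks, neighboring pulls), which must be frequent
enough to resolve above model-refit noise; 18,000-frame sessions with 8
informative + 22 noise neurons for decoding contributions (decoded on a
4-frame query grid); 1000 repetitions at 500 draws for the rank-stability
calibration; and a 150 s × 12-neuron end-to-end pipeline run. The
generator's own defaults remain full scale (1800 s, rate 0.006).

## Known limitations

- The behavioral agent is statistical, not biomechanical; lever kinematics
  beyond the pulse structure (force, compliance) are not modeled.
- The generator emits binarized activity directly; there is no
  calcium-indicator forward model or deconvolution step.
- Decoding marginalizes only over states realized in the session; in
  short sessions with few admissible library frames the decoded range is
  compressed toward the library mean.
- `kernel_consistency` compares fitted kernels per variable; with strongly
  correlated task regressors, weight sharing among them is expected and
  per-variable kernels of *all* variables should not be read as causal
  attributions (the contribution statistics exist for that).
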