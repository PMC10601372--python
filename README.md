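# levercode

Encoding and decoding analysis of motor-cortex population activity during a
head-fixed lever-pull task, as a tested, reusable Python library — together
with a synthetic-session generator that reproduces the statistical structure
of such experiments with known ground truth.

## Who this is for

Systems neuroscientists analyzing chronic two-photon calcium imaging (or any
sparse binarized activity) recorded while an animal performs a self-initiated
lever-pull task: binary activity trains at the imaging frame rate, video-
tracked body parts, and a trial structure defined by a threshold-and-hold
rule. The library covers the full analysis chain — behavioral preprocessing,
per-neuron encoding models, contribution and rank-stability statistics, and
population decoding — and ships a generative twin of the experiment so every
stage can be validated against known parameters.

## The model

**Encoding.** Each neuron's binarized activity r_i(t) ∈ {0, 1} is modeled as
a Bernoulli GLM over 20 behavioral variables (lever position and directional
velocities; lever-independent right-forepaw position/velocities; left-forepaw
position/velocities; jaw position/velocities; lick and reward trains), each
convolved with 21 Gaussian temporal basis functions (centers −3.0 … +3.0 s in
0.3 s steps, half-width at half-height 0.52 s):

    P(r_i = 1 | x, x̃) = σ( b_i + Σ_{v,j} w_{i,v,j} · (x_v * g_j)(t) )

fitted with elastic-net regularization (α = 0.2, λ = 1e-4), the penalty
`λ(α‖w‖₁ + (1−α)/2‖w‖₂²)` on standardized columns, intercept unpenalized.
Because positive frames are rare (~0.6%), each of 10 CV folds trains on
nine-tenths of the positives (contiguous in order) plus 1% of the negatives,
with a 2 s anti-leakage guard on scoring and a case-control intercept
correction so the concatenated cross-validated probability train is
calibrated. Neurons whose full model does not beat an intercept-only null in
mean cross-validated likelihood are "elusive". Prediction accuracy is the
squared correlation of trial-averaged activity and trial-averaged estimate in
the −1 … +3 s window around rewarded pull initiations; the encoding unique
contribution of a variable category is ΔR² = max(R²_full − R²_without, 0).

**Ranking.** Within a session of N neurons, accuracy rank R maps to the
normalized rank (N − R + 1)/N (best = 1, worst = 1/N; elusive neurons forced
to the bottom). Group-level rank stability across sessions is tested against
the 97.5th percentile of mean normalized ranks of 10,000 random same-size
populations.

**Decoding.** The lever trajectory is decoded by Bayesian marginalization
over the session's own realized behavioral states: with the library of
cross-validated encoding probabilities P(r_i,s | x_s, x̃_s),

    P(r̄_t | x_s, x̃_s) = Π_i (1 − |r̄_{i,t} − P(r_i,s | x_s, x̃_s)|)
    x̂_t = Σ_s x_s P(r̄_t | x_s, x̃_s) / Σ_s P(r̄_t | x_s, x̃_s)

with the population vector extended over seven temporal offsets
(t−6, t−4, t−2, t, t+2, t+4, t+6 frames) and library frames within 3.3 s of
t excluded. The decoding unique contribution of a neuron group is the R²
drop when it is removed, compared against 100 same-size random removals.

## Worked example

```python
import levercode as lc
from levercode import encoding as enc
from levercode.design import expand_design, gaussian_basis
from levercode.task import make_ground_truth, simulate_activity

config = lc.TaskConfig()                      # 2.5 mm threshold, 0.6 s hold
bundle = lc.simulate_behavior(config, duration=1700.0, skill=0.8, seed=2)
basis = gaussian_basis(config.frame_rate)
design = expand_design(bundle.behavior, basis)
truth = make_ground_truth(10, basis, design, seed=3, target_rate=0.01,
                          stable_frac=1.0, noise_frac=0.0,
                          variable_pool=("lever_pos",))
activity = simulate_activity(bundle, truth, design, seed=4)

plan = enc.plan_folds(activity[0], seed=5)
cv = enc.cv_estimate(activity[0], design.X, plan)
elusive, null = enc.fit_null_and_classify(activity[0], plan, cv)
events = bundle.trials.query("outcome == 'success'")["init_frame"].to_numpy()
print(cv.mean_likelihood, null.mean_likelihood,
      enc.prediction_accuracy(cv, activity[0], events))
```

Running `python examples/02_encoding_model.py` (which is this example with
reporting) prints:

```
design: 51000 frames x 420 regressors
neuron 0: 458 positive frames (0.0090 of the session)
mean CV likelihood: full 0.9361 vs null 0.9297 -> modelable
trial-averaged prediction accuracy (cross-validated R^2): 0.871
fitted lever kernel vs generative kernel: r = 0.792
```

The full model's cross-validated likelihood exceeds the intercept-only
null's, so the neuron is modelable; its trial-averaged activity is predicted
with R² = 0.87; and the fitted lever kernel recovers the generative temporal
dependency with r = 0.79. The other scripts in `examples/` walk through
session simulation, rank stability, and population decoding the same way.

A batch front end exists for shell use:
`levercode run --config config.yaml --out rundir` simulates a four-session
study and writes encoding tables, rank tables, stability and contribution
summaries, and a decoded-trajectory figure; `simulate`, `encode`, `rank`,
`decode`, `report` and `validate` expose the individual stages.

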