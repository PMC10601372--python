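"""Shared fixtures: synthetic sessions at the scales the tests need.

The heavy session-scoped fixtures are computed once: a four-session study
with ground-truth kernels (50k+ frames per session) whose first session is
fully encoded, and a short decoding session with a known informative/noise
split.  Everything is seeded; no fixture touches the filesystem.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest

import levercode as lc
from levercode import encoding as enc
from levercode.design import expand_design, gaussian_basis
from levercode.task import make_ground_truth, simulate_activity


@pytest.fixture(scope="session")
def task_config() -> lc.TaskConfig:
    return lc.TaskConfig()


@pytest.fixture(scope="session")
def basis():
    return gaussian_basis(30.0)


@pytest.fixture(scope="session")
def small_bundle(task_config):
    """A 2-minute behavior-only session for structural tests."""
    return lc.simulate_behavior(task_config, 120.0, skill=0.8, seed=11)


@pytest.fixture(scope="session")
def study(task_config):
    """Four-session study: 20 neurons, 51k frames/session, rate 0.01."""
    return lc.simulate_study(
        task_config,
        n_neurons=20,
        seeds=(2, 3, 4, 5),
        duration=1700.0,
        skill=0.8,
        stable_frac=0.5,
        noise_frac=0.2,
        target_rate=0.01,
        pursued_frac=0.6,
    )


@dataclass
class EncodedSession:
    bundle: object
    design: object
    truth: object
    events: np.ndarray
    plans: dict
    cvs: dict
    elusive: dict
    accuracies: dict

    def driven_variable(self, i: int) -> int:
        W = self.truth.kernels[0, i]
        return int(np.argmax(np.abs(W).sum(axis=1)))


@pytest.fixture(scope="session")
def encoded_ls13(study, basis) -> EncodedSession:
    """Full-model CV fits for every neuron of the study's first session."""
    bundles, truth = study
    b = bundles[0]
    design = expand_design(b.behavior, basis)
    events = b.trials.loc[b.trials["outcome"] == "success", "init_frame"].to_numpy()
    plans, cvs, elusive, accs = {}, {}, {}, {}
    for i in range(truth.n_neurons):
        r = b.activity[i]
        plan = enc.plan_folds(r, seed=600 + i)
        cv = enc.cv_estimate(r, design.X, plan)
        el, _ = enc.fit_null_and_classify(r, plan, cv)
        plans[i], cvs[i], elusive[i] = plan, cv, el
        accs[i] = enc.prediction_accuracy(cv, r, events)
    return EncodedSession(
        bundle=b, design=design, truth=truth, events=events,
        plans=plans, cvs=cvs, elusive=elusive, accuracies=accs,
    )


@pytest.fixture(scope="session")
def contribution_setup(task_config, basis) -> EncodedSession:
    """Fast-paced session (trial cycle ~4.5 s) with 8 lever-only neurons.

    The encoding-contribution analysis separates lever-driven activity from
    reward-locked mimicry only through lever events inside the trial-average
    window (retries, flicks, neighboring pulls); the fast pace makes those
    events frequent enough for the ordering to resolve above refit noise at
    this session length.
    """
    b = lc.simulate_behavior(task_config, 1700.0, skill=0.8, seed=2,
                             success_iti=1.5)
    design = expand_design(b.behavior, basis)
    truth = make_ground_truth(
        8, basis, design, seed=40, target_rate=0.01,
        stable_frac=1.0, noise_frac=0.0,
        variable_pool=("lever_pos", "lever_vel_pull"),
    )
    b.activity = simulate_activity(b, truth, design, seed=41)
    events = b.trials.loc[b.trials["outcome"] == "success", "init_frame"].to_numpy()
    plans, cvs, elusive, accs = {}, {}, {}, {}
    for i in range(8):
        r = b.activity[i]
        plan = enc.plan_folds(r, seed=80 + i)
        cv = enc.cv_estimate(r, design.X, plan, keep_fits=False)
        el, _ = enc.fit_null_and_classify(r, plan, cv)
        plans[i], cvs[i], elusive[i] = plan, cv, el
        accs[i] = enc.prediction_accuracy(cv, r, events)
    return EncodedSession(
        bundle=b, design=design, truth=truth, events=events,
        plans=plans, cvs=cvs, elusive=elusive, accuracies=accs,
    )


@dataclass
class DecodeSetup:
    bundle: object
    truth: object
    library: object
    informative: np.ndarray
    noise: np.ndarray
    full_set: np.ndarray


@pytest.fixture(scope="session")
def decode_setup(task_config, basis) -> DecodeSetup:
    """Mid-length session (18k frames) with 8 informative and 22 noise
    neurons, encoded so the CV probability trains form the decoder's
    library.  Shorter sessions leave too few frames where every neuron has
    a cross-validated estimate (the 2 s guard blankets them); the large
    noise pool gives the removal-control draws real diversity."""
    b = lc.simulate_behavior(task_config, 600.0, skill=0.8, seed=21)
    design = expand_design(b.behavior, basis)
    truth = make_ground_truth(
        30, basis, design, seed=22, stable_frac=8 / 30, noise_frac=22 / 30,
        target_rate=0.012, variable_pool=("lever_pos", "lever_vel_pull"),
    )
    b.activity = simulate_activity(b, truth, design, seed=23)
    probs = np.full((30, b.n_frames), np.nan)
    for i in range(30):
        r = b.activity[i]
        plan = enc.plan_folds(r, seed=700 + i)
        cv = enc.cv_estimate(r, design.X, plan, keep_fits=False)
        probs[i] = cv.prob
    library = lc.build_library(probs, b.behavior.column("lever_pos"), b.frame_rate)
    informative = np.flatnonzero(truth.labels != "noise")
    noise = np.flatnonzero(truth.labels == "noise")
    return DecodeSetup(
        bundle=b, truth=truth, library=library,
        informative=informative, noise=noise, full_set=np.arange(30),
    )
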