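"""End-to-end study driver: simulate -> encode -> rank -> decode -> report.

Runs the whole analysis on a synthetic four-session study and writes tables
(CSV/JSON), bundles and kernels (HDF5), a log, and a summary figure into a
run directory.  Every random draw is traceable to a named seed in the
configuration; identical configurations produce identical outputs.  The
slow stages (simulation and encoding) are cached: a rerun into the same
directory with an unchanged configuration hash resumes from their outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from . import behavior as bhv
from . import decoding as dec
from . import encoding as enc
from . import ranking as rnk
from .design import expand_design, gaussian_basis
from .io import load_bundle, save_bundle, save_trials_csv
from .task import SESSION_IDS, SessionBundle, TaskConfig, simulate_study

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Full configuration of an end-to-end run (seeds explicit per stage)."""

    task: TaskConfig = field(default_factory=TaskConfig)
    n_neurons: int = 60
    duration: float = 1200.0  # s per session
    skill: float = 0.8
    session_seeds: tuple[int, ...] = (11, 12, 13, 14)
    stable_frac: float = 0.45
    noise_frac: float = 0.2
    target_rate: float = 0.006
    signal_swing: float = 5.0
    pursued_frac: float = 0.5
    # GLM / CV
    alpha: float = enc.ALPHA
    lam: float = enc.LAMBDA
    n_folds: int = enc.N_FOLDS
    neg_fraction: float = enc.NEG_FRACTION
    guard: float = enc.GUARD_SECONDS
    guard_scope: str = "positives"
    fold_seed: int = 101
    # ranking
    top_band: tuple[float, float] = (0.8, 1.0)
    n_rank_draws: int = 10_000
    rank_pool: str = "all"  # "all" or "pursued"
    rank_seed: int = 202
    # decoding
    offsets: tuple[int, ...] = dec.OFFSETS
    exclusion: float = dec.EXCLUSION_SECONDS
    n_decode_controls: int = 100
    decode_seed: int = 303
    # scope switches
    do_category_models: bool = False
    do_decode_contribution: bool = True

    def __post_init__(self) -> None:
        if self.n_neurons <= 0:
            raise ValueError("n_neurons must be positive")
        if len(self.session_seeds) < len(SESSION_IDS):
            raise ValueError(f"need {len(SESSION_IDS)} session seeds")
        if self.rank_pool not in ("all", "pursued"):
            raise ValueError("rank_pool must be 'all' or 'pursued'")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["session_seeds"] = list(self.session_seeds)
        d["top_band"] = list(self.top_band)
        d["offsets"] = list(self.offsets)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "task" in d and isinstance(d["task"], dict):
            d["task"] = TaskConfig(**d["task"])
        for k in ("session_seeds", "top_band", "offsets"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as f:
            yaml.safe_dump(self.to_dict(), f, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as f:
            return cls.from_dict(yaml.safe_load(f))

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def _stage_cached(outdir: Path, stage: str, digest: str) -> bool:
    m = outdir / "manifest.json"
    if not m.exists():
        return False
    manifest = json.loads(m.read_text())
    return manifest.get("stages", {}).get(stage) == digest


def _mark_stage(outdir: Path, stage: str, digest: str) -> None:
    m = outdir / "manifest.json"
    manifest = json.loads(m.read_text()) if m.exists() else {"stages": {}}
    manifest.setdefault("stages", {})[stage] = digest
    m.write_text(json.dumps(manifest, indent=2, sort_keys=True))


def _success_events(bundle: SessionBundle) -> np.ndarray:
    t = bundle.trials
    return t.loc[t["outcome"] == "success", "init_frame"].to_numpy(dtype=int)


@dataclass
class SessionEncoding:
    """Per-session encoding-stage outputs."""

    table: pd.DataFrame  # neuron, elusive, skipped, full R2, likelihoods, [DR2]
    cv_probs: np.ndarray  # (n_neurons, frames), NaN where unscored/skipped
    kernels: np.ndarray  # (n_neurons, 20, n_lags), zeros for skipped neurons


def encode_session(
    bundle: SessionBundle, config: PipelineConfig, basis=None
) -> SessionEncoding:
    """Fit the full (and optional category) models for every neuron."""
    basis = basis or gaussian_basis(config.task.frame_rate)
    design = expand_design(bundle.behavior, basis)
    events = _success_events(bundle)
    n_neurons, n_frames = bundle.activity.shape
    lags, _ = basis.sample()
    cv_probs = np.full((n_neurons, n_frames), np.nan)
    kernels = np.zeros((n_neurons, len(bhv.CANONICAL_COLUMNS), len(lags)))
    valid = ~design.omitted

    rows = []
    for i in range(n_neurons):
        row: dict = {"neuron": i, "session": bundle.session_id}
        r = bundle.activity[i]
        try:
            plan = enc.plan_folds(
                r,
                seed=config.fold_seed + i,
                frame_rate=config.task.frame_rate,
                n_folds=config.n_folds,
                neg_fraction=config.neg_fraction,
                guard=config.guard,
                guard_scope=config.guard_scope,
                valid_mask=valid,
            )
        except enc.InsufficientPositives as e:
            logger.info("session %s neuron %d skipped: %s", bundle.session_id, i, e)
            row.update(
                skipped=True, elusive=True, full_r2=0.0,
                mean_likelihood=np.nan, null_likelihood=np.nan,
            )
            rows.append(row)
            continue
        full = enc.cv_estimate(r, design.X, plan, config.alpha, config.lam)
        elusive, null = enc.fit_null_and_classify(r, plan, full)
        r2 = (
            0.0
            if elusive
            else enc.prediction_accuracy(full, r, events, config.task.frame_rate)
        )
        cv_probs[i] = full.prob
        kernels[i] = enc.extract_kernels(full.fits, basis).kernels
        row.update(
            skipped=False,
            elusive=bool(elusive),
            full_r2=r2,
            mean_likelihood=full.mean_likelihood,
            null_likelihood=null.mean_likelihood,
        )
        if config.do_category_models and not elusive:
            for cat in bhv.CATEGORIES:
                single, loo = enc.category_models(
                    r, design, cat, plan, config.alpha, config.lam
                )
                r2_single = enc.prediction_accuracy(
                    single, r, events, config.task.frame_rate
                )
                r2_loo = enc.prediction_accuracy(
                    loo, r, events, config.task.frame_rate
                )
                row[f"r2_single_{cat}"] = r2_single
                row[f"r2_loo_{cat}"] = r2_loo
                row[f"dr2_{cat}"] = enc.unique_contribution(r2, r2_loo)
        rows.append(row)
    return SessionEncoding(
        table=pd.DataFrame(rows), cv_probs=cv_probs, kernels=kernels
    )


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Run the full study and write its artifacts into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    digest = config.digest()
    config.to_yaml(outdir / "config.yaml")
    basis = gaussian_basis(config.task.frame_rate)

    # ---- simulate -------------------------------------------------------
    bundle_paths = [outdir / f"bundle_{sid}.h5" for sid in SESSION_IDS]
    if _stage_cached(outdir, "simulate", digest) and all(
        p.exists() for p in bundle_paths
    ):
        bundles = [load_bundle(p) for p in bundle_paths]
        logger.info("simulate stage loaded from cache")
    else:
        bundles, _truth = simulate_study(
            config.task,
            config.n_neurons,
            config.session_seeds,
            duration=config.duration,
            skill=config.skill,
            stable_frac=config.stable_frac,
            noise_frac=config.noise_frac,
            target_rate=config.target_rate,
            signal_swing=config.signal_swing,
            pursued_frac=config.pursued_frac,
        )
        for b, p in zip(bundles, bundle_paths):
            problems = b.validate()
            if problems:
                raise RuntimeError(f"stage simulate, session {b.session_id}: {problems}")
            save_bundle(b, p)
            save_trials_csv(b, outdir / f"trials_{b.session_id}.csv")
        _mark_stage(outdir, "simulate", digest)
    pursued = bundles[0].pursued

    # ---- encode ---------------------------------------------------------
    enc_path = outdir / "encoding.h5"
    encodings: dict[str, SessionEncoding] = {}
    if _stage_cached(outdir, "encode", digest) and enc_path.exists():
        with h5py.File(enc_path, "r") as f:
            for sid in SESSION_IDS:
                encodings[sid] = SessionEncoding(
                    table=pd.read_csv(outdir / f"encoding_{sid}.csv"),
                    cv_probs=f[f"cv/{sid}"][()],
                    kernels=f[f"kernels/{sid}"][()],
                )
        logger.info("encode stage loaded from cache")
    else:
        with h5py.File(enc_path, "w") as f:
            for b in bundles:
                logger.info("encoding session %s", b.session_id)
                se = encode_session(b, config, basis)
                encodings[b.session_id] = se
                se.table.to_csv(outdir / f"encoding_{b.session_id}.csv", index=False)
                f.create_dataset(f"cv/{b.session_id}", data=se.cv_probs)
                f.create_dataset(f"kernels/{b.session_id}", data=se.kernels)
        _mark_stage(outdir, "encode", digest)

    # ---- rank -----------------------------------------------------------
    rank_tables: dict[str, pd.DataFrame] = {}
    for sid in SESSION_IDS:
        t = encodings[sid].table
        rank_tables[sid] = rnk.normalized_rank(
            t["full_r2"].to_numpy(), t["elusive"].to_numpy(), t["neuron"].to_numpy()
        )
        rank_tables[sid].to_csv(outdir / f"ranks_{sid}.csv", index=False)
    top20 = rnk.select_top_group(rank_tables[SESSION_IDS[0]], pursued, config.top_band)

    stability: dict[str, dict] = {}
    for k, sid in enumerate(SESSION_IDS[1:], start=1):
        pool = (
            rank_tables[sid]["neuron"].to_numpy()
            if config.rank_pool == "all"
            else np.flatnonzero(pursued)
        )
        if len(top20) == 0 or len(top20) > len(pool):
            logger.warning("rank-stability test skipped for %s", sid)
            continue
        res = rnk.rank_stability_test(
            top20, rank_tables[sid], pool,
            n_draws=config.n_rank_draws, seed=config.rank_seed + k,
        )
        stability[sid] = dataclasses.asdict(res)
    (outdir / "rank_stability.json").write_text(
        json.dumps(
            {"top20": top20.tolist(), "sessions": stability}, indent=2, sort_keys=True
        )
    )

    # ---- kernel consistency --------------------------------------------
    kern = np.stack([encodings[sid].kernels for sid in SESSION_IDS])
    p_idx = np.flatnonzero(pursued)
    consistency: dict[str, float] = {}
    if len(p_idx):
        corr, _ = enc.kernel_consistency(kern[:, p_idx])
        lever_cols = [bhv.CANONICAL_COLUMNS.index(v) for v in bhv.CATEGORIES["lever"]]
        in_top = np.isin(p_idx, top20)
        for label, mask in (("top20", in_top), ("other_pursued", ~in_top)):
            if mask.any():
                consistency[label] = float(
                    np.nanmean(corr[np.ix_(mask, lever_cols)])
                )
    (outdir / "kernel_consistency.json").write_text(
        json.dumps(consistency, indent=2, sort_keys=True)
    )

    # ---- decode ---------------------------------------------------------
    decode_rows = []
    contributions: dict[str, dict] = {}
    for b in bundles:
        se = encodings[b.session_id]
        usable = p_idx[np.all(np.isnan(se.cv_probs[p_idx]), axis=1) == False]  # noqa: E712
        if len(usable) == 0:
            continue
        lever = b.behavior.column("lever_pos")
        library = dec.build_library(se.cv_probs, lever, b.frame_rate)
        result = dec.decode_lever(
            b.activity, library, usable,
            offsets=config.offsets, exclusion=config.exclusion,
        )
        r2 = dec.decoding_accuracy(result, lever)
        decode_rows.append(
            {"session": b.session_id, "neuron_set": "pursued", "n_neurons": len(usable), "r2": r2}
        )
        sub = np.intersect1d(top20, usable)
        ctrl_pool = np.setdiff1d(usable, top20)
        if (
            config.do_decode_contribution
            and 0 < len(sub) < len(usable)
            and len(ctrl_pool) >= len(sub)
        ):
            contrib = dec.decoding_unique_contribution(
                b.activity, library, usable, sub, ctrl_pool,
                n_controls=config.n_decode_controls,
                seed=config.decode_seed,
                offsets=config.offsets, exclusion=config.exclusion,
            )
            contributions[b.session_id] = {
                "delta_r2": contrib.delta_r2,
                "control_97_5": float(np.percentile(contrib.controls, 97.5)),
                "control_max": float(contrib.controls.max()),
                "r2_full": contrib.r2_full,
                "r2_reduced": contrib.r2_reduced,
            }
        if b.session_id == SESSION_IDS[0]:
            _report_figure(outdir, b, result, lever)
    pd.DataFrame(decode_rows).to_csv(outdir / "decoding.csv", index=False)
    (outdir / "decoding_contribution.json").write_text(
        json.dumps(contributions, indent=2, sort_keys=True)
    )
    _mark_stage(outdir, "complete", digest)

    return {
        "bundles": bundles,
        "encodings": encodings,
        "rank_tables": rank_tables,
        "top20": top20,
        "stability": stability,
        "kernel_consistency": consistency,
        "decoding": decode_rows,
        "contributions": contributions,
    }


def _report_figure(outdir: Path, bundle, result, lever) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(9, 3))
    t = np.arange(bundle.n_frames) / bundle.frame_rate
    ax.plot(t, lever, color="0.6", lw=0.8, label="recorded")
    ax.plot(t, result.x_hat, color="k", lw=0.8, label="decoded")
    ax.set(xlabel="time (s)", ylabel="lever (mm)", title=bundle.session_id)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(outdir / f"decoded_{bundle.session_id}.png", dpi=120)
    plt.close(fig)


def validate_bundle(path: str | Path) -> dict:
    """Check a stored session bundle against the bundle invariants."""
    bundle = load_bundle(path)
    problems = bundle.validate()
    report = {
        "path": str(path),
        "session_id": bundle.session_id,
        "n_frames": bundle.n_frames,
        "n_neurons": 0 if bundle.activity is None else bundle.activity.shape[0],
        "n_trials": len(bundle.trials),
        "violations": problems,
        "ok": not problems,
    }
    return report
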