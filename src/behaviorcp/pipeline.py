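"""End-to-end analysis runs: simulate -> (track) -> analyze, reproducibly.

A run is driven by a single configuration mapping (usually loaded from
YAML).  Per-stage seeds are derived from the master seed by stable
hashing, every output file carries the configuration hash and seed, and a
rerun with the same configuration produces an identical output tree.

Configuration keys (all optional; defaults shown by ``default_config``)::

    seed: 1
    task: {...}            # TaskConfig fields
    generative: {...}      # GenerativeParams fields
    simulate: {subjects: [...], n_sessions: 2, n_trials: 450}
    stages: {tracking: false, psychometrics: true, similarity: true,
             cp_instant: true, cp_trajectory: true, glm: true}
    tracking: {frames_dir: null, ...TrackerConfig fields}
    cp: {n_shuffles: 100, n_bins: 6, n_components: 2, window: [-0.5, 2.5]}
    glm: {stepwise: false}
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import choice_probability as cpmod
from . import glm as glmmod
from . import psychometrics as psymod
from . import similarity as simmod
from ._utils import derive_seed
from .exceptions import ConfigurationError
from .synthetic import GenerativeParams, TaskConfig, simulate_dataset
from .tracking import HeadTracker, TrackerConfig, load_frames

logger = logging.getLogger(__name__)


def default_config() -> dict:
    return {
        "seed": 1,
        "task": {},
        "generative": {},
        "simulate": {
            "subjects": ["Edgar", "Fernando", "Gabriel"],
            "n_sessions": 2,
            "n_trials": 450,
        },
        "stages": {
            "tracking": False,
            "psychometrics": True,
            "similarity": True,
            "cp_instant": True,
            "cp_trajectory": True,
            "glm": True,
        },
        "tracking": {"frames_dir": None},
        "cp": {"n_shuffles": 100, "n_bins": 6, "n_components": 2,
               "window": [-0.5, 2.5]},
        "glm": {"stepwise": False},
    }


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for key, val in (override or {}).items():
        if isinstance(val, dict) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], val)
        else:
            out[key] = val
    return out


def load_config(path) -> dict:
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    return _merge(default_config(), user)


def config_hash(config: dict) -> str:
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode("utf-8")).hexdigest()[:16]


class _RunWriter:
    """Writes artifacts stamped with the run's config hash and seed."""

    def __init__(self, out_dir: Path, chash: str, seed: int):
        self.out_dir = Path(out_dir)
        self.out_dir.mkdir(parents=True, exist_ok=True)
        self.stamp = f"# behaviorcp config_hash={chash} seed={seed}\n"
        self.chash = chash
        self.seed = seed

    def csv(self, name: str, frame: pd.DataFrame, index=False):
        path = self.out_dir / name
        with open(path, "w") as fh:
            fh.write(self.stamp)
            frame.to_csv(fh, index=index)
        return path

    def json(self, name: str, payload: dict):
        path = self.out_dir / name
        payload = {"config_hash": self.chash, "seed": self.seed, **payload}
        path.write_text(json.dumps(payload, indent=2, default=_jsonable))
        return path


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return str(obj)


def run_full_analysis(config: dict, out_dir) -> Path:
    """Execute the enabled stages in order; return the run directory.

    Stage failures raise with the stage name attached; outputs written by
    earlier stages are preserved.
    """
    config = _merge(default_config(), config or {})
    out_dir = Path(out_dir)
    seed = int(config["seed"])
    chash = config_hash(config)
    writer = _RunWriter(out_dir, chash, seed)
    stages_cfg = config["stages"]
    log_entries: list = []

    log_path = out_dir / "run.log"

    def run_stage(name, fn):
        t0 = time.perf_counter()
        try:
            fn()
        except Exception as exc:
            writer.json("run.json", {
                "config": config, "stages": log_entries,
                "failed_stage": name, "error": str(exc),
            })
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
        elapsed = time.perf_counter() - t0
        log_entries.append(name)
        # wall times go to the log only, keeping run.json reproducible
        with open(log_path, "a") as fh:
            fh.write(f"{writer.chash} stage={name} seconds={elapsed:.3f}\n")
        logger.info("stage %s done in %.2fs", name, elapsed)

    state: dict = {}

    def stage_simulate():
        task = TaskConfig(**config["task"])
        gen = GenerativeParams(**config["generative"])
        sim = config["simulate"]
        trials, trajs = simulate_dataset(
            task, gen, subjects=sim["subjects"], n_sessions=sim["n_sessions"],
            n_trials=sim["n_trials"], seed=derive_seed(seed, "simulate"),
        )
        state["task"], state["trials"], state["trajs"] = task, trials, trajs
        with open(out_dir / "session.csv", "w") as fh:
            fh.write(writer.stamp)
            trials.to_csv(fh, index=False)
        traj_path = out_dir / "trajectories.csv"
        trajs.save(traj_path)
        # stamp the matrix file (loadtxt skips '#' comments) and sidecar
        traj_path.write_text(writer.stamp + traj_path.read_text())
        sidecar_path = traj_path.with_suffix(".csv.json")
        sidecar = json.loads(sidecar_path.read_text())
        sidecar.update({"config_hash": writer.chash, "seed": writer.seed})
        sidecar_path.write_text(json.dumps(sidecar, indent=2))

    def stage_tracking():
        frames_dir = config["tracking"].get("frames_dir")
        if not frames_dir:
            raise ConfigurationError(
                "tracking stage enabled but tracking.frames_dir not set"
            )
        tcfg = {
            k: v for k, v in config["tracking"].items() if k != "frames_dir"
        }
        tracker = HeadTracker(TrackerConfig(**tcfg))
        frames = load_frames(frames_dir)
        result = tracker.track(frames)
        pd.DataFrame(result.positions, columns=["x", "y"]).pipe(
            lambda df: writer.csv("tracked_positions.csv", df)
        )

    def stage_psychometrics():
        fits = psymod.fit_sessions(state["trials"])
        writer.csv("psychometrics.csv", fits)
        summaries = []
        for subject, g in fits.groupby("subject"):
            ok = g.loc[g["converged"]]
            if len(ok) == 0:
                continue
            model = psymod.PsychometricRegression()._set_fitted(
                ok["intercept"].mean(), ok["slope"].mean(),
                n_trials=int(ok["n_trials"].sum()),
            )
            summaries.append({"subject": subject, **model.to_dict()})
        writer.json("psychometrics_summary.json", {"subjects": summaries})

    def stage_similarity():
        corr, part, ks = simmod.longest_interval_analysis(
            state["trials"], state["trajs"], state["task"]
        )
        writer.json(
            "similarity_summary.json",
            {"groups": part.summary(), "ks_tests": ks},
        )
        rows = []
        for name in ("same_session", "same_subject_diff_session", "diff_subject"):
            for v in getattr(part, name):
                rows.append({"group": name, "r": v})
        writer.csv("similarity_coefficients.csv", pd.DataFrame(rows))

    def stage_cp_instant():
        series = cpmod.cp_timecourse_by_cell(
            state["trials"], state["trajs"],
            window=tuple(config["cp"]["window"]),
            n_shuffles=config["cp"]["n_shuffles"],
            seed=derive_seed(seed, "cp_instant"),
        )
        frames = []
        for subject, s in series.items():
            f = s.to_frame()
            f.insert(0, "subject", subject)
            frames.append(f)
        writer.csv("cp_instant.csv", pd.concat(frames, ignore_index=True))
        state["cp_instant"] = series

    def stage_cp_trajectory():
        result = cpmod.trajectory_cp_analysis(
            state["trials"], state["trajs"],
            n_components=config["cp"]["n_components"],
            n_bins=config["cp"]["n_bins"],
            seed=derive_seed(seed, "cp_trajectory"),
        )
        out = state["trials"][["subject", "session", "trial"]].copy()
        out["cp_long"] = result.posteriors
        bin_col = np.full(len(out), -1)
        for subject, binning in result.binnings.items():
            mask = result.posteriors.notna() & (out["subject"] == subject)
            bin_col[np.flatnonzero(mask)] = binning.assignments
        out["cp_bin"] = bin_col
        writer.csv("cp_trajectory.csv", out)
        rows = []
        for subject, fits in result.bin_fits.items():
            for b, fit in enumerate(fits):
                rec = {"subject": subject, "bin": b}
                rec.update(fit.to_dict() if fit is not None
                           else {"converged": False})
                rows.append(rec)
        writer.csv("cp_bin_psychometrics.csv", pd.DataFrame(rows))
        state["cp_trajectory"] = result

    def stage_glm():
        results, table, lr = glmmod.run_model_ladder(
            state["trials"], state["trajs"],
            stepwise=config["glm"]["stepwise"],
        )
        writer.csv("glm_table.csv", table.reset_index())
        writer.json(
            "glm_lr_tests.json",
            {"tests": lr.to_dict(orient="records")},
        )
        coef_rows = []
        for mid, r in results.items():
            for name, val in r.params.items():
                coef_rows.append({"model": mid, "term": name, "coef": val})
        writer.csv("glm_coefficients.csv", pd.DataFrame(coef_rows))
        state["glm"] = results

    run_stage("simulate", stage_simulate)
    if stages_cfg.get("tracking"):
        run_stage("tracking", stage_tracking)
    if stages_cfg.get("psychometrics", True):
        run_stage("psychometrics", stage_psychometrics)
    if stages_cfg.get("similarity", True):
        run_stage("similarity", stage_similarity)
    if stages_cfg.get("cp_instant", True):
        run_stage("cp_instant", stage_cp_instant)
    if stages_cfg.get("cp_trajectory", True):
        run_stage("cp_trajectory", stage_cp_trajectory)
    if stages_cfg.get("glm", True):
        run_stage("glm", stage_glm)

    summary: dict = {"config": config, "stages": log_entries}
    if "cp_instant" in state:
        summary["cp_significant_fraction"] = {
            subject: float(np.mean(s.significant)) if s.usable else None
            for subject, s in state["cp_instant"].items()
        }
    writer.json("run.json", summary)
    return out_dir
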