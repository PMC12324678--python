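"""Pipeline orchestration, reproducibility and file I/O.

Binds the stages (train -> evaluate -> behaviour -> units -> sampling)
into a single seeded run that writes versioned outputs and a manifest
recording the configuration and every seed used.  Logs are
line-oriented JSON (streamable), analysis tables are CSV, activation
datasets are single-array archives.  No stage mutates an upstream
artifact.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from metanav import agent as ag
from metanav import behavior, sampling, synthetic, units
from metanav.logs import TrajectoryLog


@dataclass
class RunConfig:
    """Declarative description of one end-to-end run."""

    out_dir: str
    seed: int = 0
    scale: str = "desk"  # desk | full
    stages: tuple[str, ...] = ("train", "evaluate", "behavior", "units", "sampling")
    conditions: tuple[str, ...] = ("both",)
    kinds: tuple[str, ...] = ("open",)
    n_eval_trials: int = 200
    n_unit_trials_per_env: int = 100
    module_k: int = 10
    n_sampling_subjects: int = 60
    stage_seeds: dict = field(default_factory=dict)

    def seed_for(self, stage: str) -> int:
        if stage not in self.stage_seeds:
            h = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
            self.stage_seeds[stage] = int.from_bytes(h[:4], "big") % (2**31)
        return self.stage_seeds[stage]


def run_pipeline(config: RunConfig) -> Path:
    """Execute the requested stages, writing artifacts and a manifest.

    Re-running with an identical configuration reproduces every output
    bit-identically.  A stage needing a missing upstream artifact fails
    with a clear dependency error.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}
    task = ag.TaskConfig(conditions=config.conditions, kinds=config.kinds)
    params = None

    if "train" in config.stages:
        ppo = (
            ag.PPOConfig.full_scale()
            if config.scale == "full"
            else ag.PPOConfig(n_envs=4, rollout_steps=64, n_updates=20)
        )
        params, curve = ag.train(task, ag.NetworkConfig(), ppo, config.seed_for("train"))
        ag.save_params(params, out / "checkpoint.npz")
        curve.to_csv(out / "training_curve.csv", index=False)
        artifacts["checkpoint"] = "checkpoint.npz"
        artifacts["training_curve"] = "training_curve.csv"

    log = None
    if "evaluate" in config.stages:
        if params is None:
            raise FileNotFoundError(
                "evaluate stage requires the train stage's checkpoint"
            )
        log, _ = ag.evaluate(
            params, task, config.n_eval_trials, config.seed_for("evaluate"),
            keep_maps=True,
        )
        log.to_jsonl(out / "trajectories.jsonl")
        artifacts["trajectories"] = "trajectories.jsonl"

    if "behavior" in config.stages:
        if log is None:
            raise FileNotFoundError("behavior stage requires evaluated trajectories")
        summary = behavior.strategy_proportions(log)
        summary.table.to_csv(out / "strategy_table.csv")
        stats = behavior.steps_to_goal_stats(
            log.trials, "condition", n_boot=1000, seed=config.seed_for("behavior")
        )
        stats.to_csv(out / "steps_stats.csv", index=False)
        artifacts["strategy_table"] = "strategy_table.csv"
        artifacts["steps_stats"] = "steps_stats.csv"

    if "units" in config.stages:
        if params is None:
            raise FileNotFoundError("units stage requires a trained checkpoint")
        ds = units.record_activations(
            params, config.n_unit_trials_per_env, config.seed_for("units")
        )
        ds.save_npz(out / "activations.npz")
        labels = units.classify_units(ds)
        modules = units.identify_functional_modules(ds, k=config.module_k)
        with open(out / "unit_labels.json", "w") as fh:
            json.dump(
                [
                    {"unit": i, "label": lab.label, "p_quadrant": lab.p_quadrant,
                     "p_landmark": lab.p_landmark, "p_interaction": lab.p_interaction}
                    for i, lab in enumerate(labels)
                ],
                fh, indent=1,
            )
        with open(out / "modules.json", "w") as fh:
            json.dump(
                {"vector": modules.vector.tolist(),
                 "transition": modules.transition.tolist(),
                 "unspecialized": modules.unspecialized.tolist(),
                 "k": modules.k},
                fh, indent=1,
            )
        artifacts["unit_labels"] = "unit_labels.json"
        artifacts["modules"] = "modules.json"

    if "sampling" in config.stages:
        matrix = synthetic.simulate_sampling_strategies(
            "mixture", config.n_sampling_subjects, config.seed_for("sampling")
        )
        np.savetxt(out / "sampling_matrix.csv", matrix, fmt="%d", delimiter=",")
        pca = sampling.sampling_pca(matrix)
        np.savetxt(out / "sampling_scores.csv", pca["scores"], delimiter=",")
        artifacts["sampling_matrix"] = "sampling_matrix.csv"
        artifacts["sampling_scores"] = "sampling_scores.csv"

    manifest = {
        "config": {k: v for k, v in asdict(config).items() if k != "stage_seeds"},
        "stage_seeds": {s: config.seed_for(s) for s in config.stages},
        "config_hash": hashlib.sha256(
            json.dumps(asdict(config), sort_keys=True, default=str).encode()
        ).hexdigest(),
        "artifacts": artifacts,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return out


def write_trajectories(log: TrajectoryLog, path) -> None:
    log.to_jsonl(path)


def read_trajectories(path) -> TrajectoryLog:
    return TrajectoryLog.from_jsonl(path)


def read_human_sessions_csv(path) -> TrajectoryLog:
    """Convert an external human-session CSV to the internal schema.

    Optional convenience for users with their own behavioural data;
    expects columns subject, trial, step, row, col, response_type
    (direction|state), action, points, plus trial-level condition,
    environment, n_landmarks, steps_to_goal, success.  Only the columns
    the internal schema needs are read.
    """
    import pandas as pd

    df = pd.read_csv(path)
    required = {"trial", "step", "row", "col", "response_type", "action", "points"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"human-session CSV missing columns: {sorted(missing)}")
    steps = pd.DataFrame({
        "trial": df["trial"],
        "step": df["step"],
        "r": df["row"],
        "c": df["col"],
        "modality": df["response_type"],
        "action": df["action"],
        "dest_type": df.get("dest_type", "non_landmark"),
        "visited_before": df.get("visited_before", False),
        "points": df["points"],
    })
    trial_cols = ["trial", "condition", "environment", "n_landmarks",
                  "steps_to_goal", "success"]
    have = [c for c in trial_cols if c in df.columns]
    trials = df[have].drop_duplicates("trial").rename(
        columns={"environment": "kind"}
    )
    for col, default in (("condition", "both"), ("kind", "open"),
                         ("n_landmarks", -1), ("steps_to_goal", -1),
                         ("success", True)):
        if col not in trials.columns:
            trials[col] = default
    return TrajectoryLog(steps, trials)
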