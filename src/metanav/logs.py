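"""Shared data containers for behavioural and unit-level analyses.

``TrajectoryLog`` is the common currency of all behavioural analyses:
one row per navigation step plus one row of metadata per trial.
``ActivationDataset`` carries per-timestep recurrent cell states with
the task annotations the unit analyses need.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

STEP_COLUMNS = [
    "trial", "step", "r", "c", "modality", "action",
    "dest_type", "visited_before", "points",
]
TRIAL_COLUMNS = [
    "trial", "condition", "kind", "n_landmarks", "steps_to_goal", "success",
]


@dataclass
class TrajectoryLog:
    """Per-step records grouped by trial, with per-trial metadata.

    ``steps`` columns: trial, step, r, c (destination cell of the step),
    modality ("direction" | "state"), action (0-7), dest_type
    ("goal" | "landmark" | "non_landmark"), visited_before (bool),
    points (balance after the step).  ``trials`` columns: trial,
    condition, kind, n_landmarks, steps_to_goal, success.  ``maps``
    optionally holds each trial's serialized map for re-annotation.
    """

    steps: pd.DataFrame
    trials: pd.DataFrame
    maps: dict[int, str] = field(default_factory=dict)

    def __post_init__(self):
        missing = set(STEP_COLUMNS) - set(self.steps.columns)
        if missing:
            raise ValueError(f"step table missing columns: {sorted(missing)}")
        missing = set(TRIAL_COLUMNS) - set(self.trials.columns)
        if missing:
            raise ValueError(f"trial table missing columns: {sorted(missing)}")

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @staticmethod
    def concat(logs: list["TrajectoryLog"]) -> "TrajectoryLog":
        """Concatenate logs, renumbering trials to stay unique."""
        steps, trials, maps = [], [], {}
        offset = 0
        for log in logs:
            s = log.steps.copy()
            t = log.trials.copy()
            s["trial"] = s["trial"] + offset
            t["trial"] = t["trial"] + offset
            maps.update({k + offset: v for k, v in log.maps.items()})
            steps.append(s)
            trials.append(t)
            offset = int(t["trial"].max()) + 1 if len(t) else offset
        return TrajectoryLog(
            pd.concat(steps, ignore_index=True),
            pd.concat(trials, ignore_index=True),
            maps,
        )

    # -- line-oriented JSON round trip ------------------------------------
    def to_jsonl(self, path):
        with open(path, "w") as fh:
            for _, row in self.trials.iterrows():
                rec = {"record": "trial", **{k: _py(row[k]) for k in TRIAL_COLUMNS}}
                if int(row["trial"]) in self.maps:
                    rec["map"] = json.loads(self.maps[int(row["trial"])])
                fh.write(json.dumps(rec) + "\n")
            for _, row in self.steps.iterrows():
                rec = {"record": "step", **{k: _py(row[k]) for k in STEP_COLUMNS}}
                fh.write(json.dumps(rec) + "\n")

    @staticmethod
    def from_jsonl(path) -> "TrajectoryLog":
        steps, trials, maps = [], [], {}
        allowed_step = set(STEP_COLUMNS) | {"record"}
        allowed_trial = set(TRIAL_COLUMNS) | {"record", "map"}
        with open(path) as fh:
            for line in fh:
                rec = json.loads(line)
                kind = rec.get("record")
                if kind == "step":
                    unknown = set(rec) - allowed_step
                    if unknown:
                        raise ValueError(f"unknown step field(s): {sorted(unknown)}")
                    steps.append({k: rec[k] for k in STEP_COLUMNS})
                elif kind == "trial":
                    unknown = set(rec) - allowed_trial
                    if unknown:
                        raise ValueError(f"unknown trial field(s): {sorted(unknown)}")
                    if "map" in rec:
                        maps[int(rec["trial"])] = json.dumps(rec["map"])
                    trials.append({k: rec[k] for k in TRIAL_COLUMNS})
                else:
                    raise ValueError(f"unknown record type {kind!r}")
        return TrajectoryLog(
            pd.DataFrame(steps, columns=STEP_COLUMNS),
            pd.DataFrame(trials, columns=TRIAL_COLUMNS),
            maps,
        )


def _py(v):
    if isinstance(v, (np.integer,)):
        return int(v)
    if isinstance(v, (np.floating,)):
        return float(v)
    if isinstance(v, (np.bool_,)):
        return bool(v)
    return v


@dataclass
class ActivationDataset:
    """Per-timestep recurrent cell states with task annotations.

    All arrays are time-aligned along axis 0.  ``activations`` holds the
    LSTM cell state (length-100 vectors); ``logits`` the unmasked policy
    logits; ``cell`` the occupied interior cell as (row, col);
    ``goal_cell`` the trial's goal; ``env_id`` the landmark-layout id;
    ``landmark_adj``/``goal_adj`` flag steps on or 4-adjacent to a
    landmark/goal; ``post_landmark`` flags steps at or after the trial's
    first landmark encounter.
    """

    activations: np.ndarray
    logits: np.ndarray
    cell: np.ndarray
    goal_cell: np.ndarray
    env_id: np.ndarray
    trial: np.ndarray
    landmark_adj: np.ndarray
    goal_adj: np.ndarray
    post_landmark: np.ndarray

    def __post_init__(self):
        n = len(self.activations)
        for name in ("logits", "cell", "goal_cell", "env_id", "trial",
                     "landmark_adj", "goal_adj", "post_landmark"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"annotation {name!r} not time-aligned")

    def __len__(self) -> int:
        return len(self.activations)

    @property
    def n_units(self) -> int:
        return self.activations.shape[1]

    @staticmethod
    def concat(parts: list["ActivationDataset"]) -> "ActivationDataset":
        offset, trials = 0, []
        for p in parts:
            trials.append(p.trial + offset)
            offset += int(p.trial.max()) + 1 if len(p.trial) else 0
        return ActivationDataset(
            activations=np.concatenate([p.activations for p in parts]),
            logits=np.concatenate([p.logits for p in parts]),
            cell=np.concatenate([p.cell for p in parts]),
            goal_cell=np.concatenate([p.goal_cell for p in parts]),
            env_id=np.concatenate([p.env_id for p in parts]),
            trial=np.concatenate(trials),
            landmark_adj=np.concatenate([p.landmark_adj for p in parts]),
            goal_adj=np.concatenate([p.goal_adj for p in parts]),
            post_landmark=np.concatenate([p.post_landmark for p in parts]),
        )

    def save_npz(self, path):
        np.savez_compressed(
            path,
            activations=self.activations, logits=self.logits, cell=self.cell,
            goal_cell=self.goal_cell, env_id=self.env_id, trial=self.trial,
            landmark_adj=self.landmark_adj, goal_adj=self.goal_adj,
            post_landmark=self.post_landmark,
        )

    @staticmethod
    def load_npz(path) -> "ActivationDataset":
        with np.load(path) as z:
            return ActivationDataset(**{k: z[k] for k in z.files})
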