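"""Trajectory analytics: strategy arbitration and navigation performance.

Strategy is read out behaviourally from the action modality of each
step: *direction* responses index a vector-based strategy, *state*
responses a transition-based one.  The module computes direction-use
proportions overall and cross-tabulated by destination type (goal,
landmark, non-landmark) x whether the destination had been visited
earlier in the trial, per-group statistics of log steps-to-goal
(natural log throughout), and the quadratic relation between a
subject's direction-use proportion and mean log performance.

Mixed-effects and Bayesian model comparison are out of scope; the
module emits tidy per-step / per-trial / per-subject tables suitable
for external statistics tooling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from metanav import gridworld as gw
from metanav.logs import TrajectoryLog

DEST_TYPES = ("goal", "landmark", "non_landmark")


def annotate_steps(log: TrajectoryLog) -> TrajectoryLog:
    """Re-derive destination-type and visited-before labels from raw positions.

    Requires the per-trial maps to be attached to the log.  "Visited
    before" means the destination cell was occupied earlier in the same
    trial's navigation phase (the start cell counts as occupied).
    """
    if not log.maps:
        raise ValueError("log carries no maps; cannot re-annotate")
    steps = log.steps.copy()
    dest_types = np.empty(len(steps), dtype=object)
    visited_flags = np.zeros(len(steps), dtype=bool)
    for trial, idx in steps.groupby("trial").groups.items():
        grid = gw.map_from_json(log.maps[int(trial)])
        sub = steps.loc[idx].sort_values("step")
        # Walk the trajectory backwards from the recorded destinations.
        cells = list(zip(sub["r"].astype(int), sub["c"].astype(int)))
        for cell in cells:
            if not grid.in_interior(cell):
                raise ValueError(f"step cell {cell} outside the interior lattice")
        start = _infer_start(cells, sub, grid)
        occupied = {start}
        for row_i, cell in zip(sub.index, cells):
            if cell == grid.goal:
                dest_types[steps.index.get_loc(row_i)] = "goal"
            elif cell in grid.landmark_cells:
                dest_types[steps.index.get_loc(row_i)] = "landmark"
            else:
                dest_types[steps.index.get_loc(row_i)] = "non_landmark"
            visited_flags[steps.index.get_loc(row_i)] = cell in occupied
            occupied.add(cell)
    steps["dest_type"] = dest_types
    steps["visited_before"] = visited_flags
    return TrajectoryLog(steps, log.trials.copy(), dict(log.maps))


def _infer_start(cells, sub, grid):
    """Back out the start cell from the first step's destination and action."""
    first = cells[0]
    action = int(sub["action"].iloc[0])
    dr, dc = gw.DIRECTIONS[action % 4]
    return (first[0] - dr, first[1] - dc)


@dataclass
class StrategySummary:
    """Direction-use proportions, overall and by destination x visit history."""

    overall_direction: float
    table: pd.DataFrame  # index dest_type, columns visited_before in {False, True}
    counts: pd.DataFrame
    n_steps: int


def strategy_proportions(log: TrajectoryLog) -> StrategySummary:
    """Exact frequencies of direction use per destination x visited cell."""
    steps = log.steps
    if len(steps) == 0:
        raise ValueError("empty trajectory log")
    is_dir = (steps["modality"] == "direction").astype(float)
    overall = float(is_dir.mean())
    grp = steps.assign(is_dir=is_dir).groupby(["dest_type", "visited_before"])
    table = grp["is_dir"].mean().unstack("visited_before")
    counts = grp["is_dir"].size().unstack("visited_before").fillna(0).astype(int)
    table = table.reindex(list(DEST_TYPES))
    counts = counts.reindex(list(DEST_TYPES)).fillna(0).astype(int)
    return StrategySummary(overall, table, counts, len(steps))


def steps_to_goal_stats(
    trials: pd.DataFrame,
    grouping: list[str] | str,
    n_boot: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Group means of ln(steps-to-goal) with bootstrap 95% intervals.

    Zero-step trials cannot be log-transformed and are excluded with a
    warning count (they cannot occur for distance-4 starts).
    """
    if isinstance(grouping, str):
        grouping = [grouping]
    trials = trials.copy()
    n_zero = int((trials["steps_to_goal"] <= 0).sum())
    if n_zero:
        import warnings

        warnings.warn(f"excluding {n_zero} zero-step trials from log transform")
        trials = trials[trials["steps_to_goal"] > 0]
    rng = np.random.default_rng(seed)
    rows = []
    for key, sub in trials.groupby(grouping):
        logs = np.log(sub["steps_to_goal"].to_numpy(dtype=float))
        boots = np.empty(n_boot)
        n = len(logs)
        for b in range(n_boot):
            boots[b] = logs[rng.integers(0, n, size=n)].mean()
        lo, hi = np.percentile(boots, [2.5, 97.5])
        key = key if isinstance(key, tuple) else (key,)
        rows.append({
            **dict(zip(grouping, key)),
            "n_trials": n,
            "mean_log_steps": float(logs.mean()),
            "ci_lo": float(lo),
            "ci_hi": float(hi),
        })
    return pd.DataFrame(rows)


def quadratic_performance_fit(
    direction_proportion: np.ndarray, mean_log_steps: np.ndarray
):
    """OLS of mean log steps on direction use with linear + quadratic terms.

    Returns the fitted statsmodels results object; ``params`` are
    (intercept, linear, quadratic) and the usual t-tests apply.  A
    U-shaped performance curve — both strategy extremes outperforming
    mixtures — shows up as a significant quadratic coefficient.
    """
    x = np.asarray(direction_proportion, dtype=float)
    y = np.asarray(mean_log_steps, dtype=float)
    if len(x) < 4:
        raise ValueError("need at least 4 subjects for a quadratic fit")
    X = np.column_stack([np.ones_like(x), x, x**2])
    if np.linalg.matrix_rank(X) < 3:
        raise ValueError("design matrix is rank deficient")
    return sm.OLS(y, X).fit()


def per_subject_summary(logs: dict[int, TrajectoryLog]) -> pd.DataFrame:
    """Tidy per-subject table: direction use and mean log steps-to-goal."""
    rows = []
    for subject, log in logs.items():
        prop = float((log.steps["modality"] == "direction").mean())
        ok = log.trials["steps_to_goal"] > 0
        rows.append({
            "subject": subject,
            "direction_proportion": prop,
            "mean_log_steps": float(
                np.log(log.trials.loc[ok, "steps_to_goal"]).mean()
            ),
            "n_trials": int(len(log.trials)),
        })
    return pd.DataFrame(rows)
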