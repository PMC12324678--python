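"""Synthetic-data generators with known ground truth.

Every analysis stage in the package has a generator here that produces
input with planted, recoverable structure: simulated participants whose
modality choices follow known probabilities and whose movement follows
a noisy gradient toward their remembered goal; memory-probe responses
drawn from the calibrated noise model; landmark-sampling count matrices
with named spatial strategies; and activation datasets with planted
spatial / landmark / conjunctive units optionally wired into synthetic
action logits.  The round trip generator -> analysis -> recovered
parameters is the package's core correctness surface.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from metanav import gridworld as gw
from metanav import memory as mem
from metanav.logs import ActivationDataset, TrajectoryLog
from metanav.units import ENV_SUITE, landmark_adjacent_map, quadrant_of


@dataclass(frozen=True)
class ParticipantProfile:
    """Generative behaviour parameters for one simulated participant.

    ``p_direction_base`` is the probability of a direction-modality
    response when no override applies; ``p_state_at_*`` override the
    modality draw when the chosen move's destination is the goal, a
    landmark, or a previously visited cell (checked in that order).
    ``competence`` in [0, 1] sets how reliably the participant takes
    the move that most reduces the distance to the remembered goal
    estimate (1 = always; 0 = uniform over valid moves).
    """

    p_direction_base: float = 0.75
    p_state_at_goal: float = 0.5
    p_state_at_landmark: float = 0.5
    p_state_at_visited: float = 0.25
    competence: float = 0.9
    noise: mem.MemoryNoiseParams = mem.MemoryNoiseParams(0.91, -0.63, 1.90)

    def __post_init__(self):
        for name in ("p_direction_base", "p_state_at_goal", "p_state_at_landmark",
                     "p_state_at_visited", "competence"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")


def simulate_participant(
    profile: ParticipantProfile,
    n_trials: int,
    seed,
    environment_kind: str = "open",
    n_unique_landmarks: int = 4,
    condition: str = "both",
    keep_maps: bool = False,
) -> TrajectoryLog:
    """Simulate one participant's navigation trajectories.

    Movement policy: softmax over the negative estimated distance from
    each candidate next cell to the remembered goal estimate, with
    temperature shrinking as competence grows; at competence 1 the move
    is the greedy distance-reducing one (ties random).  The modality of
    each step is drawn independently of the chosen move from the
    profile's probabilities.
    """
    rng = np.random.default_rng(seed)
    steps_rows, trial_rows, maps = [], [], {}
    for trial in range(n_trials):
        cfg = gw.EpisodeConfig(
            condition=condition,
            p_direction_available=gw.default_p_direction(environment_kind),
        )
        grid, start = gw.generate_trial(rng, environment_kind, n_unique_landmarks,
                                        config=cfg)
        store = mem.build_memory_store(grid, profile.noise, rng)
        goal_est, _ = store.recall(grid.identity[grid.goal])
        state = gw.init_state(grid, start, cfg, rng)
        n_steps = 0
        done = False
        while not done and n_steps < cfg.max_steps:
            mask = gw.action_mask(state, grid)
            move_slots = [i for i in range(4) if mask[i] or mask[i + 4]]
            r, c = state.cell
            dists = np.array([
                abs((c + gw.DIRECTIONS[i][1]) - goal_est[0])
                + abs((r + gw.DIRECTIONS[i][0]) - goal_est[1])
                for i in move_slots
            ])
            slot = move_slots[_choose_move(dists, profile.competence, rng)]
            dest = (r + gw.DIRECTIONS[slot][0], c + gw.DIRECTIONS[slot][1])
            p_state = _state_probability(profile, dest, grid, state)
            use_state = rng.random() < p_state
            # Respect availability: fall back to whichever modality is open.
            if use_state and not mask[slot + 4]:
                use_state = False
            if not use_state and not mask[slot]:
                use_state = True
            action = slot + 4 if use_state else slot
            prev_visited = set(state.visited)
            state, event = gw.step(state, grid, action, cfg, rng)
            n_steps += 1
            done = event == "goal"
            steps_rows.append({
                "trial": trial, "step": n_steps, "r": dest[0], "c": dest[1],
                "modality": "state" if use_state else "direction",
                "action": action,
                "dest_type": ("goal" if dest == grid.goal
                              else "landmark" if dest in grid.landmark_cells
                              else "non_landmark"),
                "visited_before": dest in prev_visited,
                "points": state.points,
            })
            if event == "truncated":
                break
        trial_rows.append({
            "trial": trial, "condition": condition, "kind": environment_kind,
            "n_landmarks": len(grid.landmarks), "steps_to_goal": n_steps,
            "success": done,
        })
        if keep_maps:
            maps[trial] = gw.map_to_json(grid)
    return TrajectoryLog(pd.DataFrame(steps_rows), pd.DataFrame(trial_rows), maps)


def _choose_move(dists, competence, rng):
    if competence >= 1.0:
        best = np.flatnonzero(dists == dists.min())
        return int(best[rng.integers(len(best))])
    temperature = max(1e-6, 2.0 * (1.0 - competence))
    z = -dists / temperature
    z -= z.max()
    p = np.exp(z)
    p /= p.sum()
    return int(rng.choice(len(dists), p=p))


def _state_probability(profile, dest, grid, state) -> float:
    if dest == grid.goal:
        return profile.p_state_at_goal
    if dest in grid.landmark_cells:
        return profile.p_state_at_landmark
    if dest in state.visited:
        return profile.p_state_at_visited
    return 1.0 - profile.p_direction_base


def simulate_probe_responses(
    grid: gw.GridMap,
    params: mem.MemoryNoiseParams,
    n_probes: int,
    seed,
) -> pd.DataFrame:
    """Memory-probe responses under the calibrated noise model.

    Each probe targets the goal or a random landmark; the response is
    the true cell plus per-axis Gaussian noise, rounded to the nearest
    cell and clipped to the interior (a click must land on the grid).
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    items = [(grid.goal, params.s_goal)] + [
        (cell, mem.landmark_noise_sd(params.m, params.c, n)) for cell, n in grid.landmarks
    ]
    rows = []
    hi = gw.INTERIOR_SIZE - 1
    for _ in range(n_probes):
        (tr, tc), sd = items[int(rng.integers(len(items)))]
        est = mem.corrupt_coordinates((float(tc), float(tr)), sd, rng)
        rows.append({
            "true_r": tr, "true_c": tc,
            "resp_r": int(np.clip(round(est[1]), 0, hi)),
            "resp_c": int(np.clip(round(est[0]), 0, hi)),
            "sd": sd,
        })
    return pd.DataFrame(rows)


def simulate_sampling_strategies(
    strategy: str,
    n_subjects: int,
    seed,
    n_blocks: int = 4,
    concentration: float = 1.2,
) -> np.ndarray:
    """Subjects x 64 sampling-count matrices with a named spatial bias.

    Strategies: ``center`` (counts concentrated near the interior
    centre), ``corner`` (concentrated at the corners), ``uniform``, or
    ``mixture`` (half centre-, half corner-samplers).  Each block
    spends the full 16-click budget, so each row sums to
    ``16 * n_blocks``.
    """
    rng = np.random.default_rng(seed)
    size = gw.INTERIOR_SIZE
    cells = [(r, c) for r in range(size) for c in range(size)]
    centre_d = np.array([abs(r - 3.5) + abs(c - 3.5) for r, c in cells])
    corner_d = np.array([
        min(abs(r - rr) + abs(c - cc) for rr in (0, size - 1) for cc in (0, size - 1))
        for r, c in cells
    ])
    def weights(kind):
        if kind == "center":
            return np.exp(-concentration * centre_d)
        if kind == "corner":
            return np.exp(-concentration * corner_d)
        if kind == "uniform":
            return np.ones(len(cells))
        raise ValueError(f"unknown strategy {kind!r}")

    out = np.zeros((n_subjects, size * size), dtype=int)
    for s in range(n_subjects):
        kind = strategy
        if strategy == "mixture":
            kind = "center" if s < n_subjects // 2 else "corner"
        w = weights(kind)
        p = w / w.sum()
        for _ in range(n_blocks):
            draws = rng.choice(len(cells), size=gw.EXPOSURE_BUDGET, p=p)
            np.add.at(out[s], draws, 1)
    return out


@dataclass(frozen=True)
class PlantedUnitSpec:
    """Ground-truth recipe for one synthetic unit's activation profile."""

    kind: str  # spatial | landmark | conjunctive | noise
    amplitude: float = 1.0
    noise_sd: float = 0.1
    quadrant: int = 0      # for spatial/conjunctive
    wired_to: str | None = None  # None | "direction" | "state"

    def __post_init__(self):
        if self.kind not in ("spatial", "landmark", "conjunctive", "noise"):
            raise ValueError(f"unknown planted kind {self.kind!r}")
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")


def generate_planted_activations(
    specs: list[PlantedUnitSpec],
    n_steps_per_env: int = 1000,
    seed: int = 0,
    env_suite=ENV_SUITE,
) -> ActivationDataset:
    """Activation dataset with planted unit types and logit wiring.

    Timesteps visit uniformly random interior cells of each layout in
    the suite.  Spatial units activate (amplitude) in their preferred
    quadrant; landmark units on or beside any landmark; conjunctive
    units multiplicatively (quadrant AND landmark adjacency); noise
    units are pure Gaussian noise.  Units with ``wired_to`` add their
    activation linearly into the four direction or four state logits,
    providing ground truth for functional-module identification.
    """
    if len(specs) > 100:
        raise ValueError("at most 100 planted units")
    rng = np.random.default_rng(seed)
    size = gw.INTERIOR_SIZE
    cells_list, env_ids = [], []
    for env_id in range(len(env_suite)):
        rc = rng.integers(0, size, size=(n_steps_per_env, 2))
        cells_list.append(rc)
        env_ids.append(np.full(n_steps_per_env, env_id))
    cells = np.concatenate(cells_list)
    env_id = np.concatenate(env_ids)
    T = len(cells)
    adj_maps = [landmark_adjacent_map(layout) for layout in env_suite]
    lm_adj = np.array([
        adj_maps[e][r, c] for e, (r, c) in zip(env_id, cells)
    ])
    quad = np.array([quadrant_of((r, c)) for r, c in cells])
    acts = np.zeros((T, len(specs)))
    for u, spec in enumerate(specs):
        noise = rng.normal(0, spec.noise_sd, size=T)
        if spec.kind == "spatial":
            signal = spec.amplitude * (quad == spec.quadrant)
        elif spec.kind == "landmark":
            signal = spec.amplitude * lm_adj
        elif spec.kind == "conjunctive":
            signal = spec.amplitude * ((quad == spec.quadrant) & lm_adj)
        else:
            signal = 0.0
        acts[:, u] = signal + noise
    logits = rng.normal(0, 0.05, size=(T, 8))
    for u, spec in enumerate(specs):
        if spec.wired_to == "direction":
            logits[:, :4] += acts[:, u][:, None]
        elif spec.wired_to == "state":
            logits[:, 4:] += acts[:, u][:, None]
    return ActivationDataset(
        activations=acts,
        logits=logits,
        cell=cells.astype(int),
        goal_cell=np.zeros_like(cells),
        env_id=env_id.astype(int),
        trial=np.arange(T),
        landmark_adj=lm_adj.astype(bool),
        goal_adj=np.zeros(T, dtype=bool),
        post_landmark=np.ones(T, dtype=bool),
    )
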