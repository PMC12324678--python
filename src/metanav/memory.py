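"""Simulated noisy spatial memory standing in for the map-reading phase.

The agent never performs map reading explicitly; instead it enters the
navigation phase holding corrupted coordinate estimates of the goal and
of each landmark, calibrated to human memory-probe errors:

* goal-noise s.d.  ``s_goal ~ N(0.91, 0.44)`` drawn per trial,
* landmark-noise s.d.  ``s_landmark = m * ln(n_exposures) + c`` with
  per-participant ``m ~ N(-0.63, 0.34)`` and ``c ~ N(1.90, 0.60)``,
* each coordinate estimate = truth + independent N(0, s) error.

Negative s.d. draws are floored at 0 (a negative s.d. is undefined; the
floor shifts the goal-noise mean by less than 0.005).  Estimates are
continuous — never rounded or clipped to the lattice — and are frozen
for the duration of a trial.  Identities without a memory entry (any
non-landmark, non-goal state, and the wall sentinel 65) recall as the
all-zero "no memory" sentinel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from metanav.gridworld import Cell, GridMap, WALL_ID

GOAL_NOISE_MEAN = 0.91
GOAL_NOISE_SD = 0.44
SLOPE_MEAN = -0.63
SLOPE_SD = 0.34
INTERCEPT_MEAN = 1.90
INTERCEPT_SD = 0.60

NO_MEMORY: tuple[tuple[float, float], float] = ((0.0, 0.0), 0.0)


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class MemoryNoiseParams:
    """Per-participant memory parameters: goal s.d. and the landmark noise line."""

    s_goal: float
    m: float
    c: float


def draw_goal_noise(rng) -> float:
    """One per-trial draw of the goal-coordinate noise s.d., floored at 0."""
    return max(0.0, float(_as_rng(rng).normal(GOAL_NOISE_MEAN, GOAL_NOISE_SD)))


def draw_landmark_noise_params(rng) -> tuple[float, float]:
    """Independent draws of the landmark-noise slope m and intercept c.

    Drawn once per simulated participant (or per agent-episode batch)
    and held fixed across that session's trials.
    """
    rng = _as_rng(rng)
    m = float(rng.normal(SLOPE_MEAN, SLOPE_SD))
    c = float(rng.normal(INTERCEPT_MEAN, INTERCEPT_SD))
    return m, c


def landmark_noise_sd(m: float, c: float, n_exposures: int) -> float:
    """Landmark-coordinate noise s.d.: m * ln(n_exposures) + c, floored at 0."""
    if n_exposures < 1:
        raise ValueError("n_exposures must be >= 1")
    return max(0.0, m * float(np.log(n_exposures)) + c)


def corrupt_coordinates(
    true_xy: tuple[float, float], s: float, rng
) -> tuple[float, float]:
    """Add independent N(0, s) error to each coordinate; continuous output."""
    if s < 0:
        raise ValueError("noise s.d. must be non-negative")
    rng = _as_rng(rng)
    eps = rng.normal(0.0, s, size=2) if s > 0 else np.zeros(2)
    return float(true_xy[0] + eps[0]), float(true_xy[1] + eps[1])


class MemoryStore:
    """Frozen per-trial memory: noisy (x, y) estimates keyed by identity.

    Holds exactly one entry for the goal and one per landmark; the
    confidence slot of each entry is the noise s.d. that was actually
    used to corrupt it.
    """

    def __init__(self):
        self._items: dict[int, tuple[Cell, tuple[float, float], float]] = {}

    def add(self, identity: int, true_cell: Cell, est_xy: tuple[float, float], sd: float):
        self._items[identity] = (true_cell, est_xy, sd)

    def recall(self, identity: int) -> tuple[tuple[float, float], float]:
        """Stored (estimated (x, y), confidence) or the no-memory sentinel."""
        if not 1 <= identity <= WALL_ID:
            raise ValueError(f"identity {identity} out of range 1..{WALL_ID}")
        if identity == WALL_ID or identity not in self._items:
            return NO_MEMORY
        _, est, sd = self._items[identity]
        return est, sd

    def __len__(self) -> int:
        return len(self._items)

    def __contains__(self, identity: int) -> bool:
        return identity in self._items

    def items(self):
        return self._items.items()

    def to_dict(self) -> dict:
        return {
            str(ident): {"true": list(cell), "est": list(est), "sd": sd}
            for ident, (cell, est, sd) in sorted(self._items.items())
        }


def build_memory_store(
    grid: GridMap, params: MemoryNoiseParams, rng
) -> MemoryStore:
    """Corrupt the goal and landmark coordinates into a trial's memory store.

    Coordinates are stored as (x, y) = (column, row) in the interior
    frame, matching the observation layout.
    """
    rng = _as_rng(rng)
    store = MemoryStore()
    gr, gc = grid.goal
    est = corrupt_coordinates((float(gc), float(gr)), params.s_goal, rng)
    store.add(grid.identity[grid.goal], grid.goal, est, params.s_goal)
    for cell, n_exp in grid.landmarks:
        sd = landmark_noise_sd(params.m, params.c, n_exp)
        r, c = cell
        est = corrupt_coordinates((float(c), float(r)), sd, rng)
        store.add(grid.identity[cell], cell, est, sd)
    return store


def draw_trial_params(rng, m: float | None = None, c: float | None = None) -> MemoryNoiseParams:
    """Per-trial parameter bundle: fresh s_goal, session-level (m, c) if given."""
    rng = _as_rng(rng)
    if m is None or c is None:
        m, c = draw_landmark_noise_params(rng)
    return MemoryNoiseParams(s_goal=draw_goal_noise(rng), m=m, c=c)
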