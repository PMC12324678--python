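"""Trial worlds and the navigation-phase environment.

The traversable world is the 8x8 interior of a 10x10 lattice whose outer
ring is wall.  Interior cells are indexed ``(row, col)`` with
``row, col in 0..7``; when coordinate *pairs* are emitted, ``x`` is the
column and ``y`` the row.  Every interior cell carries a distinct
identity integer in 1..64, freshly permuted per trial; walls and
obstacles read as the sentinel identity 65.

Two environment kinds exist: *open* (no interior obstacles) and
*cluttered* (exactly 8 interior obstacles, one per interior row and one
per interior column).  A trial's map-reading phase exposes 2-16 unique
landmarks with a fixed total budget of 16 exposures; its navigation
phase starts the navigator four grid steps from the goal and charges 50
points per step against a 1,000-point reward for reaching the goal,
capped at 200 steps.

Action space (8 discrete actions): indices 0-3 are *direction* moves in
N, S, W, E order; indices 4-7 are *state* selections of the adjacent
cell in the same N, S, W, E slot order.  Both modalities produce the
same displacement; which one was used is the behavioural readout of
navigation strategy.
"""

from __future__ import annotations

import json
from collections import deque
from dataclasses import dataclass, field

import numpy as np

INTERIOR_SIZE = 8
WALL_ID = 65
N_ACTIONS = 8
N_OBS = 48
EXPOSURE_BUDGET = 16

#: (drow, dcol) for the four cardinal slots, in N, S, W, E order.
DIRECTIONS: tuple[tuple[int, int], ...] = ((-1, 0), (1, 0), (0, -1), (0, 1))

CONDITIONS = ("both", "directions_only", "states_only", "random_alternation")

Cell = tuple[int, int]


class MapGenerationError(RuntimeError):
    """Raised when a map satisfying the placement constraints cannot be built."""


class StartPlacementError(RuntimeError):
    """Raised when no start cell at the required goal distance exists."""


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class GridMap:
    """One trial's world: obstacles, identity permutation, landmarks, goal."""

    obstacles: frozenset[Cell]
    identity: dict[Cell, int]
    landmarks: tuple[tuple[Cell, int], ...]  # ((row, col), n_exposures)
    goal: Cell
    kind: str  # "open" | "cluttered"
    variant: str = "strict"  # "strict" | "day2"
    interior_size: int = INTERIOR_SIZE

    def in_interior(self, cell: Cell) -> bool:
        r, c = cell
        return 0 <= r < self.interior_size and 0 <= c < self.interior_size

    def traversable(self, cell: Cell) -> bool:
        return self.in_interior(cell) and cell not in self.obstacles

    def identity_at(self, cell: Cell) -> int:
        """Identity integer of a cell; walls and obstacles read as 65."""
        if not self.traversable(cell):
            return WALL_ID
        return self.identity[cell]

    @property
    def landmark_cells(self) -> frozenset[Cell]:
        return frozenset(cell for cell, _ in self.landmarks)


@dataclass(frozen=True)
class EpisodeConfig:
    """Navigation-phase settings: condition logic and the point economy."""

    condition: str = "both"
    p_direction_available: float = 0.75  # used only under random_alternation
    max_steps: int = 200
    step_cost: int = 50
    goal_reward: int = 1000
    start_points: int = 1000
    start_distance: int = 4

    def __post_init__(self):
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        if not 0.0 <= self.p_direction_available <= 1.0:
            raise ValueError("p_direction_available must be in [0, 1]")
        if self.max_steps <= 0:
            raise ValueError("max_steps must be positive")


def default_p_direction(kind: str) -> float:
    """Random-alternation direction-availability probability by environment kind."""
    return 0.75 if kind == "open" else 0.50


@dataclass
class EnvState:
    """Mutable per-episode state of the navigation phase."""

    cell: Cell
    step_index: int = 0
    points: int = 1000
    visited: set[Cell] = field(default_factory=set)
    last_disp: tuple[int, int] = (0, 0)  # (dx, dy) = (dcol, drow)
    directions_available: bool = True
    states_available: bool = True


# ---------------------------------------------------------------------------
# Map generation
# ---------------------------------------------------------------------------

def _edge_cells(size: int = INTERIOR_SIZE) -> frozenset[Cell]:
    return frozenset(
        (r, c)
        for r in range(size)
        for c in range(size)
        if r in (0, size - 1) or c in (0, size - 1)
    )

_EDGE = _edge_cells()
_ALL_CELLS = tuple((r, c) for r in range(INTERIOR_SIZE) for c in range(INTERIOR_SIZE))


def allocate_landmark_exposures(
    n_unique: int | None,
    variant: str,
    rng,
    *,
    obstacles: frozenset[Cell] = frozenset(),
    exclude: frozenset[Cell] = frozenset(),
) -> list[tuple[Cell, int]]:
    """Choose landmark cells and split the 16-exposure budget among them.

    Under the *strict* variant (used on the main task) ``n_unique`` must
    divide the budget evenly (2, 4, 8 or 16 landmarks) and cells are
    unique, non-edge, non-obstacle.  Under *day2* (the forced-sampling
    control) the unique count may be anything in 2..16 (drawn uniformly
    when ``n_unique`` is None), edges are allowed, and the 16 clicks are
    spread over the chosen cells with every cell clicked at least once.
    """
    rng = _as_rng(rng)
    if variant == "strict":
        if n_unique not in (2, 4, 8, 16):
            raise MapGenerationError(
                f"strict variant needs 2, 4, 8 or 16 unique landmarks, got {n_unique}"
            )
        candidates = [
            cell for cell in _ALL_CELLS
            if cell not in _EDGE and cell not in obstacles and cell not in exclude
        ]
        if len(candidates) < n_unique:
            raise MapGenerationError("not enough free non-edge cells for landmarks")
        idx = rng.choice(len(candidates), size=n_unique, replace=False)
        per = EXPOSURE_BUDGET // n_unique
        return [(candidates[i], per) for i in idx]
    if variant == "day2":
        if n_unique is None:
            n_unique = int(rng.integers(2, 17))
        if not 2 <= n_unique <= EXPOSURE_BUDGET:
            raise MapGenerationError("day2 variant needs 2..16 unique landmarks")
        candidates = [
            cell for cell in _ALL_CELLS
            if cell not in obstacles and cell not in exclude
        ]
        idx = rng.choice(len(candidates), size=n_unique, replace=False)
        counts = np.ones(n_unique, dtype=int)
        extra = rng.integers(0, n_unique, size=EXPOSURE_BUDGET - n_unique)
        np.add.at(counts, extra, 1)
        return [(candidates[i], int(k)) for i, k in zip(idx, counts)]
    raise ValueError(f"unknown placement variant {variant!r}")


def generate_map(
    seed,
    environment_kind: str,
    n_unique_landmarks: int | None,
    placement_variant: str = "strict",
) -> GridMap:
    """Generate one trial's world, reproducibly from ``seed``.

    Cluttered maps place one obstacle in each interior row and column
    (8 in total) via a random column permutation.  The identity mapping
    is a fresh permutation of 1..64 over the interior.  The goal obeys
    the strict placement rule (non-edge, non-obstacle, distinct from
    every landmark) under both variants.
    """
    rng = _as_rng(seed)
    if environment_kind not in ("open", "cluttered"):
        raise ValueError(f"unknown environment kind {environment_kind!r}")

    if environment_kind == "cluttered":
        cols = rng.permutation(INTERIOR_SIZE)
        obstacles = frozenset((r, int(cols[r])) for r in range(INTERIOR_SIZE))
    else:
        obstacles = frozenset()

    ids = rng.permutation(64) + 1
    identity = {cell: int(ids[i]) for i, cell in enumerate(_ALL_CELLS)}

    # Goal first, then landmarks excluding the goal cell.
    goal_candidates = [
        cell for cell in _ALL_CELLS if cell not in _EDGE and cell not in obstacles
    ]
    if not goal_candidates:
        raise MapGenerationError("no eligible goal cell")
    goal = goal_candidates[int(rng.integers(len(goal_candidates)))]
    landmarks = allocate_landmark_exposures(
        n_unique_landmarks, placement_variant, rng,
        obstacles=obstacles, exclude=frozenset({goal}),
    )
    return GridMap(
        obstacles=obstacles,
        identity=identity,
        landmarks=tuple(landmarks),
        goal=goal,
        kind=environment_kind,
        variant=placement_variant,
    )


def build_exposure_schedule(
    landmarks: list[tuple[Cell, int]] | tuple[tuple[Cell, int], ...],
    rng,
) -> list[Cell]:
    """Order the 16 landmark exposures of the map-reading phase.

    Two constraints hold: no landmark appears twice consecutively, and
    each unique landmark appears once per round of ``n_unique``
    presentations before any repeats.  With 2 landmarks this forces
    strict alternation; with 16 it is a single permutation.
    """
    rng = _as_rng(rng)
    cells = [cell for cell, _ in landmarks]
    counts = {k for _, k in landmarks}
    if len(counts) != 1:
        raise ValueError("schedule requires equal exposure counts (strict variant)")
    per = counts.pop()
    n = len(cells)
    if n * per != EXPOSURE_BUDGET:
        raise ValueError("exposure counts do not sum to the 16-click budget")
    if n < 2:
        raise ValueError("need at least two unique landmarks to schedule")
    schedule: list[Cell] = []
    for _ in range(per):
        for _attempt in range(1000):
            perm = [cells[i] for i in rng.permutation(n)]
            if not schedule or perm[0] != schedule[-1]:
                break
        else:  # pragma: no cover - probability (1/n)^1000
            perm[0], perm[1] = perm[1], perm[0]
        schedule.extend(perm)
    return schedule


# ---------------------------------------------------------------------------
# Distances and start placement
# ---------------------------------------------------------------------------

def bfs_distances(grid: GridMap, source: Cell) -> dict[Cell, int]:
    """Breadth-first 4-neighbour path distances from ``source``."""
    if not grid.traversable(source):
        raise ValueError(f"source {source} is not traversable")
    dist = {source: 0}
    queue = deque([source])
    while queue:
        r, c = queue.popleft()
        d = dist[(r, c)]
        for dr, dc in DIRECTIONS:
            nxt = (r + dr, c + dc)
            if grid.traversable(nxt) and nxt not in dist:
                dist[nxt] = d + 1
                queue.append(nxt)
    return dist


def shortest_path_distance(grid: GridMap, a: Cell, b: Cell) -> int | None:
    """Shortest 4-neighbour path length avoiding obstacles; None if unreachable.

    Equals the Manhattan distance on open maps.
    """
    if not grid.traversable(a) or not grid.traversable(b):
        raise ValueError("endpoints must be traversable")
    return bfs_distances(grid, a).get(b)


def choose_start(grid: GridMap, config: EpisodeConfig, rng) -> Cell:
    """Pick a start cell exactly ``start_distance`` steps from the goal.

    The start may not be a landmark, the goal, an obstacle, or an edge
    cell.  (A day-2 bug in the original human experiment occasionally
    placed starts on landmarks; that bug is deliberately not reproduced.)
    """
    rng = _as_rng(rng)
    dist = bfs_distances(grid, grid.goal)
    eligible = [
        cell
        for cell, d in dist.items()
        if d == config.start_distance
        and cell not in _EDGE
        and cell not in grid.landmark_cells
        and cell != grid.goal
    ]
    if not eligible:
        raise StartPlacementError("no eligible start cell at the required distance")
    eligible.sort()
    return eligible[int(rng.integers(len(eligible)))]


def generate_trial(
    seed,
    environment_kind: str = "open",
    n_unique_landmarks: int = 4,
    placement_variant: str = "strict",
    config: EpisodeConfig | None = None,
    max_attempts: int = 100,
) -> tuple[GridMap, Cell]:
    """Generate a (map, start) pair, regenerating the map if start placement fails.

    Regeneration is capped at ``max_attempts`` to guarantee termination.
    """
    rng = _as_rng(seed)
    config = config or EpisodeConfig()
    for _ in range(max_attempts):
        grid = generate_map(rng, environment_kind, n_unique_landmarks, placement_variant)
        try:
            start = choose_start(grid, config, rng)
        except StartPlacementError:
            continue
        return grid, start
    raise MapGenerationError(
        f"no valid start placement in {max_attempts} map attempts"
    )


# ---------------------------------------------------------------------------
# Navigation-phase dynamics
# ---------------------------------------------------------------------------

def available_modalities(config: EpisodeConfig, rng) -> tuple[bool, bool]:
    """Per-step (directions_available, states_available) flags.

    Under random alternation exactly one modality is available each
    step; directions are drawn with ``p_direction_available`` (0.75 in
    open fields, 0.50 in cluttered environments).
    """
    if config.condition == "both":
        return True, True
    if config.condition == "directions_only":
        return True, False
    if config.condition == "states_only":
        return False, True
    rng = _as_rng(rng)
    direction = bool(rng.random() < config.p_direction_available)
    return direction, not direction


def init_state(grid: GridMap, start: Cell, config: EpisodeConfig, rng) -> EnvState:
    """Fresh episode state positioned at ``start`` with the opening balance."""
    d, s = available_modalities(config, rng)
    return EnvState(
        cell=start,
        points=config.start_points,
        visited={start},
        directions_available=d,
        states_available=s,
    )


def action_mask(state: EnvState, grid: GridMap) -> np.ndarray:
    """Boolean validity over the 8 actions.

    An action is valid iff its modality is available this step and its
    target cell is traversable.  Slots 0-3 are direction moves, 4-7
    state selections, both in N, S, W, E order.
    """
    mask = np.zeros(N_ACTIONS, dtype=bool)
    r, c = state.cell
    for i, (dr, dc) in enumerate(DIRECTIONS):
        ok = grid.traversable((r + dr, c + dc))
        mask[i] = ok and state.directions_available
        mask[i + 4] = ok and state.states_available
    return mask


def step(
    state: EnvState, grid: GridMap, action: int, config: EpisodeConfig, rng
) -> tuple[EnvState, str]:
    """Advance one step; returns the new state and an event label.

    Events: ``"moved"``, ``"blocked"`` (invalid target, no cost — only
    reachable when masking is disabled), ``"goal"`` (terminal, +1,000
    points) or ``"truncated"`` (200-step cap reached).  Every effective
    move costs 50 points, including the final move onto the goal.
    """
    if not 0 <= action < N_ACTIONS:
        raise ValueError(f"action index {action} out of range")
    r, c = state.cell
    dr, dc = DIRECTIONS[action % 4]
    target = (r + dr, c + dc)
    modality_ok = (
        state.directions_available if action < 4 else state.states_available
    )
    if not modality_ok or not grid.traversable(target):
        # Blocked clicks have no effect and incur no cost.
        return _copy_state(state), "blocked"
    new = EnvState(
        cell=target,
        step_index=state.step_index + 1,
        points=state.points - config.step_cost,
        visited=state.visited | {target},
        last_disp=(dc, dr),  # dx = column change, dy = row change
        directions_available=state.directions_available,
        states_available=state.states_available,
    )
    if target == grid.goal:
        new.points += config.goal_reward
        return new, "goal"
    if new.step_index >= config.max_steps:
        return new, "truncated"
    d, s = available_modalities(config, rng)
    new.directions_available, new.states_available = d, s
    return new, "moved"


def _copy_state(state: EnvState) -> EnvState:
    return EnvState(
        cell=state.cell,
        step_index=state.step_index,
        points=state.points,
        visited=set(state.visited),
        last_disp=state.last_disp,
        directions_available=state.directions_available,
        states_available=state.states_available,
    )


def score_probe(response_cell: Cell, true_cell: Cell) -> int:
    """Memory-probe points: 30/20/10/0 for grid-step error 0/1/2/>2."""
    d = abs(response_cell[0] - true_cell[0]) + abs(response_cell[1] - true_cell[1])
    return {0: 30, 1: 20, 2: 10}.get(d, 0)


# ---------------------------------------------------------------------------
# Observation assembly
# ---------------------------------------------------------------------------

def assemble_observation(
    state: EnvState, grid: GridMap, memory, config: EpisodeConfig
) -> np.ndarray:
    """Build the 48-slot input vector for the agent.

    Layout (lengths in parentheses): condition one-hot (4); obstacle
    x,y pairs sorted row-major, zeros in the open field (16); states
    available (1); directions available (1); current identity (1);
    adjacent identities N,S,W,E (4); goal identity (1); estimated
    current x,y (2); estimated adjacent x,y (8); estimated goal x,y
    (2); confidence current (1); confidence adjacent (4); confidence
    goal (1); last displacement dx,dy (2).  Identity integers are fed
    as raw scalars; coordinate estimates come from the trial's memory
    store (zeros for non-landmark identities).
    """
    obs = np.zeros(N_OBS, dtype=np.float64)
    obs[CONDITIONS.index(config.condition)] = 1.0
    if grid.obstacles:
        for i, (r, c) in enumerate(sorted(grid.obstacles)):
            obs[4 + 2 * i] = c  # x
            obs[5 + 2 * i] = r  # y
    obs[20] = float(state.states_available)
    obs[21] = float(state.directions_available)
    ids = [grid.identity_at(state.cell)]
    r, c = state.cell
    for dr, dc in DIRECTIONS:
        ids.append(grid.identity_at((r + dr, c + dc)))
    ids.append(grid.identity[grid.goal])
    obs[22] = ids[0]
    obs[23:27] = ids[1:5]
    obs[27] = ids[5]
    coords = np.zeros(12)
    confs = np.zeros(6)
    for j, ident in enumerate(ids):
        (x, y), sd = memory.recall(ident)
        coords[2 * j] = x
        coords[2 * j + 1] = y
        confs[j] = sd
    obs[28:40] = coords
    obs[40:46] = confs
    obs[46] = state.last_disp[0]
    obs[47] = state.last_disp[1]
    return obs


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def map_to_json(grid: GridMap) -> str:
    payload = {
        "interior_size": grid.interior_size,
        "obstacles": sorted(list(o) for o in grid.obstacles),
        "identity": {f"{r},{c}": v for (r, c), v in sorted(grid.identity.items())},
        "landmarks": [[r, c, n] for (r, c), n in grid.landmarks],
        "goal": list(grid.goal),
        "kind": grid.kind,
        "variant": grid.variant,
    }
    return json.dumps(payload)


def map_from_json(text: str) -> GridMap:
    data = json.loads(text)
    identity = {}
    for key, v in data["identity"].items():
        r, c = key.split(",")
        identity[(int(r), int(c))] = int(v)
    return GridMap(
        obstacles=frozenset(tuple(o) for o in data["obstacles"]),
        identity=identity,
        landmarks=tuple(((r, c), n) for r, c, n in data["landmarks"]),
        goal=tuple(data["goal"]),
        kind=data["kind"],
        variant=data["variant"],
        interior_size=data["interior_size"],
    )
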