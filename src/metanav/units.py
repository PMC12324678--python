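"""Unit-level analyses of the recurrent network.

Recurrent cell states are characterised the way hippocampal/cortical
recordings are: units are typed as *spatial* (main effect of spatial
quadrant only), *landmark* (main effect of landmark adjacency only) or
*conjunctive* (both main effects and/or an interaction) by a two-factor
ANOVA over smoothed mean-activation maps from four fixed two-landmark
environments; functional *vector* / *transition* modules are the units
whose cell state best linearly explains the direction / state action
logits; modules are lesioned by zeroing their cell and hidden states;
task variables are decoded with ridge (continuous locations) and
logistic (adjacency) read-outs; and representational geometry is
summarised by per-location PCA centroids.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.ndimage import gaussian_filter
from sklearn.decomposition import PCA
from sklearn.linear_model import LogisticRegression, Ridge
from sklearn.model_selection import train_test_split
from statsmodels.formula.api import ols

from metanav import agent as ag
from metanav import gridworld as gw
from metanav.logs import ActivationDataset

#: The four fixed two-landmark layouts used for unit typing, as interior
#: (row, col) cells.
ENV_SUITE: tuple[tuple[gw.Cell, gw.Cell], ...] = (
    ((2, 2), (5, 5)),
    ((2, 5), (5, 2)),
    ((2, 2), (5, 2)),
    ((2, 5), (5, 5)),
)

SMOOTHING_SIGMA = 0.7
ALPHA = 0.05


@dataclass
class UnitLabel:
    label: str  # spatial | landmark | conjunctive | none
    p_quadrant: float
    p_landmark: float
    p_interaction: float


@dataclass
class ModuleAssignment:
    """Vector/transition/unspecialized unit sets with their mean R^2."""

    vector: np.ndarray
    transition: np.ndarray
    unspecialized: np.ndarray
    r2_direction: np.ndarray
    r2_state: np.ndarray
    k: int


# ---------------------------------------------------------------------------
# Recording
# ---------------------------------------------------------------------------

def record_activations(
    params,
    n_trials_per_env: int = 1000,
    seed: int = 0,
    env_suite=ENV_SUITE,
    conditions: tuple[str, ...] = ("both",),
) -> ActivationDataset:
    """Greedy evaluation on the fixed landmark layouts, logging cell states."""
    parts = []
    rng = np.random.default_rng(seed)
    for env_id, cells in enumerate(env_suite):
        task = ag.TaskConfig(
            conditions=conditions, kinds=("open",), fixed_landmarks=tuple(cells)
        )
        _, ds = ag.evaluate(
            params, task, n_trials_per_env, rng.integers(2**31),
            record_activations=True, env_id=env_id,
        )
        parts.append(ds)
    return ActivationDataset.concat(parts)


# ---------------------------------------------------------------------------
# Spatial maps and unit typing
# ---------------------------------------------------------------------------

def unit_spatial_maps(dataset: ActivationDataset, unit: int) -> np.ndarray:
    """Per-environment 8x8 mean-activation maps, Gaussian-smoothed.

    Unvisited cells (rare at 1,000 trials per environment) are imputed
    with the unit's grand mean before smoothing; smoothing uses
    sigma=0.7 cells with reflective boundaries, which conserves the map
    mean for a constant field.
    """
    env_ids = np.unique(dataset.env_id)
    size = gw.INTERIOR_SIZE
    maps = np.zeros((len(env_ids), size, size))
    act = dataset.activations[:, unit]
    grand = float(act.mean())
    for k, env in enumerate(env_ids):
        sel = dataset.env_id == env
        sums = np.zeros((size, size))
        counts = np.zeros((size, size))
        np.add.at(sums, (dataset.cell[sel, 0], dataset.cell[sel, 1]), act[sel])
        np.add.at(counts, (dataset.cell[sel, 0], dataset.cell[sel, 1]), 1.0)
        with np.errstate(invalid="ignore"):
            m = np.where(counts > 0, sums / np.maximum(counts, 1), grand)
        maps[k] = gaussian_filter(m, sigma=SMOOTHING_SIGMA, mode="reflect")
    return maps


def quadrant_of(cell: gw.Cell) -> int:
    """Quadrant index of an interior cell: the four 4x4 blocks."""
    half = gw.INTERIOR_SIZE // 2
    return int(cell[0] >= half) * 2 + int(cell[1] >= half)


def landmark_adjacent_map(landmark_cells) -> np.ndarray:
    """Boolean 8x8 map of cells on or 4-adjacent to a landmark."""
    size = gw.INTERIOR_SIZE
    out = np.zeros((size, size), dtype=bool)
    for r, c in landmark_cells:
        out[r, c] = True
        for dr, dc in gw.DIRECTIONS:
            rr, cc = r + dr, c + dc
            if 0 <= rr < size and 0 <= cc < size:
                out[rr, cc] = True
    return out


def classify_unit_from_maps(maps: np.ndarray, landmark_layouts) -> UnitLabel:
    """Two-factor ANOVA (quadrant x landmark adjacency) on the 256 map values."""
    rows = []
    size = gw.INTERIOR_SIZE
    for env, layout in enumerate(landmark_layouts):
        adj = landmark_adjacent_map(layout)
        for r in range(size):
            for c in range(size):
                rows.append({
                    "act": maps[env, r, c],
                    "quadrant": quadrant_of((r, c)),
                    "lm": int(adj[r, c]),
                })
    df = pd.DataFrame(rows)
    if df["act"].std() < 1e-12:
        return UnitLabel("none", 1.0, 1.0, 1.0)
    model = ols("act ~ C(quadrant) * C(lm)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    p_quad = float(table.loc["C(quadrant)", "PR(>F)"])
    p_lm = float(table.loc["C(lm)", "PR(>F)"])
    p_int = float(table.loc["C(quadrant):C(lm)", "PR(>F)"])
    sig_quad, sig_lm, sig_int = p_quad < ALPHA, p_lm < ALPHA, p_int < ALPHA
    if (sig_quad and sig_lm) or sig_int:
        label = "conjunctive"
    elif sig_quad:
        label = "spatial"
    elif sig_lm:
        label = "landmark"
    else:
        label = "none"
    return UnitLabel(label, p_quad, p_lm, p_int)


def classify_units(
    dataset: ActivationDataset, landmark_layouts=ENV_SUITE
) -> list[UnitLabel]:
    """Type every unit from its smoothed spatial maps."""
    return [
        classify_unit_from_maps(unit_spatial_maps(dataset, u), landmark_layouts)
        for u in range(dataset.n_units)
    ]


# ---------------------------------------------------------------------------
# Functional modules
# ---------------------------------------------------------------------------

def identify_functional_modules(dataset: ActivationDataset, k: int = 10) -> ModuleAssignment:
    """Rank units by how much variance their cell state explains in the logits.

    Each unit's cell state is regressed onto each of the 8 action
    logits; R^2 values are averaged over the 4 direction logits and the
    4 state logits separately.  The top-k units per criterion form the
    vector / transition modules (overlaps go to the criterion with the
    higher R^2, backfilling from the next rank; ties break by unit
    index) and the bottom-k on the maximum of the two averages form the
    unspecialized set.
    """
    n_units = dataset.n_units
    if k > n_units:
        raise ValueError(f"k={k} exceeds available units ({n_units})")
    act = dataset.activations
    logits = dataset.logits
    r2 = np.zeros((n_units, logits.shape[1]))
    act_c = act - act.mean(axis=0)
    logit_c = logits - logits.mean(axis=0)
    act_ss = (act_c**2).sum(axis=0)
    logit_ss = (logit_c**2).sum(axis=0)
    # Simple univariate regression: R^2 equals the squared correlation.
    cov = act_c.T @ logit_c
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.nan_to_num(cov**2 / np.outer(act_ss, logit_ss))
    r2_dir = r2[:, :4].mean(axis=1)
    r2_state = r2[:, 4:].mean(axis=1)
    if k == 0:
        empty = np.array([], dtype=int)
        return ModuleAssignment(empty, empty, empty, r2_dir, r2_state, 0)
    order_dir = np.lexsort((np.arange(n_units), -r2_dir))
    order_state = np.lexsort((np.arange(n_units), -r2_state))
    vector, transition = _assign_topk(order_dir, order_state, r2_dir, r2_state, k)
    worst = np.maximum(r2_dir, r2_state)
    unspecialized = np.lexsort((np.arange(n_units), worst))[:k]
    return ModuleAssignment(
        np.array(sorted(vector), dtype=int),
        np.array(sorted(transition), dtype=int),
        np.array(sorted(unspecialized), dtype=int),
        r2_dir,
        r2_state,
        k,
    )


def _assign_topk(order_dir, order_state, r2_dir, r2_state, k):
    """Disjoint top-k sets, overlaps resolved by the higher R^2 with backfill."""
    want_dir = list(order_dir)
    want_state = list(order_state)
    vector: list[int] = []
    transition: list[int] = []
    taken: set[int] = set()
    contested = set(want_dir[:k]) & set(want_state[:k])
    for u in contested:
        if r2_dir[u] >= r2_state[u]:
            vector.append(u)
        else:
            transition.append(u)
        taken.add(u)
    for target, ranking in ((vector, want_dir), (transition, want_state)):
        for u in ranking:
            if len(target) >= k:
                break
            if u not in taken:
                target.append(u)
                taken.add(u)
    return vector, transition


# ---------------------------------------------------------------------------
# Lesions
# ---------------------------------------------------------------------------

def apply_lesion(params, unit_set):
    """Forward function with the given units' cell and hidden states zeroed.

    An empty set reproduces the intact network bit-for-bit; lesioning
    is idempotent because the zeroing happens at every timestep.
    """
    lesion = np.asarray(sorted(unit_set), dtype=int)

    def lesioned_forward(observation, recurrent_state):
        return ag.forward(params, observation, recurrent_state, lesion=lesion)

    return lesioned_forward


def evaluate_lesioned(
    params,
    lesions: dict[str, np.ndarray],
    task: ag.TaskConfig,
    n_trials: int = 4000,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-lesion, per-condition excess steps-to-goal vs the intact model.

    Lesioned and intact models run on identical trial seeds so deltas
    are paired.  Also reports the shift in direction-modality use.
    """
    rows = []
    intact_by_cond = {}
    for condition in task.conditions:
        sub = ag.TaskConfig(
            conditions=(condition,), kinds=task.kinds,
            n_landmarks_choices=task.n_landmarks_choices,
            zero_noise=task.zero_noise, fixed_landmarks=task.fixed_landmarks,
        )
        log, _ = ag.evaluate(params, sub, n_trials // len(task.conditions), seed)
        intact_by_cond[condition] = log
    for name, unit_set in lesions.items():
        for condition in task.conditions:
            sub = ag.TaskConfig(
                conditions=(condition,), kinds=task.kinds,
                n_landmarks_choices=task.n_landmarks_choices,
                zero_noise=task.zero_noise, fixed_landmarks=task.fixed_landmarks,
            )
            log, _ = ag.evaluate(
                params, sub, n_trials // len(task.conditions), seed, lesion=unit_set
            )
            intact = intact_by_cond[condition]
            rows.append({
                "lesion": name,
                "condition": condition,
                "excess_steps": float(
                    log.trials["steps_to_goal"].mean()
                    - intact.trials["steps_to_goal"].mean()
                ),
                "direction_use": float((log.steps["modality"] == "direction").mean()),
                "intact_direction_use": float(
                    (intact.steps["modality"] == "direction").mean()
                ),
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Decoding
# ---------------------------------------------------------------------------

def decode_continuous(
    dataset: ActivationDataset,
    unit_set,
    target: str = "current",
    alpha: float = 0.5,
    test_size: float = 0.2,
    seed: int = 0,
) -> float:
    """Mean held-out Euclidean error of ridge-decoded (x, y) location.

    Separate ridge regressions (penalty ``alpha``) predict x and y of
    the current or goal location from the chosen units' cell states;
    the 80/20 split is seeded.
    """
    if len(dataset) < 100:
        raise ValueError("need at least 100 timesteps to decode")
    X = dataset.activations[:, np.asarray(sorted(unit_set), dtype=int)]
    cells = dataset.cell if target == "current" else dataset.goal_cell
    # (x, y) = (col, row)
    Y = np.column_stack([cells[:, 1], cells[:, 0]]).astype(float)
    if len(np.unique(Y, axis=0)) < 2:
        raise ValueError("fewer than 2 distinct target locations")
    Xtr, Xte, Ytr, Yte = train_test_split(X, Y, test_size=test_size, random_state=seed)
    pred = np.column_stack([
        Ridge(alpha=alpha).fit(Xtr, Ytr[:, j]).predict(Xte) for j in range(2)
    ])
    return float(np.sqrt(((pred - Yte) ** 2).sum(axis=1)).mean())


def decode_binary(
    dataset: ActivationDataset,
    unit_set,
    target: str = "landmark",
    test_size: float = 0.2,
    seed: int = 0,
) -> float:
    """Held-out misclassification rate for landmark/goal adjacency.

    The majority class is under-sampled (seeded) to match class counts
    before the 80/20 split; the classifier is a logistic regression on
    the chosen units' cell states.
    """
    y = (dataset.landmark_adj if target == "landmark" else dataset.goal_adj).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError(f"only one {target}-adjacency class present")
    X = dataset.activations[:, np.asarray(sorted(unit_set), dtype=int)]
    rng = np.random.default_rng(seed)
    idx0 = np.flatnonzero(y == 0)
    idx1 = np.flatnonzero(y == 1)
    n = min(len(idx0), len(idx1))
    keep = np.concatenate([
        rng.choice(idx0, size=n, replace=False),
        rng.choice(idx1, size=n, replace=False),
    ])
    Xb, yb = X[keep], y[keep]
    Xtr, Xte, ytr, yte = train_test_split(
        Xb, yb, test_size=test_size, random_state=seed, stratify=yb
    )
    clf = LogisticRegression(max_iter=2000).fit(Xtr, ytr)
    return float((clf.predict(Xte) != yte).mean())


# ---------------------------------------------------------------------------
# Representational geometry
# ---------------------------------------------------------------------------

def representational_pca(
    dataset: ActivationDataset,
    unit_set,
    condition_split: str = "post_landmark",
    n_components: int = 3,
) -> pd.DataFrame:
    """Mean principal-component scores per (cell, condition).

    PCA (mean-centering only) runs on the chosen units' cell states;
    the first ``n_components`` scores are averaged per grid location
    under each level of the condition flag (pre/post first landmark
    encounter, or on-landmark vs not).
    """
    units = np.asarray(sorted(unit_set), dtype=int)
    if len(units) < n_components:
        raise ValueError("need at least as many units as components")
    X = dataset.activations[:, units]
    pca = PCA(n_components=n_components)
    scores = pca.fit_transform(X)
    if condition_split == "post_landmark":
        cond = dataset.post_landmark.astype(int)
    elif condition_split == "on_landmark":
        cond = dataset.landmark_adj.astype(int)
    else:
        raise ValueError(f"unknown condition split {condition_split!r}")
    df = pd.DataFrame({
        "r": dataset.cell[:, 0], "c": dataset.cell[:, 1], "condition": cond,
        **{f"pc{i + 1}": scores[:, i] for i in range(n_components)},
    })
    out = df.groupby(["r", "c", "condition"]).mean().reset_index()
    out.attrs["explained_variance_ratio"] = pca.explained_variance_ratio_
    return out
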