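"""Recurrent policy/value network and masked-action PPO training.

The agent is an LSTM with 100 recurrent units feeding separate policy
and value heads (two fully connected tanh layers of 64 units each).
Invalid actions — moves into walls or obstacles, or responses of a
modality unavailable this step — are masked by replacing their logits
with a large negative constant before the softmax, so they are never
chosen and never enter the policy or entropy losses.

Training uses Proximal Policy Optimization with a clipped surrogate
objective::

    L_total = L_policy + c1 * L_value - c2 * L_entropy
    L_policy = -E[ min(r_t A_t, clip(r_t, 1-eps, 1+eps) A_t) ]
    L_value  =  E[ (V(s_t) - R_t)^2 ]
    L_entropy = E[ policy entropy over valid actions ]

with advantages from generalized advantage estimation (gamma=0.99,
lambda=0.95 by default) and gradients clipped to global norm 0.5.
Episodes truncated at the 200-step cap are bootstrapped as
non-terminal.  The full-scale configuration (128 environments x 8,192
steps per update x 8,000 updates) matches the published training
regime; the desk-scale default (8 x 256 x 300) is sized for a single
CPU and is what the analysis scripts and tests run.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from metanav import gridworld as gw
from metanav import memory as mem
from metanav.autodiff import Adam, Tensor, log_softmax
from metanav.logs import ActivationDataset, TrajectoryLog

MASK_CONSTANT = -1e8

#: Fixed per-slot observation scaling applied inside the network before the
#: LSTM.  Identity slots span 1..65 and coordinate slots 0..7; without
#: rescaling the first-layer pre-activations saturate tanh/sigmoid gates.
#: This is a conditioning choice internal to the network: the observation
#: contract (raw integers and coordinates) is unchanged.
def default_obs_scale() -> np.ndarray:
    scale = np.ones(gw.N_OBS)
    scale[4:20] = 1 / 7.0        # obstacle coordinates
    scale[22:28] = 1 / 65.0      # identity integers
    scale[28:40] = 1 / 7.0       # estimated coordinates
    scale[40:46] = 1 / 2.0       # confidence (noise s.d.)
    return scale


@dataclass(frozen=True)
class NetworkConfig:
    n_input: int = gw.N_OBS
    n_recurrent: int = 100
    head_hidden: int = 64
    n_head_layers: int = 2
    n_actions: int = gw.N_ACTIONS
    scale_observations: bool = True


@dataclass(frozen=True)
class PPOConfig:
    learning_rate: float = 3e-4
    vf_coef: float = 0.5          # c1
    ent_coef: float = 0.001       # c2
    clip_range: float = 0.2       # epsilon
    max_grad_norm: float = 0.5
    gamma: float = 0.99
    gae_lambda: float = 0.95
    n_epochs: int = 4
    normalize_advantage: bool = True
    n_envs: int = 8
    rollout_steps: int = 256
    n_updates: int = 300

    def __post_init__(self):
        if not 0 < self.clip_range < 1:
            raise ValueError("clip_range must be in (0, 1)")
        for name in ("vf_coef", "ent_coef", "learning_rate", "max_grad_norm"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @staticmethod
    def desk_scale(**overrides) -> "PPOConfig":
        return PPOConfig(**overrides)

    @staticmethod
    def full_scale(**overrides) -> "PPOConfig":
        """Published regime: 128 envs x 8,192 steps = 1,048,576 steps/update."""
        base = dict(n_envs=128, rollout_steps=8192, n_updates=8000)
        base.update(overrides)
        return PPOConfig(**base)

    @property
    def steps_per_update(self) -> int:
        return self.n_envs * self.rollout_steps


@dataclass(frozen=True)
class TaskConfig:
    """Which task distribution the agent trains or is evaluated on."""

    conditions: tuple[str, ...] = gw.CONDITIONS
    kinds: tuple[str, ...] = ("open", "cluttered")
    n_landmarks_choices: tuple[int, ...] = (2, 4, 8, 16)
    placement_variant: str = "strict"
    zero_noise: bool = False
    fixed_landmarks: tuple[gw.Cell, ...] | None = None


# ---------------------------------------------------------------------------
# Network parameters and forward passes
# ---------------------------------------------------------------------------

def init_network(config: NetworkConfig, seed) -> dict[str, Tensor]:
    """Initialise all parameters, reproducibly from ``seed``.

    Weights are scaled-normal (1/sqrt(fan_in)); the forget-gate bias is
    initialised to 1, a standard stabilisation for LSTM training.
    """
    rng = np.random.default_rng(seed)
    H, I, A, D = config.n_recurrent, config.n_input, config.n_actions, config.head_hidden

    def w(shape, fan_in):
        return Tensor(rng.normal(0.0, 1.0 / np.sqrt(fan_in), size=shape))

    params = {
        "Wx": w((I, 4 * H), I),
        "Wh": w((H, 4 * H), H),
        "b": Tensor(np.zeros(4 * H)),
    }
    params["b"].data[H:2 * H] = 1.0  # forget gate
    sizes = [H] + [D] * config.n_head_layers
    for head in ("p", "v"):
        for i in range(config.n_head_layers):
            params[f"{head}W{i}"] = w((sizes[i], sizes[i + 1]), sizes[i])
            params[f"{head}b{i}"] = Tensor(np.zeros(sizes[i + 1]))
    params["pWout"] = w((D, A), D)
    params["pbout"] = Tensor(np.zeros(A))
    params["vWout"] = w((D, 1), D)
    params["vbout"] = Tensor(np.zeros(1))
    params["_obs_scale"] = Tensor(
        default_obs_scale() if config.scale_observations else np.ones(I),
        requires_grad=False,
    )
    return params


def trainable(params: dict[str, Tensor]) -> dict[str, Tensor]:
    return {k: v for k, v in params.items() if not k.startswith("_")}


def init_recurrent_state(params, batch: int) -> tuple[np.ndarray, np.ndarray]:
    H = params["Wh"].data.shape[0]
    return np.zeros((batch, H)), np.zeros((batch, H))


def _np(params):  # raw ndarray view of the parameters
    return {k: v.data for k, v in params.items()}


def forward(params, observation, recurrent_state, lesion=None):
    """One deterministic step: (logits, value, (h', c')).

    ``observation`` is (48,) or (batch, 48).  ``lesion`` is an optional
    index array of recurrent units whose hidden and cell states are
    forced to zero at every timestep.
    """
    p = _np(params)
    obs = np.atleast_2d(np.asarray(observation, dtype=np.float64))
    if obs.shape[-1] != p["Wx"].shape[0]:
        raise ValueError(f"observation length {obs.shape[-1]} != {p['Wx'].shape[0]}")
    h, c = recurrent_state
    H = p["Wh"].shape[0]
    x = obs * p["_obs_scale"]
    z = x @ p["Wx"] + h @ p["Wh"] + p["b"]
    i = _sigmoid(z[:, :H])
    f = _sigmoid(z[:, H:2 * H])
    g = np.tanh(z[:, 2 * H:3 * H])
    o = _sigmoid(z[:, 3 * H:])
    c_new = f * c + i * g
    h_new = o * np.tanh(c_new)
    if lesion is not None and len(lesion):
        h_new = h_new.copy()
        c_new = c_new.copy()
        h_new[:, lesion] = 0.0
        c_new[:, lesion] = 0.0
    a = h_new
    n_layers = _n_head_layers(params)
    pa, va = a, a
    for j in range(n_layers):
        pa = np.tanh(pa @ p[f"pW{j}"] + p[f"pb{j}"])
        va = np.tanh(va @ p[f"vW{j}"] + p[f"vb{j}"])
    logits = pa @ p["pWout"] + p["pbout"]
    value = (va @ p["vWout"] + p["vbout"])[:, 0]
    if np.asarray(observation).ndim == 1:
        return logits[0], float(value[0]), (h_new, c_new)
    return logits, value, (h_new, c_new)


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


def _n_head_layers(params) -> int:
    n = 0
    while f"pW{n}" in params:
        n += 1
    return n


def mask_logits(logits, mask):
    """Replace invalid-action logits with a large negative constant.

    Works on NumPy arrays and on autodiff Tensors (gradient flows only
    through valid slots).  Raises if any row has no valid action.
    """
    mask_arr = np.asarray(mask, dtype=bool)
    if not np.all(mask_arr.any(axis=-1)):
        raise ValueError("action mask with no valid action")
    if isinstance(logits, Tensor):
        m = Tensor(mask_arr.astype(float), requires_grad=False)
        return logits * m + Tensor((1.0 - mask_arr) * MASK_CONSTANT, requires_grad=False)
    return np.where(mask_arr, logits, MASK_CONSTANT)


# ---------------------------------------------------------------------------
# Advantages and losses
# ---------------------------------------------------------------------------

def compute_advantages(rewards, values, dones, config: PPOConfig):
    """Generalized advantage estimates and returns R_t = A_t + V_t.

    ``rewards`` and ``dones`` have shape (T, ...) and ``values``
    (T+1, ...) including the bootstrap value of the state after the
    rollout.  ``dones`` marks true episode terminations; bootstrapping
    for truncated episodes is handled by folding gamma*V(next) into the
    truncating step's reward before calling this function.
    """
    rewards = np.asarray(rewards, dtype=np.float64)
    values = np.asarray(values, dtype=np.float64)
    dones = np.asarray(dones, dtype=np.float64)
    T = rewards.shape[0]
    if values.shape[0] != T + 1:
        raise ValueError("values must include the bootstrap row (T+1 entries)")
    adv = np.zeros_like(rewards)
    gae = np.zeros_like(rewards[0])
    for t in range(T - 1, -1, -1):
        not_done = 1.0 - dones[t]
        delta = rewards[t] + config.gamma * values[t + 1] * not_done - values[t]
        gae = delta + config.gamma * config.gae_lambda * not_done * gae
        adv[t] = gae
    returns = adv + values[:-1]
    return adv, returns


def ppo_loss_terms(new_logp, old_logp, advantages, values, returns, entropy,
                   config: PPOConfig):
    """The four PPO losses from per-sample quantities (NumPy or Tensor).

    Returns (L_policy, L_value, L_entropy, L_total).  Minimising
    L_total maximises the clipped surrogate objective and the policy
    entropy while regressing the value head onto the returns.
    """
    is_tensor = isinstance(new_logp, Tensor)
    if is_tensor:
        ratio = (new_logp - Tensor(old_logp, requires_grad=False)).exp()
        adv = Tensor(advantages, requires_grad=False)
        surr = (ratio * adv).minimum(
            ratio.clip(1 - config.clip_range, 1 + config.clip_range) * adv
        )
        l_policy = -surr.mean()
        l_value = ((values - Tensor(returns, requires_grad=False)) ** 2).mean()
        l_entropy = entropy.mean()
    else:
        ratio = np.exp(np.asarray(new_logp) - np.asarray(old_logp))
        clipped = np.clip(ratio, 1 - config.clip_range, 1 + config.clip_range)
        l_policy = -np.mean(np.minimum(ratio * advantages, clipped * advantages))
        l_value = np.mean((np.asarray(values) - np.asarray(returns)) ** 2)
        l_entropy = np.mean(entropy)
    l_total = l_policy + config.vf_coef * l_value - config.ent_coef * l_entropy
    return l_policy, l_value, l_entropy, l_total


@dataclass
class RolloutBatch:
    """Time-aligned rollout storage for one PPO update."""

    observations: np.ndarray   # (T, N, 48)
    actions: np.ndarray        # (T, N)
    masks: np.ndarray          # (T, N, 8) boolean validity
    old_logp: np.ndarray       # (T, N)
    advantages: np.ndarray     # (T, N)
    returns: np.ndarray        # (T, N)
    episode_starts: np.ndarray  # (T, N) 1.0 where a new episode begins
    h0: np.ndarray             # (N, H) recurrent state at rollout start
    c0: np.ndarray             # (N, H)

    def __post_init__(self):
        T, N = self.actions.shape
        for name in ("observations", "masks", "old_logp", "advantages",
                     "returns", "episode_starts"):
            if getattr(self, name).shape[:2] != (T, N):
                raise ValueError(f"batch field {name!r} not time-aligned")
        chosen_valid = np.take_along_axis(
            self.masks, self.actions[..., None], axis=-1
        )
        if not chosen_valid.all():
            raise ValueError("batch contains a masked (invalid) chosen action")


def _lstm_sequence(zx_all: Tensor, Wh: Tensor, h0, c0, keep) -> Tensor:
    """Fused LSTM recurrence over a (T, N, 4H) input-projection tensor.

    One tape node whose backward is a hand-written, fully vectorised
    backpropagation-through-time loop; this avoids building thousands
    of small tape nodes for long rollouts.  ``keep`` is (T, N) with 0
    wherever an episode starts (state reset, gradient cut).  Gradients
    flow to the input projections and to ``Wh``; the rollout-boundary
    states ``h0``/``c0`` are constants (truncated BPTT).
    """
    zx = zx_all.data
    T, N, H4 = zx.shape
    H = H4 // 4
    W = Wh.data
    hs = np.empty((T, N, H))
    cache_i = np.empty((T, N, H)); cache_f = np.empty((T, N, H))
    cache_g = np.empty((T, N, H)); cache_o = np.empty((T, N, H))
    cache_tc = np.empty((T, N, H))
    cache_hin = np.empty((T, N, H)); cache_cin = np.empty((T, N, H))
    h, c = h0, c0
    for t in range(T):
        k = keep[t][:, None]
        hin = h * k
        cin = c * k
        z = zx[t] + hin @ W
        i = _sigmoid(z[:, :H])
        f = _sigmoid(z[:, H:2 * H])
        g = np.tanh(z[:, 2 * H:3 * H])
        o = _sigmoid(z[:, 3 * H:])
        c = f * cin + i * g
        tc = np.tanh(c)
        h = o * tc
        hs[t] = h
        cache_i[t], cache_f[t], cache_g[t], cache_o[t] = i, f, g, o
        cache_tc[t], cache_hin[t], cache_cin[t] = tc, hin, cin
    out = Tensor(hs, (zx_all, Wh))

    def back(g_out):
        dzx = np.zeros_like(zx)
        dW = np.zeros_like(W)
        dh_rec = np.zeros((N, H))
        dc_rec = np.zeros((N, H))
        Wt = W.T
        for t in range(T - 1, -1, -1):
            i, f, g, o = cache_i[t], cache_f[t], cache_g[t], cache_o[t]
            tc, hin, cin = cache_tc[t], cache_hin[t], cache_cin[t]
            dh = g_out[t] + dh_rec
            do = dh * tc
            dc = dc_rec + dh * o * (1.0 - tc**2)
            df = dc * cin
            di = dc * g
            dg = dc * i
            dz = np.concatenate(
                [di * i * (1 - i), df * f * (1 - f),
                 dg * (1 - g**2), do * o * (1 - o)], axis=1
            )
            dzx[t] = dz
            dW += hin.T @ dz
            k = keep[t][:, None]
            dh_rec = (dz @ Wt) * k
            dc_rec = dc * f * k
        zx_all._accum(dzx)
        Wh._accum(dW)

    out._backward = back
    return out


def _forward_sequence_tape(params, batch: RolloutBatch):
    """Differentiable replay of a rollout; returns per-step Tensors.

    The recurrent state is reset (multiplied by zero) wherever an
    episode started, exactly as during collection.
    """
    p = params
    T, N = batch.actions.shape
    H = p["Wh"].data.shape[0]
    scale = p["_obs_scale"].data
    n_layers = _n_head_layers(params)
    # Input projections have no recurrence: one big matmul for all steps.
    x_all = Tensor(
        (batch.observations * scale).reshape(T * N, -1), requires_grad=False
    )
    zx_all = (x_all @ p["Wx"] + p["b"]).reshape(T, N, 4 * H)
    keep = 1.0 - batch.episode_starts
    hs = _lstm_sequence(zx_all, p["Wh"], batch.h0, batch.c0, keep).reshape(T * N, H)
    pa, va = hs, hs
    for j in range(n_layers):
        pa = (pa @ p[f"pW{j}"] + p[f"pb{j}"]).tanh()
        va = (va @ p[f"vW{j}"] + p[f"vb{j}"]).tanh()
    logits = pa @ p["pWout"] + p["pbout"]
    values = (va @ p["vWout"] + p["vbout"]).reshape(T, N)
    masks_flat = batch.masks.reshape(T * N, -1)
    masked = mask_logits(logits, masks_flat)
    logp_all = log_softmax(masked, axis=-1)
    onehot = np.eye(logits.data.shape[-1])[batch.actions.reshape(-1)]
    logp = (logp_all * Tensor(onehot, requires_grad=False)).sum(axis=-1)
    probs = logp_all.exp()
    valid = Tensor(masks_flat.astype(float), requires_grad=False)
    ent = -((probs * logp_all) * valid).sum(axis=-1)
    return logp.reshape(T, N), ent.reshape(T, N), values


def ppo_losses(params, batch: RolloutBatch, config: PPOConfig):
    """Full differentiable PPO losses for a rollout batch.

    Returns (L_policy, L_value, L_entropy, L_total) as scalar Tensors;
    call ``.backward()`` on L_total to populate parameter gradients.
    """
    new_logp, entropy, values = _forward_sequence_tape(params, batch)
    return ppo_loss_terms(
        new_logp, batch.old_logp, batch.advantages, values, batch.returns,
        entropy, config,
    )


# ---------------------------------------------------------------------------
# Environment sessions
# ---------------------------------------------------------------------------

class EpisodeSession:
    """One live navigation episode: map, memory store and env state."""

    def __init__(self, task: TaskConfig, rng: np.random.Generator):
        self.rng = rng
        condition = task.conditions[int(rng.integers(len(task.conditions)))]
        kind = task.kinds[int(rng.integers(len(task.kinds)))]
        n_lm = task.n_landmarks_choices[int(rng.integers(len(task.n_landmarks_choices)))]
        self.config = gw.EpisodeConfig(
            condition=condition, p_direction_available=gw.default_p_direction(kind)
        )
        if task.fixed_landmarks is not None:
            self.grid, start = _fixed_landmark_trial(task.fixed_landmarks, rng, self.config)
        else:
            self.grid, start = gw.generate_trial(
                rng, kind, n_lm, task.placement_variant, self.config
            )
        if task.zero_noise:
            params = mem.MemoryNoiseParams(0.0, 0.0, 0.0)
        else:
            m, c = mem.draw_landmark_noise_params(rng)
            params = mem.MemoryNoiseParams(mem.draw_goal_noise(rng), m, c)
        self.memory = mem.build_memory_store(self.grid, params, rng)
        self.state = gw.init_state(self.grid, start, self.config, rng)
        self.seen_landmark = False
        self._update_seen()

    def _update_seen(self):
        if self.state.cell in self.grid.landmark_cells:
            self.seen_landmark = True

    def observation(self) -> np.ndarray:
        return gw.assemble_observation(self.state, self.grid, self.memory, self.config)

    def mask(self) -> np.ndarray:
        return gw.action_mask(self.state, self.grid)

    def step(self, action: int) -> tuple[float, bool, bool]:
        """Apply an action; returns (reward, terminal, truncated).

        The training reward is the human point schedule scaled by 1/1000:
        -0.05 per step, +1.0 on reaching the goal.
        """
        self.state, event = gw.step(self.state, self.grid, action, self.config, self.rng)
        self._update_seen()
        if event == "goal":
            return 0.95, True, False
        if event == "truncated":
            return -0.05, False, True
        return -0.05, False, False


def _fixed_landmark_trial(cells, rng, config):
    """Open-field trial with landmarks pinned to given interior cells."""
    grid = gw.generate_map(rng, "open", len(cells) if len(cells) in (2, 4, 8, 16) else 2,
                           "strict")
    per = gw.EXPOSURE_BUDGET // len(cells)
    goal_candidates = [
        cell for cell in grid.identity
        if grid.traversable(cell)
        and cell not in cells
        and not (cell[0] in (0, 7) or cell[1] in (0, 7))
    ]
    goal = goal_candidates[int(rng.integers(len(goal_candidates)))]
    grid = gw.GridMap(
        obstacles=grid.obstacles,
        identity=grid.identity,
        landmarks=tuple((tuple(c), per) for c in cells),
        goal=goal,
        kind="open",
        variant="strict",
    )
    start = gw.choose_start(grid, config, rng)
    return grid, start


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def train(task: TaskConfig, net_config: NetworkConfig, ppo_config: PPOConfig, seed):
    """Meta-train the agent; returns (params, training curve DataFrame).

    Conditions and environment kinds are interleaved at random across
    the parallel environments.  The curve logs, per update, the mean
    episode length and reward of episodes finished during that rollout,
    the losses and the pre-clip gradient norm.
    """
    rng = np.random.default_rng(seed)
    params = init_network(net_config, rng.integers(2**31))
    if ppo_config.n_updates == 0:
        return params, pd.DataFrame(
            columns=["update", "ep_len", "ep_reward", "l_policy", "l_value",
                     "l_entropy", "l_total", "grad_norm"]
        )
    opt = Adam(trainable(params), lr=ppo_config.learning_rate)
    N, T = ppo_config.n_envs, ppo_config.rollout_steps
    envs = [EpisodeSession(task, np.random.default_rng(rng.integers(2**31)))
            for _ in range(N)]
    h, c = init_recurrent_state(params, N)
    pending_start = np.ones(N)  # episode begins at rollout start
    curve = []
    for update in range(ppo_config.n_updates):
        obs_buf = np.zeros((T, N, net_config.n_input))
        act_buf = np.zeros((T, N), dtype=np.int64)
        mask_buf = np.zeros((T, N, net_config.n_actions), dtype=bool)
        logp_buf = np.zeros((T, N))
        val_buf = np.zeros((T + 1, N))
        rew_buf = np.zeros((T, N))
        done_buf = np.zeros((T, N))
        start_buf = np.zeros((T, N))
        h0, c0 = h.copy(), c.copy()
        ep_lens, ep_rews = [], []
        ep_len = np.zeros(N)
        ep_rew = np.zeros(N)
        for t in range(T):
            start_buf[t] = pending_start
            h = h * (1.0 - pending_start)[:, None]
            c = c * (1.0 - pending_start)[:, None]
            pending_start = np.zeros(N)
            obs = np.stack([e.observation() for e in envs])
            masks = np.stack([e.mask() for e in envs])
            logits, values, (h, c) = forward(params, obs, (h, c))
            masked = mask_logits(logits, masks)
            logp_all = masked - _logsumexp(masked)
            probs = np.exp(logp_all)
            actions = _sample_rows(probs, rng, masks)
            obs_buf[t] = obs
            act_buf[t] = actions
            mask_buf[t] = masks
            logp_buf[t] = np.take_along_axis(logp_all, actions[:, None], 1)[:, 0]
            val_buf[t] = values
            for n, env in enumerate(envs):
                reward, terminal, truncated = env.step(int(actions[n]))
                ep_len[n] += 1
                ep_rew[n] += reward
                done_buf[t, n] = float(terminal)
                if truncated:
                    # Non-terminal cap: bootstrap with the value of the
                    # state the episode would have continued from.
                    nxt = env.observation()
                    _, v_next, _ = forward(
                        params, nxt, (h[n:n + 1], c[n:n + 1])
                    )
                    rew_buf[t, n] = reward + ppo_config.gamma * float(v_next)
                    done_buf[t, n] = 1.0
                else:
                    rew_buf[t, n] = reward
                if terminal or truncated:
                    ep_lens.append(ep_len[n])
                    ep_rews.append(ep_rew[n])
                    ep_len[n] = 0.0
                    ep_rew[n] = 0.0
                    envs[n] = EpisodeSession(
                        task, np.random.default_rng(rng.integers(2**31))
                    )
                    pending_start[n] = 1.0
        obs = np.stack([e.observation() for e in envs])
        keep = (1.0 - pending_start)[:, None]
        _, val_buf[T], _ = forward(params, obs, (h * keep, c * keep))
        adv, ret = compute_advantages(rew_buf, val_buf, done_buf, ppo_config)
        if ppo_config.normalize_advantage:
            adv = (adv - adv.mean()) / (adv.std() + 1e-8)
        batch = RolloutBatch(
            observations=obs_buf, actions=act_buf, masks=mask_buf,
            old_logp=logp_buf, advantages=adv, returns=ret,
            episode_starts=start_buf, h0=h0, c0=c0,
        )
        losses = {}
        grad_norm = 0.0
        for _epoch in range(ppo_config.n_epochs):
            opt.zero_grad()
            l_pol, l_val, l_ent, l_tot = ppo_losses(params, batch, ppo_config)
            if not np.isfinite(l_tot.data):
                raise FloatingPointError(
                    f"non-finite PPO loss at update {update}: "
                    f"policy={l_pol.data}, value={l_val.data}, entropy={l_ent.data}"
                )
            l_tot.backward()
            grad_norm = opt.clip_grad_norm(ppo_config.max_grad_norm)
            opt.step()
            losses = {
                "l_policy": float(l_pol.data), "l_value": float(l_val.data),
                "l_entropy": float(l_ent.data), "l_total": float(l_tot.data),
            }
        curve.append({
            "update": update,
            "ep_len": float(np.mean(ep_lens)) if ep_lens else np.nan,
            "ep_reward": float(np.mean(ep_rews)) if ep_rews else np.nan,
            **losses,
            "grad_norm": float(grad_norm),
        })
    return params, pd.DataFrame(curve)


def _logsumexp(x):
    m = x.max(axis=-1, keepdims=True)
    return m + np.log(np.exp(x - m).sum(axis=-1, keepdims=True))


def _sample_rows(probs, rng, masks=None):
    u = rng.random((probs.shape[0], 1))
    idx = (probs.cumsum(axis=1) < u).sum(axis=1).astype(np.int64)
    # Guard against rounding pushing the index past the support.
    over = idx >= probs.shape[1]
    if masks is not None:
        over |= ~masks[np.arange(len(idx)), np.minimum(idx, probs.shape[1] - 1)]
    if over.any():
        idx[over] = probs[over].argmax(axis=1)
    return idx


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

def evaluate(
    params,
    task: TaskConfig,
    n_trials: int,
    seed,
    lesion=None,
    policy: str = "greedy",
    record_activations: bool = False,
    env_id: int = 0,
    keep_maps: bool = False,
):
    """Run frozen-weight episodes; returns (TrajectoryLog, ActivationDataset|None).

    Actions are selected greedily (argmax of masked logits, ties broken
    by the lowest action index) unless ``policy="random"``, which draws
    uniformly over valid actions and ignores ``params``.  Conditions are
    balanced over trials by cycling ``task.conditions``.  With
    ``record_activations`` the LSTM cell state, unmasked logits and task
    annotations are logged at every step.
    """
    rng = np.random.default_rng(seed)
    if params is None:
        policy = "random"
    if policy == "random" and record_activations:
        raise ValueError("cannot record activations for the random baseline")
    steps_rows, trial_rows, maps = [], [], {}
    acts, logits_log, cells, goals, env_ids, trials_idx = [], [], [], [], [], []
    lm_adj, goal_adj, post_lm = [], [], []
    lesion = np.asarray(sorted(lesion), dtype=int) if lesion is not None else None
    n_cond, n_kind = len(task.conditions), len(task.kinds)
    for trial in range(n_trials):
        condition = task.conditions[trial % n_cond]
        trial_task = TaskConfig(
            conditions=(condition,),
            kinds=(task.kinds[(trial // n_cond) % n_kind],),
            n_landmarks_choices=(
                task.n_landmarks_choices[
                    (trial // (n_cond * n_kind)) % len(task.n_landmarks_choices)
                ],
            ),
            placement_variant=task.placement_variant,
            zero_noise=task.zero_noise,
            fixed_landmarks=task.fixed_landmarks,
        )
        env = EpisodeSession(trial_task, np.random.default_rng(rng.integers(2**31)))
        if params is not None:
            h, c = init_recurrent_state(params, 1)
        done = truncated = False
        n_steps = 0
        lm_cells = env.grid.landmark_cells
        adj_lm = _adjacency_set(lm_cells)
        adj_goal = _adjacency_set({env.grid.goal})
        while not done and not truncated:
            obs = env.observation()
            mask = env.mask()
            if policy == "random":
                valid = np.flatnonzero(mask)
                action = int(valid[rng.integers(len(valid))])
                logits = np.zeros(gw.N_ACTIONS)
            else:
                logits, _, (h, c) = forward(params, obs, (h, c), lesion=lesion)
                action = int(np.argmax(mask_logits(logits, mask)))
            if record_activations:
                acts.append(c[0])
                logits_log.append(np.asarray(logits, dtype=float))
                cells.append(env.state.cell)
                goals.append(env.grid.goal)
                env_ids.append(env_id)
                trials_idx.append(trial)
                lm_adj.append(env.state.cell in adj_lm)
                goal_adj.append(env.state.cell in adj_goal)
                post_lm.append(env.seen_landmark)
            prev_visited = set(env.state.visited)
            reward, done, truncated = env.step(action)
            n_steps += 1
            dest = env.state.cell
            steps_rows.append({
                "trial": trial, "step": n_steps, "r": dest[0], "c": dest[1],
                "modality": "direction" if action < 4 else "state",
                "action": action,
                "dest_type": _dest_type(dest, env.grid),
                "visited_before": dest in prev_visited,
                "points": env.state.points,
            })
        trial_rows.append({
            "trial": trial, "condition": condition, "kind": env.grid.kind,
            "n_landmarks": len(env.grid.landmarks), "steps_to_goal": n_steps,
            "success": bool(done),
        })
        if keep_maps:
            maps[trial] = gw.map_to_json(env.grid)
    log = TrajectoryLog(
        pd.DataFrame(steps_rows, columns=[
            "trial", "step", "r", "c", "modality", "action", "dest_type",
            "visited_before", "points"]),
        pd.DataFrame(trial_rows),
        maps,
    )
    dataset = None
    if record_activations:
        dataset = ActivationDataset(
            activations=np.asarray(acts),
            logits=np.asarray(logits_log),
            cell=np.asarray(cells, dtype=int),
            goal_cell=np.asarray(goals, dtype=int),
            env_id=np.asarray(env_ids, dtype=int),
            trial=np.asarray(trials_idx, dtype=int),
            landmark_adj=np.asarray(lm_adj, dtype=bool),
            goal_adj=np.asarray(goal_adj, dtype=bool),
            post_landmark=np.asarray(post_lm, dtype=bool),
        )
    return log, dataset


def _dest_type(cell, grid) -> str:
    if cell == grid.goal:
        return "goal"
    if cell in grid.landmark_cells:
        return "landmark"
    return "non_landmark"


def _adjacency_set(cells) -> set:
    out = set()
    for r, c in cells:
        out.add((r, c))
        for dr, dc in gw.DIRECTIONS:
            out.add((r + dr, c + dc))
    return out


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------

def save_params(params, path):
    np.savez_compressed(path, **{k: v.data for k, v in params.items()})


def load_params(path) -> dict[str, Tensor]:
    with np.load(path) as z:
        return {
            k: Tensor(z[k], requires_grad=not k.startswith("_")) for k in z.files
        }
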