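# metanav

Few-shot goal-directed navigation in a grid world: a task simulator, a
calibrated noisy spatial-memory model, a meta-trained recurrent
reinforcement-learning agent, and the analysis suite that dissects both
behaviour and network units.

## The scientific problem

People can navigate environments they have never moved through, using
nothing but a briefly studied map. Two readouts of a cognitive map can
support this: a **vector-based** strategy (choose a movement *direction*
from remembered relative positions — a Euclidean readout) and a
**transition-based** strategy (choose which adjacent *state* to occupy
next — a topological readout). This package implements a computational
testbed for how those strategies are arbitrated and how they emerge in
a learning system:

- an 8x8 grid task where every trial is a novel map (fresh identity
  permutation, landmarks, goal, obstacles), navigated with *direction*
  actions or *state* actions under four availability conditions;
- a spatial-memory model calibrated to human probe errors: per-trial
  goal noise `s_goal ~ N(0.91, 0.44)` and landmark noise
  `s_landmark = m ln(n_exposures) + c`, `m ~ N(-0.63, 0.34)`,
  `c ~ N(1.90, 0.60)` (grid units);
- an LSTM agent (100 recurrent units, separate 2x64-tanh policy and
  value heads) trained with masked-action PPO
  (`L = L_policy + 0.5 L_value - 0.001 L_entropy`, clip 0.2, gradient
  norm cap 0.5) to meta-learn few-shot navigation — each trial must be
  solved with no prior experience of that map;
- analyses of the trained network in the style of systems neuroscience:
  spatial / landmark / conjunctive unit typing by two-factor ANOVA,
  vector / transition functional modules by logit regression, module
  lesions, ridge/logistic decoding of task variables, representational
  geometry, and landmark-sampling strategy metrics with a
  subjects x locations PCA.

It is written for computational cognitive scientists who want to run,
perturb, or extend the model and its analyses end-to-end on a single
CPU, with every analysis stage validated against synthetic data whose
ground truth is known. The network and PPO run on a small built-in
reverse-mode autodiff core (finite-difference-verified), so no deep
learning framework is required.

## Worked example

```python
import numpy as np
from metanav import agent as ag

task = ag.TaskConfig(conditions=("both",), kinds=("open",))
params, curve = ag.train(task, ag.NetworkConfig(), ag.PPOConfig(), seed=1)

random_log, _  = ag.evaluate(None,   task, 1000, 123, policy="random")
trained_log, _ = ag.evaluate(params, task, 1000, 123)
print("random  median steps:", random_log.trials.steps_to_goal.median())
print("trained median steps:", trained_log.trials.steps_to_goal.median())
```

prints (seed 1, desk scale: 8 envs x 256 steps x 300 updates, ~3 min):

```
random  median steps: 78.0
trained median steps: 10.0
```

The agent starts four steps from a goal it has never seen, on a map it
has never visited; a uniform-random walk over valid moves needs a
median 78 steps, while the meta-trained policy — combining its noisy
goal memory, wall-contact localisation, and displacement integration —
reaches it in a median of 10.

The numbered drivers under `analysis/` run the full study pipeline and
write tidy tables to `results/`:

| script | what it shows |
|---|---|
| `01_simulate_behavior.py` | strategy use by destination type x visit history; the quadratic strategy-performance relation (mixtures navigate worst) |
| `02_train_agent.py` | desk-scale meta-training curve; trained vs random evaluation |
| `03_unit_analyses.py` | unit typing, vector/transition modules, lesions, decoding, geometry (needs 02's checkpoint) |
| `04_sampling_analysis.py` | landmark-sampling accessibility/centrality (chance centrality = 4 exactly), probe error, and the sampling PCA separating planted strategies |

For example, `04_sampling_analysis.py` prints centre-weighted samplers
at mean centre distance 2.55 (below the chance value 4), corner-weighted
at 5.45, uniform at 4.00, and a first sampling PC that cleanly separates
the centre and corner cohorts (mean scores +12.5 vs -12.5).

## Layout

```
src/metanav/      gridworld, memory, agent (+autodiff), behavior,
                  units, sampling, synthetic, logs, interface
analysis/         numbered narrative drivers (see table above)
tests/            pytest suite incl. acceptance checks
scripts/          acceptance.py
docs/methods.md   model, assumptions, parameters, limitations
```

Full-scale training (128 envs x 8,192 steps x 8,000 updates x 20
seeds) is retained behind `PPOConfig.full_scale()` but is cluster-class;
every shipped analysis and test runs at desk scale. See
`docs/methods.md` for the model details and the problem sizes used.
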