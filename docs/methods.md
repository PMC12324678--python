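# Methods

## The task

Each trial presents a wholly novel map: an 8x8 traversable interior
inside a 10x10 lattice whose outer ring is wall. Every interior cell
carries a distinct identity integer in 1..64, permuted fresh per trial;
walls and obstacles read as the sentinel 65. *Open* environments have no
interior obstacles; *cluttered* environments have exactly eight, one per
interior row and one per interior column (a random column permutation).
A map-reading phase reveals 2, 4, 8 or 16 unique landmarks under a fixed
budget of 16 total exposures (2 landmarks are shown 8 times each, 16
once each); the exposure order never repeats a landmark consecutively
and completes a full round of all landmarks before any repeat. The
navigator then starts exactly four grid steps (breadth-first-search
distance) from the goal, on a non-edge, non-landmark, non-obstacle cell,
and navigates under one of four conditions: *both* response modalities
available, *directions only*, *states only*, or *random alternation*
(exactly one modality per step; directions drawn with probability 0.75
in open fields and 0.50 in cluttered ones). Navigation starts with
1,000 points, costs 50 per step, and pays 1,000 at the goal; episodes
cap at 200 steps. Memory probes score 30/20/10/0 points for grid-step
errors of 0/1/2/>2.

Coordinate conventions: interior cells are `(row, col)` in {0..7}^2;
emitted coordinate pairs use `x = column`, `y = row`. All grid distances
are 4-neighbour path distances (equal to Manhattan distance in open
maps); the probe-error metric is Manhattan. Action slots are fixed at
N, S, W, E for both modalities (indices 0-3 direction moves, 4-7 state
selections); the shuffled on-screen placement of the human states
display carries no information in the integer encoding, so it has no
analogue here.

## Simulated spatial memory

Agents skip the map-reading phase; its outcome is modelled directly.
Per trial, the goal-coordinate noise s.d. is drawn as
`s_goal ~ N(0.91, 0.44)` (grid units, calibrated to human probe
errors). Landmark noise follows `s_landmark = m*ln(n_exposures) + c`
with per-participant `m ~ N(-0.63, 0.34)` and `c ~ N(1.90, 0.60)`; the
natural log is used (the base is a configurable reading of the fitted
curve). Each stored coordinate is truth plus an independent `N(0, s)`
draw — continuous, never rounded or clipped. Negative s.d. draws are
floored at zero rather than redrawn; the floor moves the goal-noise
mean by less than 0.005, which the Monte-Carlo acceptance check absorbs
explicitly. Memory is frozen within a trial, and identities without an
entry (including the wall sentinel) recall as zeros.

## The agent

An LSTM with 100 recurrent units feeds separate policy and value heads,
each two fully connected tanh layers of 64 units; the policy head emits
8 logits, the value head a scalar. The 48-slot observation concatenates,
in order: condition one-hot (4), obstacle x,y pairs sorted row-major
(16; zeros in open fields), state/direction availability flags (2),
current, adjacent (N,S,W,E) and goal identity integers (6), estimated
current/adjacent/goal coordinates from memory (12), the noise s.d.
actually used for each of those six items as confidence (6), and the
previous displacement (2). Identity integers enter as raw scalars.
Inside the network a fixed per-slot rescaling (identities /65,
coordinates /7, confidences /2) conditions the first layer; this is a
numerical choice internal to the model — the observation contract stays
raw.

Invalid actions (unavailable modality, or target cell not traversable)
are masked by replacing their logits with -1e8 before the softmax.
Training is PPO with the clipped surrogate objective: minimise
`-E[min(r A, clip(r, 1-eps, 1+eps) A)] + c1 E[(V-R)^2] - c2 E[H]`,
with entropy H computed over valid actions only. (The printed loss
composition is ambiguous about signs — the surrogate is an objective
yet is summed into a loss — so the standard convention above is used.)
Coefficients: learning rate 3e-4 (Adam), c1 = 0.5, c2 = 0.001,
eps = 0.2, gradient clipped to global norm 0.5. Advantages use
generalized advantage estimation with gamma = 0.99, lambda = 0.95
(standard reference defaults; the source regime does not print them),
normalised per batch; returns are `R_t = A_t + V_t`. The 200-step cap
is treated as truncation, not termination: the capped step's reward is
augmented with `gamma * V(next state)`. Recurrent state resets at
episode boundaries, and replay during updates applies the same reset
mask (truncated BPTT across rollout boundaries, 4 epochs per batch over
the full rollout as a single sequence batch). The training reward is
the human point schedule divided by 1,000 (-0.05 per step, +1.0 at
goal), which preserves the optimal policy at friendlier magnitudes.

Because no deep-learning framework is assumed, the network and PPO are
implemented over a small reverse-mode autodiff core (`autodiff.py`)
with a fused, hand-derived backpropagation-through-time kernel for the
LSTM; gradients are verified against central finite differences in the
test suite (agreement ~1e-7 relative).

**Scales.** The full-scale regime is 128 parallel environments x 8,192
steps per update (1,048,576 environment steps per update) x 8,000
updates x 20 seeds — a cluster-class budget retained behind
`PPOConfig.full_scale()`. The desk-scale default used by the analysis
scripts and tests is 8 environments x 256 steps x 300 updates (~614k
steps, about 3 minutes on one CPU), trained on the open-field *both*
condition. Desk scale does not reproduce the published asymptotic
behaviour (e.g. strategy proportions of fully trained agents); it is
sized to demonstrate learning — the trained greedy policy beats the
uniform-random-valid baseline on median steps-to-goal by a wide margin
(median ~10 vs ~74 in a 1,000-episode evaluation).

Evaluation freezes the weights and picks the argmax of the masked
logits (ties broken by the lowest action index).

## Unit analyses

Activations are the LSTM cell state, recorded during greedy evaluation
on four fixed open-field layouts of two landmarks each: (2,2)+(5,5),
(2,5)+(5,2), (2,2)+(5,2), (2,5)+(5,5) (interior row, col). Per unit
and environment, mean activation per cell is smoothed with a Gaussian
filter (sigma 0.7 cells, reflective boundary; unvisited cells imputed
with the unit's grand mean before smoothing). A two-factor ANOVA over
the 256 cell-environment values — quadrant (the four 4x4 blocks) x
on-or-adjacent-to-landmark (the landmark cell and its 4-neighbours;
diagonals excluded to match the movement topology) — types each unit at
alpha = 0.05, uncorrected: *spatial* (quadrant main effect only),
*landmark* (adjacency main effect only), *conjunctive* (both main
effects and/or an interaction), else *none*. Note the smoothing
correlates neighbouring cells, so the nominal alpha is approximate for
null units; the recovery guarantees quoted below are empirical, not
distributional.

Functional modules regress each unit's cell state onto each of the 8
action logits (univariate, so R^2 is the squared correlation) and
average over the 4 direction and 4 state logits separately. The top-k
units per criterion are the *vector* and *transition* modules; the
bottom-k on the maximum of both averages are *unspecialized*. k
defaults to 10 (the procedure's stated count; a figure caption
elsewhere says 20 — k is configurable). Overlapping top-k units go to
the criterion with the higher R^2, backfilled from the next rank, ties
broken by unit index.

Lesions zero the chosen units' cell and hidden states at every
timestep; an empty lesion is bit-identical to the intact model and
lesioning is idempotent. Lesioned and intact evaluations share trial
seeds so excess-steps deltas are paired. Decoding uses ridge regression
(alpha 0.5) per coordinate for current/goal location (error = held-out
mean Euclidean distance) and logistic regression for landmark/goal
adjacency with the majority class under-sampled to balance (error =
held-out misclassification rate); splits are seeded 80/20.
Representational geometry averages the first three PCA scores
(mean-centred, unscaled) of a module's cell states per grid location
under each condition (pre/post first landmark encounter, or
on-landmark vs not).

## Landmark-sampling analytics

Accessibility is the mean Manhattan distance from each of the 64
interior cells to its nearest landmark; centrality is the mean
Manhattan distance of landmarks from the interior centre (3.5, 3.5).
Manhattan is the default metric because it is the only one under which
the uniform-placement chance level is exactly 4 (verified by
enumeration); Euclidean is available behind a flag. Metrics count each
sampled cell once by default, with a count-weighted variant. The
sampling PCA runs on the subjects x 64-locations count matrix,
mean-centred by column, no scaling.

## Synthetic generators

The generators exist to give every analysis a ground-truth-known input;
they are deliberately simple and are not fits to human data.

*Participants* choose each move by softmax over the negative estimated
Manhattan distance from the candidate cell to the remembered goal
estimate, with temperature `2*(1-competence)` (competence 1 = greedy,
ties random); the modality is drawn independently of the chosen move,
with state-response probabilities overridden when the destination is
the goal, a landmark, or an already-visited cell (checked in that
order), otherwise the base direction probability. With zero memory
noise and competence 1 every open-field trial finishes in exactly 4
steps. A known limitation: because the movement score targets the
*estimated* goal, high-competence participants with noisy memory hover
near the estimate rather than searching systematically, so steps-to-goal
is not monotone in competence at high memory noise. The behavioural
demonstration script therefore plants its performance structure through
memory precision (strategy-consistent participants get sharper goal
memories), which the trajectory analytics then recover.

*Probe responses* are truth plus per-axis Gaussian noise, rounded to
the nearest cell and clipped to the interior (a click must land on the
grid); symmetry holds before clipping.

*Sampling strategies* draw 16 clicks per block from a cell distribution
exponential in distance-to-centre (centre strategy), distance-to-corner
(corner), or uniform; the mixture cohort is half centre, half corner.

*Planted activations* compose quadrant means, landmark-adjacency bumps,
multiplicative conjunctions, or pure noise over uniformly visited
cells of the four-layout suite, optionally wiring chosen units linearly
into the direction or state logits.

What passing these round trips shows — and does not show: the analysis
code recovers structure it is pointed at, under the noise model the
generators implement (independent Gaussian noise, uniform visitation).
Real trajectories have autocorrelated visitation and non-Gaussian
activation noise; recovery rates there are not guaranteed by these
tests.

## Numerical choices and degenerate inputs

Masking constant -1e8; masked softmax probabilities underflow to exact
zero, and entropy terms are zeroed for invalid slots. Greedy ties break
to the lowest action index. Map generation retries start placement at
most 100 times before failing loudly. Strict-variant landmark counts
must divide the 16-exposure budget; the day-2 control draws 2..16
unique cells (edges allowed) and spreads the budget with every cell
clicked at least once. Degenerate-variance units are labelled *none*
with all p-values 1. The sampling PCA rejects constant matrices;
decoders reject single-class targets and fewer than two distinct
locations. Zero-step trials (impossible for distance-4 starts) are
excluded from log-step statistics with a warning. All randomness flows
through explicitly seeded NumPy generators; pipeline runs record every
stage seed in a manifest.

## Problem sizes used by the shipped analyses

Behavioural cohort: 60 subjects x 60 trials. Agent: desk scale as
above, evaluated on 1,000 trials per policy. Unit recording: 250
trials per environment (the typing procedure was specified at 1,000;
250 keeps the battery interactive while leaving every cell visited many
times). Lesions: 100 trials per condition. Sampling: 50-100 subjects
per cohort. Acceptance checks use 100,000 Monte-Carlo draws where a
distributional mean is asserted.

## Known limitations

Desk-scale training is three orders of magnitude short of the full
regime, so unit-type fractions and strategy proportions of the trained
network are not expected to match published full-scale values; the
analyses are validated on planted ground truth instead. The ANOVA
operates on smoothed maps (inherited design), inflating its false-
positive rate on null units. Mixed-effects and Bayesian model
comparison are out of scope; the behaviour module exports tidy tables
for external statistics tooling. Human-facing presentation details
(images, animations, display timing) are abstracted away by the integer
encoding.
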