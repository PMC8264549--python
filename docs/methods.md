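# Methods

## The model

`antforage` simulates a colony of foraging ants as independent active-inference
agents coupled only through a shared pheromone field (stigmergy). The arena is
a T-maze carved out of a 40 × 40 cell grid: a corridor bar across the top, a
vertical stem down to the nest at the bottom-centre, and a food patch at the
distal end of one bar arm. The food alternates between the two arms every 500
steps of a 2,000-step run, so a successful colony must repeatedly rediscover
the resource.

Each cell of the maze carries an integer pheromone level from 1 (no deposited
pheromone) to 10. The environment-side mapping from every location to its
outcome distribution — one-hot at the cell's current level, since sensing is
unbiased — is the *reallocation matrix*, the generative process from which
each agent's likelihood is re-cut at every step.

### Per-step inference

Every forager runs a single-factor Markov decision process over its 3 × 3
neighbourhood, with a one-step policy horizon:

- **Hidden states** (9): the neighbourhood cells in the fixed order
  [stay, N, NE, E, SE, S, SW, W, NW].
- **Outcomes** (10): the pheromone levels.
- **Likelihood A** (10 × 9): re-cut from the reallocation matrix each step;
  column *j* is one-hot at the level of neighbourhood cell *j*. This
  *likelihood remapping* is what confines the agent's knowledge to its
  immediate surroundings — it never represents the full maze.
- **Transitions B** (9 matrices, 9 × 9): policy *i* deterministically relocates
  every state to state *i*.
- **Preferences C** (10): *flat* — uniform; *strict* — C(o) ∝ exp(α·o),
  a monotone preference for denser pheromone.
- **Prior D** (9): one-hot at "stay" (the ant knows which cell it occupies).

State inference minimises variational free energy; for this model the
minimiser is the exact categorical posterior, `qs = softmax(ln D + ln A[o,·])`,
computed in closed form with a 1e-16 probability floor before every logarithm
(all logs natural). Policies are scored by expected free energy

G(π) = Σ_o qo_π(o)·[ln qo_π(o) − ln C(o)]  +  Σ_s qs_π(s)·H[A(·|s)]

(risk plus ambiguity; with one-hot sensing the ambiguity vanishes and
G(π) = −ln C(level at destination π)). The action is sampled from
`qpi ∝ exp(−γ·G + bonus)` over the feasible policies; wall and off-grid moves
are masked out before normalisation rather than penalised. Sampling is the
model's only behavioural stochasticity; a greedy `argmax` mode (which makes
each agent deterministic) is available behind the `action_selection` config
flag.

### Ecology

Unladen foragers deposit nothing and simply carry out the pheromone-biased
walk above. On stepping onto the food cell they become *laden*; laden
foragers deposit one pheromone level at each cell they move to (saturating at
10) and receive an additive log-space homing bonus: every policy whose
destination strictly decreases the Euclidean distance to the nest earns κ.
On reaching the nest they unload, increment their round-trip count, and
resume searching. The field decays stochastically: each cell above baseline
loses one level with probability `p_decay` per step.

## Parameters

| name | default | units / meaning |
|---|---|---|
| `n_ants` | 30 | colony size (reference sizes 10, 30, 50, 70) |
| `n_steps` | 2000 | run length in steps |
| `switch_period` | 500 | food alternation period (switches at 500/1000/1500) |
| `p_decay` | 1e-4 | per-cell per-step evaporation probability |
| `alpha` | 0.5 | strict-preference slope, log-odds per pheromone level |
| `gamma` | 1.0 | policy precision of the action softmax |
| `kappa` | 2.0 | homing bonus (log-space) for laden foragers |
| `scent_radius` | 0 | Chebyshev detection range of food/home scents |
| `corridor_width` | 6 | width of bar and stem, cells |
| `snapshot_every` | 50 | field snapshot cadence, steps |

Because the likelihood is one-hot, only the product γ·α sets the strength of
trail following (relative step log-odds per pheromone level), with κ acting
as an independent homeward drive for laden foragers. κ must exceed the
maximal trail pull γ·α·(10−1) for laden foragers to be guaranteed to escape a
saturated peak; with the defaults (pull up to 4.5 vs κ = 2) homing instead
relies on the noise of sampling, which suffices on young trails but lets a
forager linger near heavily reinforced cells.

The decay probability is read literally from its percentage form ("0.01 %" →
1e-4); the alternative 1 % reading, and reset-to-baseline (rather than
one-level) decay, are available as `p_decay` / `decay_mode` options. At 1e-4
a trail laid in the first epoch is essentially permanent on the 2,000-step
horizon, which matters for the switching dynamics discussed below.

## Scheduling and reproducibility

Agents are stepped sequentially in id order within each step, so a deposit is
visible to later-indexed nestmates in the same step (a `synchronous` mode,
which freezes the field for sensing within a step, is available for
sensitivity analysis). Decay is applied once per step after all agents move;
metrics are recorded at end-of-step state. Every forager owns a random stream
spawned from `SeedSequence(master_seed, spawn_key=(agent_id,))`; the decay
stream uses a reserved id. Identical configurations therefore reproduce runs
bit-for-bit, regardless of colony size ordering or platform.

The decay draw consumes one uniform per grid cell every step even when no
cell holds pheromone, so trajectories do not depend on whether early draws
were skipped.

## Colony phenotypes

- **Round trips**: cumulative nest → food → nest cycles summed over the
  colony.
- **Distance coefficient**: DC = (1/N)·Σ_i Σ_j ‖x_i − x_j‖ over ordered pairs,
  i.e. (N−1) times the mean pairwise distance. This normalisation is adopted
  because it reproduces the characteristic magnitudes (~100 at N = 10 and
  ~900 at N = 70 imply mutually consistent mean pairwise distances of 11–13
  cells); a `mean_pairwise` mode is exposed as an alternative. "Plateau" DC
  is the time average over steps 500–2,000, after the colony's spatial
  distribution has converged.
- **Per-arm pheromone mass**: Σ(level − 1) over walkable cells strictly left /
  right of the stem centreline — an operationalisation of trail "locking"
  onto one arm. With an odd stem width the centre column counts toward
  neither arm.

## Design choices where the design was open

- **Maze geometry** is parameterised (grid size, corridor width, stem
  length); defaults: corridor 6 cells, stem reaching the bottom row, food on
  the middle bar row at columns 0 and width−1.
- **Homing** is implemented as the additive κ bonus described above. Many
  biological mechanisms could stand behind an inbound nest-ward bias (path
  integration, celestial cues, visual homing); the bonus abstracts them as a
  single log-space drive composable with the pheromone term.
- **D** one-hot at "stay": the forager is certain of its own location, and
  uncertainty enters only through what it can observe.
- **Deposition at the destination cell** after the move (`deposit_at`
  configurable to `origin`).
- **Initial food arm**: left.

## The generator as study condition

The simulator's defaults *are* the study conditions: 40 × 40 T-maze, 2,000
steps, switches at 500/1,000/1,500, colony sizes in {10, 30, 50, 70}, decay
1e-4. Synthetic runs capture trail formation, recruitment and arm switching
as emergent outcomes of local inference; they do not emulate nestmate
interactions, multi-component pheromones, path memory, or heterogeneity
among foragers, so passing tests say nothing about those aspects of real
colonies.

## Numerical choices

Probabilities are floored at 1e-16 before logarithms; softmaxes subtract the
maximum before exponentiation; normalisation invariants are enforced to
1e-12 in tests. Categorical sampling inverts the CDF on one uniform draw per
step. Ties in `argmax` mode resolve to the lowest policy index (numpy
convention).

## Known limitations

- **Trails do not accelerate round trips on this horizon.** Outbound
  movement along an established trail is still undirected diffusion, and
  deposits concentrate where homeward paths overlap (the stem and junction),
  so the local pheromone gradient tends to point toward the trunk rather
  than the food. Measured across the (γ·α, κ) plane, strict-preference
  colonies complete consistently *fewer* median round trips than
  flat-preference ones at 30 ants / 2,000 steps, even though they form and
  re-lock arm trails reliably. A directional or food-ward cue (or trail
  geometry memory) would be needed to turn trails into a net transport gain;
  that is outside this model.
- **Deposition is ladenness-driven, not preference-driven**, so flat-prior
  colonies — whose laden foragers also home under κ — likewise lay most new
  mass on the food-bearing arm; arm-mass dominance alone therefore separates
  the two phenotypes only weakly. What distinguishes strict colonies is that
  their *outbound* foragers respond to the trail (confinement, recruitment
  of movement onto the trail corridor), not the mass bookkeeping.
- With `p_decay` = 1e-4, stale trails persist across epochs; the "gradual
  fade" of an abandoned trail is only visible at the 1 % reading of the
  decay parameter.
- A laden forager's own fresh deposits mildly attract it (destination
  deposition plus strict preferences); with κ well below γ·α·9 this can
  trap laden foragers on self-reinforced peaks.
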