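# Methods

`preypred` implements the computational pipeline of a predator–prey foraging
task on a hexagonal gridworld: a feature-based MDP task engine, value-iteration
predators, observer models of action prediction, inverse reinforcement
learning (IRL) of reward weights, interactive Monte-Carlo-tree-search (MCTS)
planners with inverse-binomial-sampling (IBS) likelihoods, hierarchical
Bayesian regressions, a synthetic-data generator, and model/parameter
recovery studies. This note documents the models, the numerical choices, and
what the synthetic data can and cannot show.

## Task world and MDP

The world is a `width × height` (default 21 × 10) grid of flat-top hexagons
in **odd-q offset coordinates**: origin `(0, 0)` at the top left, rows
increasing downward, odd columns shifted half a cell down. The six movement
directions are fixed in ring order `n, ne, se, s, sw, nw`; their offset
deltas are constants in `hexworld.py`. Any consistent 6-neighbour layout
preserves the semantics of every model; this one is pinned for
reproducibility of file formats and seeds. Cells may be removed as walls;
cells carry three binary features — trees, red ground, and the prey's current
position — and a predator with reward weights `r ∈ R³` receives
`R(s, a) = f(s′) · r` on entering `s′`. Transitions are deterministic; the
prey feature is rebuilt whenever the prey moves.

Scoring follows the task: +100 points per coin the prey collects, −1000 on
capture. Capture fires on co-location after **either** actor's move (a
symmetric reading; `step_game(..., symmetric_capture=False)` restores the
literal predator-enters-prey rule). The predator is forced to move on every
step; staying put is never an action.

## Predator agent

Value iteration (`V ← max_a [R + γ V(s′)]`, `V₀ = 0`, γ = 0.9, at most 500
sweeps) with early stopping when the sup-norm change falls below `tol`
(default 1e-6; oracle comparisons in the tests run at 1e-12 so the residual
of the stopping rule does not contaminate the comparison). Action selection
is either greedy (`max`, ties broken uniformly at random under the run's
seed) or softmax with temperature τ (τ = 1 in the stochastic-agent
condition). During a game the MDP is re-solved once per predator turn with
the prey pinned at its current cell, implementing the planner's
stationary-prey assumption.

## Action-prediction models

Seven observer models predict the predator's next move. Policy learners
track per-direction action frequencies with a delta rule whose learning rate
decays as `α_t = α·n^{−λ}`; the generalizing variant first smooths the
observed one-hot action with a squared-exponential kernel over the action
ring (directions at 0°, 60°, …, 300°, positions normalized to [0, 1),
minimal circular distance; kernel rows renormalized so smoothing conserves
the observation's unit mass). The repeat model is the `α = 1, λ = 0` special
case. Goal inference solves the MDP under the predator's true weights and
converts Q values to probabilities with softmax (τ = 1). Combined models
min–max rescale each component over the available actions, mix them with
weight `W ∈ [0, 1]`, renormalize to a categorical distribution, and mix in a
1% uniform floor. The floor keeps the one-hot repeat model's likelihood
finite on non-repeat choices; the renormalization (rather than a second
softmax over the rescaled values) is deliberate — values confined to [0, 1]
pushed through softmax(τ=1) cap every model's choice probability at
`e/(e+5) ≈ 0.35`, which makes the model family practically unidentifiable.

Likelihoods are categorical over the **participant's predicted action**;
learning updates use the predator's **observed** action and persist across
games. Free parameters (α, λ for policy variants; W, α, λ for combined;
W for combined-repeat) are fitted by differential evolution (seeded,
box bounds α ∈ (0, 1], λ ∈ [0, 3], W ∈ [0, 1]); BIC is
`k·ln N + 2·(−log L)`. With the kernel length scale at its fitting default
(0.02) the smoothed target is numerically a delta on this metric, so the
generalizing and plain learners coincide; recovery studies therefore use
ℓ = 0.15, where generalization is materially distinct. The per-trial
likelihood loop is JIT-compiled with numba.

## Inverse reinforcement learning

*Model-free baselines.* Occupancy counts sum each feature over the states
the predator occupies (per-step prey snapshots). Direction-of-travel counts
sum features along the ray obtained by repeating the observed action to the
grid edge, stopping at walls (walls are impassable, so the "traversable
line" reading). The relative variant also counts the rays of the untaken
actions, normalizes both count vectors to sum 1, and reports their
difference. All estimates are calibrated to the rating scale by
`r → 4·r/max|r|` (zero vectors pass through).

*MaxEnt (infinite-horizon maximum causal entropy).* Alternates soft value
iteration (log-sum-exp backup, warm-started between gradient steps: full
solve on the first pass, up to 30 refinement sweeps afterwards at tol 1e-5),
a softmax(τ=1) policy, expected state visitation, expected-feature
computation, and a gradient step `r ← r + α_k (F_obs − F̂)` with
`α_k = α₀·k^{−λ}` (α₀ = 1, λ = 0.5; unspecified upstream, chosen once as a
Robbins–Monro-style decay). The literal zero-initialized, undiscounted
visitation recursion cannot propagate mass, so visitation is computed as the
discounted expected occupancy from the trajectory's start state, solved
exactly as the linear system `D = d₀ + γ Pπᵀ D` (total mass `1/(1−γ)`), and
expected features are normalized by `ΣD` so they are commensurate with the
mean observed features. Iteration stops at `max|F_obs − F̂| < 1e-4` or a cap
(1000 by default; 150–300 in the recovery and validity studies — the argmax
of the estimate is stable well before full convergence). The feature map is
frozen with the prey at its position at the start of the trajectory: this
static-map assumption is exactly why the method degrades when the predator's
goal is the moving prey.

*Hypothesis-testing Bayesian IRL.* Candidate weight vectors on [−1, 1]³
(flat prior) are scored by the likelihood of every observed action under a
successor-representation Q function: `M` is the discounted expected
state–action occupancy matrix of the **uniform** policy over the objective
transitions (`M = (I − γT)⁻¹`, γ = 0.9 matching the forward model), and
`Q(s,a) = M[{s,a},:]·R_vec` with the reward vector rebuilt at every step so
the prey feature tracks the prey. Action probabilities use softmax with
temperature 0.083. The posterior is approximated with an affine-invariant
ensemble sampler (emcee; 12 walkers, ~500 warm-up and 2000 retained draws;
the likelihood is evaluated for whole walker batches via precomputed
`M·Φ` blocks, so a fit takes well under a second); the point estimate is the
posterior mean, calibrated to [−4, 4]. The upstream analysis used NUTS; the
estimand is identical and the posterior is three-dimensional and unimodal in
practice, so the sampler choice is immaterial.

*Rating fit statistics.* R² is the squared Pearson correlation of pooled
predictions and ratings; adjusted R² is `1 − (1−R²)(n−1)/(n−p−1)`; BIC uses
a Gaussian residual model, `n·ln(RSS/n) + p·ln n`.

## Interactive planning

The prey plans in the joint (prey, predator) MDP — 210² = 44,100 position
states on the wall-free grid — approximated online by UCT. Tree nodes sit at
prey decision points; predator moves between them are sampled per variant
(absent for `mcts`; uniform for `mcts-rand`; the value-iteration policy
under the true weights, greedy or softmax(τ_opp), for `mcts-rw`). Children
are keyed by prey action only, so backups average over opponent
stochasticity (open-loop backups). Rollouts use a uniform prey policy;
simulations run to the end of the game; returns are 100 per coin minus
1000·θ on capture, where θ is the threat sensitivity. Returns are min–max
normalized within each tree and the exploration constant is √2, so one
constant serves across θ (neither is reported upstream; the normalized
formulation makes the choice scale-free). The default budget is 1000
simulations per decision; simulations of whole subject cohorts and
recovery fits use 100–300 (recorded in each report) — the toy-oracle tests
hold at these budgets. Coins are consumed once within a simulation.

IBS estimates the log likelihood of observed choices: simulate the model
until it reproduces the observed action; a first match on draw K contributes
`−Σ_{j<K} 1/j`; estimates average over independent repeats (16 by default, 1–2
inside recovery). Simulation is capped (K_max 2500 by default, 15–25 in
recovery) with the contribution floored at the K_max harmonic sum and the
estimate flagged. Parameter estimation for (τ_opp, θ) offers a grid search
over an IBS-scored lattice and a rejection-style scheme (uniform draws
scored by per-choice agreement, best tenth kept) — a deliberate,
lighter-weight replacement for neural posterior estimation over the same
simulator, preserving the estimand without a trained network.

## Behavioral statistics

Hierarchical regressions model accuracy (Bernoulli, logit link) or
confidence (Beta; mean via logit link, free concentration κ; observations
squeezed from [0,1] to (0,1) by `y(n−1)/n + 1/(2n)`) on an intercept and
z-scored trial and game numbers, with non-centered subject coefficients
`β_s = μ + σ·ε_s`. Priors: Normal(0,1) on μ and ε, HalfNormal(1) on σ,
log-normal-ish prior on κ. Sampling uses emcee with differential-evolution
moves (vectorized posterior; ≥2000 steps, first half discarded); summaries
(mean, 95% HPDI, bulk ESS, R-hat) come from arviz with walkers treated as
chains, and any group-level R-hat above 1.05 flags the fit — ensemble
chains in ~40 dimensions mix slowly, so flagged fits at default budgets are
expected and the HPDIs should be read as approximate.

Zone occupancy divides the prey's steps inside the rich-reward zone by the
maximum attainable count: total prey moves minus the BFS shortest-path lead-in
(`max(0, T − (d−1))` for distance d), assuming the zone can be held once
reached — true for every generated zone (≥2 adjacent cells). Rating error is
the mean absolute difference from the calibrated truth on [−4, 4]; its null
distribution uses uniform integer ratings on the 9-point scale.

## Synthetic data

The generator emulates the three studies without any deposited data.
Environment archetypes reproduce defining constraints rather than literal
maps. `decoupled` places red ground along the predator's route to its trees.
`avoid` (unsafe) puts the rich coins inside a one-cell-wide walled corridor
whose only passage is blocked by the tree pair where the predator camps:
with a fully predictable predator, rewards in the open can always be grazed
safely by an exact planner, so genuine unsafety requires geometry that
forces the prey through the predator's cycle — as the original walled maps
did. A safe lure coin at the corridor mouth lets short-sighted planners
discover the corridor at desk-scale search budgets. `approach` (safe) comes
in two flavors: "camp" (experiment-2 cells) places the trees just beyond
the predator's start so it settles immediately, with the rich zone a few
cells beneath the start — safe in fact, but risky under an opponent model
that expects random straying; "transit" (experiment-3 cells) places the
trees far across the map and the zone close beneath the early leg of the
predator's long sweep, which gives noisy opponent models real exposure and
threat sensitivity its leverage. The prey start is searched to be 3–4 moves
from the zone with the sparse coins no closer, so the approach/avoid
trade-off is genuine. `random`/`practice` layouts place one well-separated
cluster per feature plus scattered singleton patches, echoing the task
maps' feature density (without the separation, trajectories cannot
disambiguate preferences; without the singletons, short chase paths cross
no static features at all). Approach/avoid layouts are verified by
simulating the greedy predator and intersecting its route with the zone;
generation retries with jittered placements.

Simulated observers predict from the W-weighted combined model (defaults
centred on W ≈ 0.87 with subject-level jitter), rate confidence from a Beta
model improving over the session, and report weights as calibrated truth
plus Gaussian noise (SD 1.0) rounded to the 9-point scale. The prey in
chase simulations forages under threat, like a participant whose score
depends on coins: each candidate move is scored by distance-to-predator
minus 0.5 × distance-to-nearest-remaining-coin, with 15% uniform lapses
(pure flight and pure random walks are available as options, but both
produce an artifact — prey motion correlated with the predator's direction
of travel — that contaminates reward-weight inference with spurious prey
evidence). With the predator moving twice per prey move, most
prey-preference games end in capture, as in the real task. Planner subjects run an MCTS variant per move. Move structure
follows the studies: 1 prey / 2 predator moves × 10 turns (experiment 1),
4 / 6 × 2 (experiment 2), 1 / 2 × 12 or 4 / 8 × 3 (experiment 3 short/long),
and the experiment-3 2 × 3 design crosses horizon with predictable /
irreducible (softmax τ = 1) / reducible (weights withheld) predators.

What passing tests on these data do **not** show: human participants differ
from the generative models in ways the pipeline cannot detect here (lapses,
learning of the layout itself, risk attitudes beyond θ), the archetypes
reproduce constraints rather than the original maps, and recovery results
certify identifiability **under the generator's noise levels**, not under
human noise.

## Recovery studies

For each family the harness simulates datasets from every candidate with
parameters drawn uniformly within the fitting bounds, fits all candidates,
and tabulates best-fit counts (lowest BIC; highest IBS log likelihood for
planning) plus generating-vs-recovered parameter correlations. Prediction
datasets use ~240 trials (12 games); IRL datasets use 3 games × 20 moves on
small (12 × 8) layouts with per-game random preference conditions — with a
single condition the five estimators' predictions are nearly collinear and
no confusion analysis can separate them — and report winner stability over
random 50-dataset subsets; planning datasets use one approach and one avoid
game, generated at 200 simulations per move and fitted at 150 with reduced
IBS budgets, all recorded in the report notes.

## Known limitations

- The hex layout, MaxEnt visitation initialization, MaxEnt learning-rate
  schedule, UCT exploration constant and simulation budgets, and the
  combined-model normalization are pinned choices where the source
  material is silent; each is documented above and changing them changes
  numbers, not conclusions.
- The ensemble sampler's R-hat on the hierarchical regressions exceeds NUTS
  standards at default budgets; increase `n_steps` for publication-grade
  intervals.
- Kernel generalization at length scale 0.02 is a numerical no-op under the
  circular action metric; the scale of the kernel's input axis is the one
  genuinely underdetermined quantity in the model family.
- IBS with a small K_max floors very unlikely choices, biasing recovery
  log likelihoods upward for badly misfitting models; this only tightens
  the model-comparison tests.
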