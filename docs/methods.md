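# Methods

## The task

Each simulated session mirrors a binary size-classification experiment.  A
run is 170 trials; the five stimulus levels (integer units −2…2) are
randomized within every block of five trials, so each level occurs 34 times
per run and the level cannot repeat within a block.  Corrective feedback is
stochastic: on every trial a virtual criterion `b ~ N(μ_True, σ_True²)`
with `σ_True = 1.28` decides the nominally correct class (*large* iff
`S > b`), and feedback reports whether the choice matched that class.  Per
run, `μ_True` is 0 for the first 40–50 trials (the switch trial is drawn
uniformly in that range; the design leaves the rule open) and then switches
to one of {−0.4, 0, +0.4}, assigned to runs in equal proportion in shuffled
order.  A session is 30 runs.  Stimulus units are the integer levels
throughout; physical ring sizes are metadata and never enter computation.
Invalid/no-response trials are not simulated; a `valid` flag exists for
ingesting real data.

Agents are re-initialized at each run start (boundary belief to its prior,
values to `V_init`), reflecting the per-run reference display; this is
configurable off.  Lapse trials (probability `lapse_rate`) replace the
agent's choice with a fair coin without informing the agent.

## The two learning accounts

**Value updating** (belief-based RL).  Given measurement `m ~ N(S, σ_m²)`,
the belief state is `p_L = Φ((m − μ₀)/σ_m)` with a constant boundary `μ₀`.
Expected values are `Q_L = p_L V_L`, `Q_S = (1 − p_L) V_S`; choice is
softmax with inverse temperature β.  After feedback (`r = 1` correct, `0`
incorrect) the chosen value updates by `δ = r − p_C V_C`, `V_C ← V_C + αδ`.
Since `δ` keeps the sign of the feedback until `Q_C` reaches the reward
ceiling, feedback effects shrink with confidence but never reverse.  No
temporal discounting; rewards exactly {0, 1}; values unclipped (fitting
bounds constrain them instead).

**Boundary updating** (Bayesian criterion learning).  The agent's internal
model assumes `S ~ N(B, σ_S²)`, `m ~ N(S, σ_m²)`, and a mnemonic recall
`m′ ~ N(m, σ_m′²)` available at update time.  Decisions use only the belief
mean: `p_L = Φ((m − B̂)/σ_m)`, *large* iff `p_L > 0.5` (exact ties broken by
a fair coin; a measure-zero event).  After feedback, the informed class
state is deduced (`CL = large` iff (*large*, *correct*) or (*small*,
*incorrect*)) and the boundary belief is updated by Bayes' rule with the
closed-form likelihood

    p(m′, CL=small | b) = Φ((b − w(b))/√v) · N(m′; b, σ_M² + σ_S²),
    w(b) = (b σ_M² + m′ σ_S²)/(σ_M² + σ_S²),  v = σ_M² σ_S²/(σ_M² + σ_S²),

with `σ_M² = σ_m′² + σ_m²` and the complementary CDF for `CL = large`.  The
Gaussian factor attracts the boundary toward the remembered stimulus; the
CDF factor pushes it away from the informed class side.  Their balance
produces the stimulus-dependent bias reversal.  On recall as the next
trial's prior, the posterior decays toward the attractor `μ₀` with rate
`λ = σ₀²/(σ₀² + σ²_post)` and gains diffusion variance `σ_diffusion²`,
which keeps the belief from sharpening to a halt.

The decision stage takes `p(S|m) = N(S; m, σ_m²)`; the alternative of
shrinking it by the believed stimulus prior is a genuinely open modelling
choice we did not adopt, because the belief-state definition is stated in
exactly this unshrunk form for the RL account and the two accounts must
share their perception stage.  The run-start belief is `N(μ₀, σ₀²)`; the
design motivates a per-run reset but leaves the exact initial belief open.

**Reference agents.**  Base: boundary fixed at 0, argmax readout — one free
parameter (σ_m).  Fixed: constant fitted boundary μ₀ — two.  Hybrid: both
updating algorithms on one platform, softmax readout over values times
BMBU-inferred class probabilities — nine.  Base and Fixed use argmax on
`p_L` (their stochasticity is the measurement), matching their parameter
counts.  In the Hybrid, the value update and boundary update are computed
from the same episode and are independent given it, so their order is
irrelevant.

## Numerics of the posterior grid

The boundary posterior is evaluated on a dense grid: support is the union
of prior mean ± 8 prior SD and `m′` ± 8 √(σ_S² + σ_M²), 2001 points,
trapezoid integration; the returned belief carries the grid mean and
variance (the recall step consumes exactly these two moments; the
non-Gaussian shape is not otherwise retained).  Two safeguards: if the
normalizer underflows, the grid is widened once before failing; and if the
posterior mass occupies under 20% of the support (a prior far sharper than
the grid spacing, as in the pinned-decay limit σ₀ → 0), the grid is re-laid
over the occupied region so the moments stay resolved.  Accuracy is
validated against a 10⁵-point refinement (≤ 1e−4 on both moments) and the
closed-form likelihood against brute-force quadrature (≤ 1e−8).  Simulation
and fitting paths may lower `n_grid` (1001/501/401 below) to trade accuracy
for speed; the validation suite runs at the 2001-point default.

## History-effect estimation

For each of the 20 episodes, all matching trials (toi) are located and the
trials at toi−1 (retrospective) and toi+1 (prospective) are stacked,
respecting run boundaries.  A cumulative Gaussian is fitted to the stacked
choice proportions by binomial maximum likelihood; the PSE is its mean, with
negative values meaning bias toward *large*.  The reported estimate is the
mean PSE over binomial bootstrap resamples (default 5,000) drawn at the
observed per-level proportions — observed rather than fitted proportions,
for model-freeness — with their SD as its uncertainty.  Resamples with
non-identifiable refits are dropped and counted; the estimate is flagged
when over 20% drop.  Cells with fewer than 50 conditioned trials (default,
configurable) are reported missing, never imputed.  The guess/lapse variant
bounds γ, λ in [0, 0.5] by bounded maximum likelihood.  Note one property
of the block design: the trial after a level-`s` trial repeats `s` only
across block edges (P = 0.04 vs 0.24 for the other levels), so
episode-conditioned successor stimuli are not uniform; the analyses never
assume they are.

## Fitting

The log likelihood of a simulator agent is estimated without bias by
inverse binomial sampling: per trial, simulated choices are drawn until one
matches the observed choice, and a match on draw K contributes
`−Σ_{j=1}^{K−1} 1/j`.  Latent state is propagated between trials using the
observed choice and feedback (clamped to data), with the matching draw's
measurement feeding the memory/update step, so the emission stays
consistent with the conditioning event; this convention is isolated in one
function so a full-resimulation alternative can be swapped in.  The
per-draw emission is a lapse mixture (probability `lapse_rate` of a fair
coin), which bounds the match probability away from zero; the session-level
lapse rate is `(γ + λ)/2` from the 4-parameter fit to the grand-mean
psychometric curve.  Trials exceeding `max_draws` (default 10⁴) are floored
at the corresponding harmonic sum and flagged.

Optimization: Latin-hypercube start points within box bounds (σ's in
[0.01, 10], α in [0, 1], β in [0, 50], μ₀ in [−2, 2], V_init in [0, 5]; all
configurable), with scale parameters searched in log space and one start
seeded from the data (σ_m from the grand psychometric slope, μ₀ from its
PSE).  Each start runs bounded Powell on the IBS objective under common
random numbers with *per-trial* substreams (counter-keyed Philox lanes), so
the frozen-noise surface is smooth in θ and deterministic within a start.
A noise-aware refinement follows: every start's optimum is re-scored under
one shared multi-seed average, the best is re-optimized under that
re-averaged objective (optionally followed by a short many-repetition
polish), and the winner is re-evaluated on fresh seeds for the reported
log likelihood.  When fits of competing models will be compared, the final
evaluation can share one seed set across models, which estimates evidence
*differences* with roughly an order of magnitude less noise — decisive for
penalty-separated nested pairs.  Acceptance of the scheme is defined by
recovery tests, not by any particular optimizer trajectory.

## Model comparison

Per-agent evidence is `−AICc/2` with `AICc = −2LL + 2p + 2p(p+1)/(n−p−1)`.
Group-level inference follows the standard variational random-effects
scheme: uniform Dirichlet(1) prior over model frequencies, responsibilities
∝ exp(evidence + digamma terms), concentration updates to a 1e−6 tolerance
(max 500 iterations).  Exceedance probabilities come from Monte-Carlo
sampling of the Dirichlet posterior (10⁶ samples by default); the Bayesian
omnibus risk from the free-energy comparison against the null of equal
frequencies; protected exceedance is `(1 − BOR)·XP + BOR/M`.

## Synthetic-data generator: what it does and does not emulate

The generator reproduces the design variables that drive the analyses —
block-randomized stimuli, run structure, stochastic nonveridical feedback,
criterion drift, lapses — and is the package's stand-in for human data.  It
does not emulate response times, deadline pressure, finger-mapping effects,
session-to-session carryover, or slow non-systematic drifts in strategy.
Tests passing on synthetic data therefore establish the internal
consistency of the method (models are simulable, identifiable, and their
predicted signatures measurable by the analysis pipeline), not that any
particular human population behaves like either agent.

## Default parameters and calibration

`σ_True = 1.28`, 170 trials/run, 30 runs, blocks of 5, and the μ_True
schedule are fixed design constants.  The ex ante simulation varies σ_m
over 25 uniform levels on [0.15, 3.27] with no lapses and no bias
(μ₀ = 0).  The remaining parameters are exposed in config with defaults
chosen once against two criteria: simulated task accuracy must fall in the
observed human range (about 61–74% correct; our grid averages ≈ 70%), and
the agents must express their defining qualitative signatures across the
whole σ_m grid — monotone feedback-congruent bias for value updating, bias
reversal between S = 0 and S = 2 for boundary updating.  The chosen
defaults are: value agent `α = 0.2, β = 4, V_init = 1`; boundary agent
`σ_S = 2.2, σ₀ = 2.0, σ_m′ = 0.8, σ_diffusion = 0.4`.  The signature
constraint binds: with larger memory noise or a tighter believed stimulus
spread, the measurement pull overtakes the feedback push at weak stimuli
once σ_m is large, and the S = 0 bias loses its sign consistency across the
grid.  A persistent prior (σ₀ large relative to σ_diffusion) and a broad
believed stimulus spread keep the feedback push dominant at weak evidence
while the measurement pull still wins at S = 2.

## Problem sizes used in validation

The committed test-suite and acceptance-script runs use desk scales chosen
as the package's own validation sizes: ex ante, 10 σ_m levels × 30 runs ×
20–40 repetitions (prospective direction, grid 1001, 150 bootstrap
resamples per cell); the no-updating null, 60–100 sessions of 30 runs with
200 bootstrap resamples per cell; IBS bias, 3–10 × 10⁴ repetitions of an
exactly solvable two-trial problem; parameter recovery, 6 agents × 1,020
trials per main model; model recovery, four generating models with
per-model dataset designs (12×170 and 8×170 for the penalty-separated Base
and Fixed rows, 6×680 and 7×850 for the dynamic rows), all four candidates fitted to
every dataset under shared final evaluation seeds (grid 301, 500-draw IBS
cap).  Full-scale analogues (100 repetitions, 153,000-trial recovery
datasets, 20 starts) are available through the same configs.

## Known limitations

- IBS estimates are noisy (SD grows with √trials); the refinement stage
  reduces but does not remove optimizer noise, so desk-scale recovery
  correlations are conservative lower bounds on full-scale performance.
- In the value-updating model, σ_m and the softmax inverse temperature β
  trade off along a shallow observational ridge: a near-argmax readout
  (large β) with inflated σ_m produces nearly the same choice statistics as
  the true soft readout.  Recovered σ_m therefore correlates excellently
  with the truth (r > 0.9) but carries a positive offset (~+0.3 level
  units, stable from 10³ to 5×10³ trials), with β absorbing the
  difference; μ₀ and the world model's parameters are unaffected.  Fits of
  the value model to real data should interpret σ_m and β jointly, not
  separately.
- The skew-normal family of the exact posterior is summarized by two
  moments at recall; trial-by-trial traces of the full shape are available
  only through the returned grid.
- Group BMS exceedance uses Monte-Carlo sampling; at the default 10⁶
  samples the PXP resolution is ~1e−3.
- The Hybrid agent's nine parameters are weakly identified at small trial
  counts; it is included for model comparison, not for parameter
  interpretation.
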