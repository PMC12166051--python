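# Methods

## Task model

The task is a 5×5 grid world navigated with three moves — up-left
(−1, −1), down (+1, 0), up-right (−1, +1) under a rows-top-to-bottom
convention — in fixed sequences of four moves from a fixed start cell.
Paths may not leave the grid or revisit any cell, the start cell
included. From the grid center (2, 2) exactly 36 of the 3⁴ = 81 raw move
strings survive these rules; brute-force scanning of all 25 candidate
start cells shows the center is the only start with that count, and it
admits the two-downs-then-two-up-rights default sequence, so (2, 2) is
the package default (the enumerator stays parameterized by start cell).
The only way a path can revisit a cell is to return to the start, which
happens exactly for the in-bounds permutations of {L, R, D, D}; 12 of
the 81 raw strings are such permutations.

Circle values are multiples of 10 in [−60, 60] without zero. Collected
points receive additive Gaussian noise (σ = 1.3 per move) rounded half
away from zero — the symmetric reading of "nearest integer" that avoids
a sign-dependent bias between positive and negative circles. The trial
reward is max{0, 100 − 2·|goal − points|}.

## Canonical design

16 blocks × 20 trials. Goals are stored as offsets from the default
sequence's expected sum (default 120, i.e., four circles averaging 30;
the sum is configurable and goals scale with it, so the choice is
inert). The four shipped goal trajectories are canonical integer tables
chosen to satisfy every quantitative constraint the design states:

* 20 goals each; the first two offsets of every trajectory within ±5;
* per-trajectory maximum absolute offsets {24, 16, 20, 12}, spanning
  12–24 — one trajectory rises after mid-block and falls back (max 24),
  one stays mostly near zero (max 12);
* per-trajectory in-window (|offset| ≤ 5) counts {7, 7, 7, 14}, so with
  each trajectory presented once per 4-block segment the design-wide
  in-window share is exactly 140/320 = 43.75%.

The exact shapes beyond these constraints are illustrative; only the
constraints are asserted by tests. Segment orders are a fixed
pseudo-random Latin arrangement with no trajectory repeated across any
block boundary; 8 of 16 blocks are bonus blocks, two per trajectory.
Default-sequence circle values differ across blocks at constant sum.

Block grids carry the default sequence's four values on its path; the
other 20 cells are drawn uniformly from the allowed values with a
per-(seed, block) generator, resampled deterministically until every
out-of-window goal admits at least one sequence strictly closer to the
goal than the default sequence — so deviating is always in principle
worthwhile out of window. In window the default is automatically among
the best sequences, since every other point sum is a multiple of 10.
Bonus receipt is sampled at p = 0.25 exactly when the default sequence
is chosen in a bonus block; the realized +20 enters the reward, never
the learned point sum.

## Choice models

All models share the value term p(R̂|π) = (R̂_π/ΣR̂)^β over the
36-sequence space and differ in the reward structure and the presence of
a repetition prior (see README for the family). Implementation choices
where the design was genuinely open:

* **Observed rewards.** "The exact observed reward" is operationalized
  as: store the sequence's realized point total and recompute the reward
  against the *current* trial's goal (goals change within a block, so
  caching a stale reward would be incoherent). If a sequence is repeated
  within a block, the latest observation overwrites earlier ones —
  the simplest memory; the point noise is small and zero-mean, so the
  alternatives (first-wins, averaging) differ negligibly.
* **Memory horizons.** Observed point sums reset to the default sequence
  alone at each block boundary (grids change between blocks); usage
  counts γ never reset — the repetition prior accumulates over the whole
  session.
* **Reward floor.** R̂ entries are clamped at ε = 0.01: the reward rule
  can produce exactly 0, which would zero the choice probability and
  make an observed choice impossible (−∞ log-likelihood). The floor is
  two orders of magnitude below any attainable reward difference, so the
  distortion is negligible, and it also makes β = 0 well-defined
  (pure-prior model; 0⁰ never arises).
* **Exact-reward model.** EVM's expected rewards use noiseless cell
  sums; the point noise does not depend on the sequence and so cannot
  change the ordering.
* **Timeouts** update no beliefs and contribute no likelihood terms.
  All behavioral proportions likewise exclude timed-out trials from
  numerator and denominator.

Probabilities are computed in log space (stable for large β); the
likelihood precomputes the parameter-independent belief trajectory per
participant once, reducing each likelihood evaluation to a (trials × 36)
array operation.

## Fitting

Priors (shape–rate Gammas, the convention of the probabilistic-
programming stack this literature uses): β ~ Gamma(3, 1),
R0 ~ Gamma(55, 0.75), h ~ Beta(3, 3), b_DAS ~ Gamma(3, 0.1). Fits are
per-participant and independent; no hierarchical pooling.

* **MAP**: multi-start (default 8: prior medians plus prior draws)
  L-BFGS-B on transformed parameters (log β, log R0, logit h,
  log b_DAS) maximizing log-likelihood + log-prior. Deterministic per
  seed; the workhorse for recovery pipelines.
* **MCMC**: affine-invariant ensemble sampling (emcee) on the same
  transformed posterior including the change-of-variables Jacobian,
  initialized in a tight ball around the MAP mode. Defaults: 4 chains ×
  1000 retained draws after 1000 warm-up, with internal thinning
  (factor 4) because ensemble walkers are autocorrelated; walkers are
  treated as chains for split-R̂, and R̂ > 1.01 surfaces as a warning in
  the diagnostics, never silently. Pointwise log-likelihoods are emitted
  for every retained draw. Desk-scale runs in the test suite use
  2 chains × 300 draws.

Shrinkage is 1 − (posterior SD/prior SD)². With a strongly repetitive
simulated agent most parameters shrink strongly (β and R0 ≈ 0.85), but
h itself shows only ≈ 0.35 under the shipped design: high bias
strengths are weakly identified (see Limitations), so the package
asserts the group-level property — most shrinkage values above 0.4 —
rather than a per-parameter bound.

## Model comparison

PSIS-LOO is implemented in-package: per-trial importance ratios are the
reciprocal likelihoods; the largest ⌈min(S/5, 3√S)⌉ weights are replaced
by expected order statistics of a generalized Pareto distribution fitted
to the exceedances (Zhang–Stephens empirical-Bayes estimator), capped at
the maximum raw weight; k̂ > 0.7 flags unreliable trials. The in-package
implementation exists because the degenerate constant-likelihood case
(the UNIFORM baseline) must reduce exactly to the closed form
elpd = −N·ln 36 (LOOIC = 2N·ln 36); a unit test cross-checks the
implementation against an independent library oracle to machine
precision on random matrices. LOOIC differences and their standard
errors come from pointwise elpd differences against the best model;
participant-level best-model ties within 10⁻⁹ are recorded as ties and
assigned to no model.

Point (MAP) fits are compared through a penalized approximation packaged
as the same result type: elpd ≈ Σ pointwise log-likelihood − k free
parameters, the classic information-criterion penalty, with the penalty
spread uniformly over trials so pointwise differences stay meaningful.
This is an approximation to, not an estimate of, leave-one-out accuracy;
the full PSIS-LOO path is used whenever draws exist.

## Synthetic cohorts and what they do (not) show

Simulated agents sample every trial from their model's choice
distribution, observe noisy realized points and update beliefs exactly
as the likelihood assumes, and never time out. The generator therefore
emulates the experimental *design* (trial structure, goal trajectories,
bonus schedule, point noise) and *model-consistent* choice behavior. It
does not emulate: reaction times, lapses/timeouts, within-session
parameter drift, or any strategy outside the model family (e.g., the
goal-threshold heuristics real participants report). Passing recovery
tests on these cohorts shows the estimation and selection machinery is
sound under the model's own assumptions — not that the models are true
of human data.

Validation pipelines (all bit-reproducible under fixed seeds, reports
carry a config hash):

* **Demonstration run**: 100 sessions at β = 5, R0 = 70, h = 0.91. The
  default sequence's prior grows monotonically in trend from 1/36 and
  the mean choice probability is higher over the last 80 than the first
  80 trials (≈ 0.28 → 0.63 on the shipped design). Exact levels are
  design-dependent (grids and goal tables are this package's canonical
  stand-ins), so structure, not levels, is asserted.
* **Parameter recovery**: 24 agents over h ∈ {0.1, 0.5, 0.9} ×
  β ∈ {2, 8} × R0 ∈ {40, 70} × 2 seeds, MAP-fitted; Spearman ρ ≥ 0.7
  for h and β. β and R0 recover cleanly; h recovery is rank-correct but
  compressed (see Limitations).
* **Model recovery**: cohorts simulated from each generating model are
  fitted by all candidates and assigned by LOOIC; a strong-repetition
  cohort (h = 0.9) is attributed to the repetition-prior model at the
  group level and for a majority of individual agents.

Problem sizes in the shipped tests (agents per grid cell, draws per
chain, sessions per demonstration) are the package's desk-scale
defaults, chosen so the full loop stays interactive; every pipeline
accepts larger values through the same entry points.

## Known limitations

* **Identifiability of h.** Agents with high β and low R0 choose the
  default sequence on ~95% of trials regardless of h (repetition is then
  explained by the value term), leaving the likelihood nearly flat in h.
  Consequently h estimates are biased toward the prior center: low-to-
  medium strengths are overestimated and high strengths underestimated,
  and the posterior of h can remain wide even for strongly repetitive
  agents. No unbiasedness is asserted for h < 0.4 or h > 0.8.
* The ensemble sampler is not a gradient-based sampler; its draws mix
  more slowly per step, which the thinning defaults compensate only
  partly at desk scale (inspect the reported R̂ before using desk-scale
  posteriors quantitatively).
* The canonical grids and goal tables satisfy all stated quantitative
  constraints but are otherwise this package's own constructions;
  quantities that depend on the specific layouts (e.g., mean rewards of
  particular strategies) are not comparable across other instantiations
  of the same design rules.
* Per-move (within-sequence) decisions, the redo-on-invalid-move
  mechanic, and forward planning are outside the models' scope: the unit
  of choice is the whole four-move sequence.
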