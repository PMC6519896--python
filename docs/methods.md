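# Methods

## The process being modelled

`scidiscovery` simulates scientific discovery as iterated model comparison.
A community of scientists shares one consensus, the *global model* M_G,
drawn from a fixed universe of candidate linear models. At each discrete
time step one scientist, sampled from the population, runs an idealized
experiment: she proposes a challenger M_P, a fresh dataset D is generated
from the (unknown to her) true model, and a penalized-likelihood statistic
S decides the contest. The proposal dethrones the consensus iff
S(M_P) < S(M_G) strictly; otherwise — losses, exact ties, self-proposals —
the consensus stands. The true model is always a member of the search
space, so the interesting dynamics come entirely from *how* the space is
searched and *how* contests are decided, not from misspecification.

Four properties of the resulting consensus trajectory are studied: the
mean first passage time to the true model (speed of discovery), the
stickiness of the true model (one-step probability of keeping it once it
is consensus), the long-run proportion of time the truth is consensus
(stationary probability), and — once replication experiments enter — the
rate of reproducibility.

## Model space

Candidate models are hierarchical linear models without intercept on
three factors: every interaction term present implies all its lower-order
terms. The enumerated space consists of the hierarchical closures of
"any subset of main effects plus at most one interaction term", which on
three factors gives exactly 14 models: the 7 nonempty main-effect subsets,
{xi, xj, xixj} for each pair, {x1, x2, x3, xixj} for each pair, and the
full 7-predictor model. Hierarchical models with two two-way interactions
but no three-way (e.g. {x1,x2,x3,x1x2,x1x3}) are deliberately *not*
members; proposal moves that would land there are disallowed. Factor
counts other than 3 are supported by the same rule but are outside the
canonical analysis.

Models serialize to labels like `1+2+12` (for y = β1x1 + β2x2 + β12x1x2 + ε)
used in all CSV/JSON output and on the command line.

## Data generation and noise calibration

Each experiment draws n = 100 rows with the three factors i.i.d.
Normal(mean 1, sd 1) by default (uniform laws and per-factor
means/scales are configurable), and

    y_i = Σ_T θ_T Π_{j∈T} x_ij + ε_i,   ε_i ~ N(0, σ²).

All coefficients default to θ_T = 1. The error variance is calibrated
through the noise-to-signal ratio σ² : E(y|μ_x), where E(y|μ_x) is the
deterministic part at the predictor means; ratio 1:4 (the low-noise
default) means σ² = E(y|μ_x)/4. With unit means and coefficients,
E(y|μ_x) equals the predictor count, so the full model has E = 7.

The predictor law and the coefficients are exactly the quantities the
original study did not print; the defaults above are this package's
documented reconstruction, chosen for symmetry
(every term contributes equally) and a strictly positive calibration base.
The reconstruction reproduces every *qualitative* pattern of the study
(orderings across populations and statistics, limits, the hard-strategy
ABM first-passage scale) but yields a stronger signal than the original
runs — a single main effect has a t-statistic around 20 at n = 100 — so
the *levels* of the stochastic aggregates (time at truth, its printed
percentages) come out higher than the printed ones. See "What passing
tests show" below.

## Model fitting and contests

Fits are Gaussian maximum likelihood: least squares with σ̂² = RSS/n and
max log L = −(n/2)(log(2π σ̂²) + 1). The two comparison statistics are

    AIC = 2k − 2 log L_max,     SC = k log n − 2 log L_max,

with k counting the error variance (k = predictors + 1). Because every
contest compares two models on the *same* dataset with the same n, the
"+1" shifts both scores equally and never changes a contest between
models differing only in predictors. A zero-RSS fit (possible only in the
σ² = 0 limit) gets a −∞ likelihood sentinel and contests between two
perfect fits are decided by k alone — the limiting behaviour of the
penalty. Rank-deficient designs raise rather than guess.

Win probabilities P(M_P dethrones M_G) are estimated by Monte Carlo. The
pairwise estimator uses independent datasets per pair; the table builder
scores all 14 models on one shared batch of datasets (default 10⁴) and
reads off every pairwise comparison, which is statistically equivalent
per entry and ~200× cheaper. Batched fitting shares one 7-column Gram
matrix per dataset across all models.

## Scientist types and strategy modes

* **Tess** (theory tester): uniform over in-space models exactly one main
  effect away from the consensus; dropping a main drops every interaction
  containing it; moves leaving the space are excluded, as is the empty
  model.
* **Mave** (maverick): uniform over all 14 models, ignoring the consensus
  (the current global model is included; proposing it is a no-op contest —
  a config flag excludes it instead).
* **Bo** (boundary tester): uniform over the models that add one
  interaction (plus its hierarchical closure) to the consensus. At the
  full model this set is empty and Bo proposes the consensus itself, a
  guaranteed retain — this keeps the step well defined without injecting
  off-strategy behaviour.
* **Rey** (replicator): no proposal distribution; see the ABM below.

A *hard* strategy is exactly the above. A *soft* strategy re-allocates a
small probability ε (default 0.1) uniformly over the models *outside*
the strategy set (a variant spreading ε over the whole space is
available). Soft mode gives every model positive proposal probability
under every type, which is what makes the no-replication chain's
transition graph fully connected.

## The exact chain (no replication)

Without a replicator the consensus is a first-order Markov chain with

    T[g→m] = Σ_t w_t · q_t(m|g) · p_win(m,g)   (m ≠ g),

diagonal by complementarity. Population presets: 99% of the dominant
type with the remaining 1% split equally over the other two proposing
types, and an epistemically diverse preset at 1/3 each.

The stationary distribution is obtained from the linear system
π(T − I) = 0 with Σπ = 1. Uniqueness requires a single *closed*
communicating class rather than full irreducibility: Monte-Carlo win
tables legitimately contain exact zeros for contests whose true
probability is astronomically small, which makes the corresponding
models transient (π = 0) without affecting the long-run law. Several
closed classes raise an error carrying the class decomposition. The
diagonal of T is positive in practice (retained contests), so
periodicity is not a concern. Mean first passage times solve
m_i = 1 + Σ_{j≠target} T[i,j] m_j after a reachability check; stickiness
is simply T[truth, truth].

## The agent-based process (with replication)

A replication experiment re-runs the *predecessor's* exact
(M_P, M_G) pair on new data — even when the consensus has moved in
between, and even when the predecessor was herself a replication (the
pair propagates). The result reproduces the original iff the win/lose
outcome matches. Because a step now depends on the previous experiment,
the process is a higher-order chain and is analyzed by forward
simulation. Conventions, each chosen where the study design left the
point open and surfaced as configuration:

* the initial consensus is uniform over the 13 non-true models
  (fixable);
* if the replicator is drawn at t = 0 she is redrawn among proposing
  types (a replication needs a predecessor);
* Rey's own contest outcome updates the consensus (the update rule is
  unconditional); a flag disables this for sensitivity analysis;
* first passage counts steps from t = 0 *without* burn-in discard and is
  0 if the run starts at the truth; runs that never hit the truth are
  reported censored, never imputed — pooled medians enter censored runs
  as +∞ and are therefore defined whenever censoring is below 50%;
* all other metrics (time at truth, empirical stickiness, reproducibility
  rates) use post-burn-in steps only. Reproducibility rates are plain
  sample proportions, overall and stratified by whether the replicated
  pair's global model was the truth; a stratum with no replications is
  undefined (None), not zero.

Runs default to 11000 iterations with 1000 burn-in. For speed, a run
precomputes the RSS of all 14 models on each step's fresh dataset in one
batched pass; the sequential loop does only bookkeeping, making a full
run ≈0.5 s. A reference single-`step` implementation with identical
decision logic exists for structural tests.

## Factorial design and summaries

The ABM factorial crosses 3 true models ({x1}, {x1,x2,x3,x1x2}, full
model — a complexity gradient), 3 noise ratios (1:4, 1:1, 4:1), 5
populations (four 99%-dominant, one diverse at 25% each) and both
statistics, with hard strategies by default and 100 independently seeded
replicates per cell (seed = SeedSequence(base, (design, cell,
replicate)), so results are bit-reproducible and order-independent).
Summaries report per-group and marginal medians, IQRs and means, plus
Spearman rank correlations (scipy, average ranks; constant input raises
an explicit undefined-correlation error) between the reproducibility rate
and the other properties.

## Problem sizes used in the shipped analyses

The acceptance script uses 10⁴ Monte-Carlo datasets per win-probability
table and 20 replicates per factorial cell at full 11000-iteration runs;
the test suite uses the same machinery at reduced scale (2.5k-rep tables,
2 replicates per cell, 10⁵-step trajectories for the ABM-vs-chain
cross-validation). These sizes give binomial standard errors ≤ 0.005 on
win probabilities and keep the full analysis within minutes on one core.

## What passing tests do and do not show

The synthetic generator *is* the study system — there is no external
data. Structural and limiting results (the 14-model space, distribution
normalization, stationary fixed points, replication semantics, σ² = 0
determinism, SC consistency in n, the equivalence of the forward
simulation and the exact chain) are exact or statistically tight and are
all verified. The *levels* of the stochastic aggregates depend on the
reconstructed generator parameters: with the defaults above, time spent
at the truth is systematically higher, and soft-strategy passage times
longer, than the original study's printed values, while every ordering
and interaction pattern among populations and statistics reproduces.
One structural note: with per-experiment step counting, the mean first
passage time of a 99%-dominant population is bounded below by ~14 steps
(a uniform proposer hits a specific model with probability ≤ 1/14 per
step), so printed single-digit passage times are only consistent with
counting consensus *changes*; this package counts experiments, as its
chain operations define.

## Known limitations

Scientists have no memory, no learning, no direct interaction, and no
questionable research practices — by design. The replicator replicates
only her immediate predecessor. The model universe is small and fully
enumerable; nothing here addresses search in spaces too large to
enumerate, non-Gaussian noise, correlated designs, or measurement error.
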