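# Methods

## The optimization model

Both optimizers minimize a scalar fitness over a box. The population of
`n_agents` whales is updated synchronously once per iteration; within a
sweep, agents are updated sequentially in place, and the random partner used
by the exploration branch is drawn from the live population (so an agent
updated earlier in the sweep can be chosen). The incumbent best is elitist:
it is replaced only on strict improvement, and among equal-fitness agents in
the same sweep the lowest index wins. Candidates falling outside the box are
projected back by clipping (not reflected or resampled), and a candidate
whose fitness evaluates to a non-finite value is rejected — the agent keeps
its previous position — with a warning.

Per agent and iteration, coefficients are drawn as `A = 2a·r − a` and
`C = 2·r′` with independent `r, r′ ~ U[0,1]^d`, `l ~ U[−1,1]`,
`p ~ U[0,1]`, and `a(t) = 2(1 − t/t_max)`. Branch selection: spiral when
`p ≥ 0.5`; otherwise encircle when `|A₀| < 1` and explore when `|A₀| ≥ 1`,
where `A₀` is a single component of the coefficient vector. A single
component carries exactly the `U[−a, a]` law of the scalar coefficient in
the classical formulation, so exploration fires with probability
`(a−1)/a` while `a > 1` and never afterwards. We first used the mean of the
componentwise magnitudes here; that statistic concentrates at `a/2 < 1` by
averaging, which silently disabled the exploration branch after the first
sweep and let the population collapse onto the incumbent — visible as frozen
convergence traces and a collapse of unique candidates in discrete problems.

The distance terms use componentwise absolute values (`D = |C∘X* − X|`,
`D′ = |X* − X|`). Without the absolute value the encircling recursion
diverges for negative distances. The exploration update defaults to the
standard form `X_rand − A∘D`; a `literal_equations` switch exposes the
variant that scales the distance by the agent's own position instead of `A`,
for ablation only.

### MWOA

Two modifications, and only these two: (1) the encircling branch becomes
`w·X + C∘(X* − X)` with `w(t) = cos(nπt/t_max)`; spiral and exploration are
unchanged, and `A` is still drawn each iteration but used only for branch
selection. (2) the initial population comes from the piecewise linear
chaotic map instead of uniform draws. As printed, the inertia-weighted
update carries no absolute value and no `A`; we implement it as printed.
With `n = 1` the inertia weight runs negative in the second half of the run,
reversing the self-term; the default `n = 0.5` keeps `w ∈ [0, 1]`, decaying
1 → 0. Note the incumbent is not a fixed point of this update: at `X = X*` the
attraction term vanishes and the agent moves to `w·X*`, i.e. is pulled
toward the origin as `w` decays — which keeps population diversity up and,
in the binary selection task, acts as sparsity pressure.

### PWLCM

The map on (0,1) with `β ∈ (0, 0.5)` (default 0.4):
`xy → xy/β` on `(0, β)`; `xy → (xy−β)/(0.5−β)` on `[β, 0.5)`; on `[0.5, 1)`
the same two branches applied to `1 − xy`. Degenerate outputs in {0, 1} are
perturbed by `1e−10`; an orbit value that maps onto itself is kicked by
`1e−7` so harvesting never stalls. The invariant density is close to
uniform (all 10 histogram bins of 10⁴ iterates fall in [0.09, 0.11] at
`β = 0.4`) and orbits separated by 1e−8 diverge past 0.1 within ~17 steps.
The starting value for a run is a fixed Knuth multiplicative hash of the run
seed onto (0,1), with a burn-in of 100 iterations.

### Numerical contracts

Identical configuration and seed reproduce histories and best positions bit
for bit. Histories are monotone non-increasing by elitism. On a
5-dimensional quadratic bowl over [−10, 10] (30 agents, 200 iterations) both
variants reach fitness below 1e−2 in at least 9 of 10 seeds.

## Feature selection

Whales live in [0,1]^16 (one dimension per source feature) and are
thresholded at 0.5 into masks at evaluation time; an all-zero mask is
repaired by switching on the largest component. Masks act on source
features: a feature's whole one-hot indicator group is kept or dropped
atomically. Fitness is the convex combination
`α·(1 − F1_cv) + β·(k/d)` with `α = 0.99`, `β = 0.01`, `k` selected
features, `d = 16`, and `F1_cv` the stratified 5-fold cross-validated F1 of
the wrapper classifier on the masked columns. Fold assignment derives from
the run seed and is shared by every evaluation in a run, so masks are
compared on identical folds; repeated masks are served from a cache.

Three design choices matter for search quality and were driven by failure
analysis on planted-signal cohorts:

* **Wrapper classifier = boosted stumps** (depth 1, 100 trees, learning rate
  0.3, fixed, not co-tuned). The label signal in one-hot indicator data is
  additive in the indicators, so stumps suffice to rank masks; deeper trees
  overfit uninformative columns enough to make the fitness non-monotone in
  mask size, burying the feature-count penalty.
* **Sparse, non-overlapping chaotic initialization.** A chaotic permutation
  deals the 16 features round-robin to the agents; each agent starts with
  only its dealt features above threshold. No two whales overlap in their
  initial selected features, the union covers every feature, and the search
  starts from small incumbent masks instead of dense ~8-feature ones.
* **Near-threshold starting values** (off-bits in (0.35, 0.475), on-bits in
  (0.525, 0.70)). The update rules perturb a coordinate in proportion to
  position differences, so a coordinate parked near 0 or 1 (e.g. after
  clipping) becomes practically unswitchable; starting near 0.5 keeps every
  bit reachable throughout the run.

## Hyperparameter tuning

Search box `max_depth ∈ [3, 10]` (integer), `learning_rate ∈ [0.01, 0.3]`
(continuous), `n_estimators ∈ [10, 200]` (integer); integer dimensions are
rounded half away from zero at training time and both raw and decoded values
are reported. The box was chosen to contain the two optima reported for
this problem class — (4, 0.292, 39) and (6, 0.0128, 135) — with margin.
Fitness is `1 − F1_cv` on all features (or a fixed mask), folds again fixed
per run. The library-default configuration (6, 0.3, 100) is injected as
agent 0, so by elitism the tuned result can never score below the baseline
on its own folds — a guarantee the tests assert empirically.

## Synthetic cohorts

The generator reproduces the published composition of the 383-patient DTC
recurrence cohort: per-feature category counts (gender 312/71; pathology
287/48/28/20; N 264/119; M 365/18; stage 333/32/4/3/11; response
208/61/114) and 120 recurrences, exactly, every run. Each feature column is
an independent seeded permutation of its level counts, so columns are
marginally faithful but jointly independent; dependence enters only through
the label model. The published tumor-size sub-level counts sum to 377, not
383; the 6 unaccounted rows are assigned to the modal level T2 and the T
marginal is flagged as adjusted. Features the publication does not tabulate
get uniform placeholder marginals, flagged so tests never treat them as
published values.

Labels in exact mode: rows are ranked by a logistic score and the top 120
become positive, ties broken by row index. Because the score takes few
distinct values, the cut lands inside a tie group whose labels are
index-split — irreducible label noise no classifier can resolve from the
features. The default weights (Response: excellent −0.5 / indeterminate
+0.5 / incomplete +1.0; pathology: micro-papillary and follicular +0.5,
Hurthle +1.5) put roughly 20 such noise rows at the boundary, giving a
strong but imperfect signal: measured 5-fold CV F1 of the default classifier
is ≈ 0.80–0.90 across generator seeds. The sampled mode draws i.i.d. rows
from the marginal proportions with Bernoulli labels from the logistic model.

`plant_signal` rebuilds the label model with weight `effect` on the
elevated-risk levels of designated features and zero elsewhere, giving
selection experiments a known ground truth.

**What the generator does not emulate:** real joint dependence between
clinical features (e.g. stage–N–M consistency), ordinal structure, cohort
heterogeneity, and feature–label relationships beyond the explicit logistic
score. Passing tests therefore demonstrate that the machinery recovers a
known signal under controlled conditions, not that it would select the same
features on real data.

**Known limitation — recovery is realization-sensitive.** The index-split
tie labels are constants of the generated dataset, so other features can
correlate with them by chance; on some generator seeds such chance
correlates are worth more cross-validated F1 than the 0.01/16-per-feature
penalty, and the selected mask legitimately keeps 5–6 features. Measured
over optimizer seeds 0–9 at effect 3.0: recovery of both planted features
with ≤ 4 total succeeds in 9/10 runs (both variants) on the fixture cohort,
but can drop to 3–8/10 on other cohort realizations.

## Evaluation

Positive class is recurrence throughout. Metrics come from integer
confusion-matrix counts; ratios with zero denominators report 0.0 with a
`degenerate` flag rather than raising, keeping batch comparisons total. ROC
thresholds sit at unique score values with tied scores grouped into one
step; AUC is trapezoidal. Comparison tables print integer percents (AUC to
two decimals) and keep full-precision values alongside.

## Problem sizes

Defaults are sized for a laptop CPU: 383-row cohorts, 5-fold CV, selection
at 10 agents × 20 iterations (≈ 200 cached fitness evaluations, a few
seconds per run), tuning at 10 agents × 15 iterations (≈ 10 s). The bowl
benchmark (30 agents × 200 iterations × 10 seeds × 2 variants) takes a few
seconds.
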