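# Methods

## Problem and encoding

Wrapper feature selection scores candidate feature subsets by the
cross-validated performance of a classifier trained on exactly those
columns. `cfsa` encodes a subset of `d` candidate features as a
continuous point in the unit box `[0, 1]^d` and decodes it by
thresholding at 0.5: feature `j` is selected iff `x_j > 0.5`. The unit
box with a midpoint threshold makes selection symmetric (a uniform draw
selects each feature with probability 1/2). If no component clears the
threshold, the largest one is forced on (ties to the lowest index);
repairing rather than raising keeps every optimizer move valid, since a
wrapper objective over zero features is undefined. All moves clamp
out-of-box components to the boundary — the simplest contract, and the
decode only cares about which side of 0.5 a component lies on.

## The cuttlefish algorithm

CFA is a population metaheuristic patterned on the three light-reflecting
cell layers of cuttlefish skin (chromatophores, iridophores,
leucophores). Every move is `new = reflection + visibility`, where
reflection rescales an existing position and visibility scales a
difference toward the current best. The population of `N ≥ 4` members is
split round-robin by index into four near-equal groups (remainders to
the earliest groups):

* **S1 (cases 1–2, stretch/shrink)** `new_j = R·x_j + (best_j − x_j)`
  with `R ~ U(r2, r1)` and visibility fixed at 1. Defaults `r1 = 0.5`,
  `r2 = −2`: R is mostly negative, so this group explores inverted,
  stretched reflections of the member around the best.
* **S2 (cases 3–4, mirror)** `new_j = best_j + V·(best_j − x_j)` with
  `V ~ U(v2, v1)`, defaults `v1 = 1`, `v2 = −1`; reflection is the best
  itself.
* **S3 (case 5, interval around the best)** `new_j = best_j + V·(best_j
  − AVtop)` where `AVtop` is the scalar mean of the best position's
  components, recomputed each outer iteration. The scalar reading of
  "average of the best" is used (the algorithm stores a single best);
  a per-dimension running archive of historical bests would be the
  alternative reading.
* **S4 (case 6, random matching)** a fresh uniform draw, identical to an
  initialisation member.

`R` and `V` are redrawn per member per iteration (not per component).
Replacement is greedy: a proposal replaces the member it was derived
from only when strictly fitter; the global best is updated whenever any
evaluated solution exceeds it. Fitness is maximised. These policies are
the package's own choices where the algorithm statement leaves them
open; together they make the best-so-far trace non-decreasing, which the
tests assert.

## Simulated annealing and the hybrid

SA operates on the same continuous encoding: a neighbour perturbs every
component by an independent `U(−step, step)` draw (default half-width
0.1), the mask is re-decoded and scored, and a worsening move of cost
change `Δc` (cost = −fitness) is accepted with the Metropolis
probability `exp(−Δc/t)`; improvements are always accepted. Note the
exponent sign: the uphill acceptance probability must be `e^{−Δc/t}` —
a positive exponent would exceed one and not be a probability. The
temperature cools geometrically, `t ← α·t`, once per iteration, from
`t0 = 9` with `α = 0.95`; after `k` steps it is exactly `t0·α^k`. The
refinement loop runs `n_iter` iterations (default 100) and returns the
best solution *visited*, never the final accepted state, so refinement
can never lose fitness — this makes the hybrid's "keep the better of
proposal and refinement" merge well-defined.

The hybrid embeds SA in the two exploitative groups: each outer
iteration recomputes `AVtop`, applies the group move to every member,
and for S2/S3 additionally refines the proposal by SA, keeping the
better of the two. With `n_iter = 0` (or `--mode cfa`) the hybrid
reduces exactly to plain CFA — same trajectories under a shared seed,
asserted bitwise in the tests. The outer iteration budget (`max_iter`)
and the SA inner budget are distinct knobs; the reference inner value
100 sits with the temperature constants, and the outer default is also
100, both configurable.

## Objective, caching and determinism

The default objective is `w·acc + (1−w)·(1 − |m|/d)` with `w = 1` (pure
mean stratified k-fold CV accuracy, default 5 folds, k-NN with k = 5 as
the search-time classifier). The parsimony term is provided because
clinical selection pipelines typically prefer compact panels; `w` is a
stated experiment parameter wherever it is not 1. The CV split is
shuffled with a fixed `cv_seed`, making fitness a deterministic function
of the mask; when the smallest class has fewer members than the
requested folds, the fold count is reduced with a warning. Imputation
happens once, before CV — simpler, at the cost of a mild information
leak across folds, which matters little for the selection ranking but is
worth remembering when quoting absolute accuracies. Evaluations are
memoised per run by mask bit-string; distinct-evaluation counts are
logged in manifests so optimizer/oracle comparisons can be
budget-matched. One run seed feeds three named substreams
(initialisation, move coefficients, annealing); the CLI derives
`cv_seed` from the same seed. Re-running with one seed reproduces
masks, fitnesses and manifests bit for bit.

## Verification oracles

* `exhaustive_search` scores all `2^d − 1` non-empty masks with the
  identical objective (guard: refuses `d > 15`), breaking ties toward
  fewer features, then the lexicographically smallest mask. On the d=8
  study problem the hybrid reaches this certified optimum in ≥ 16 of 20
  seeded runs (in the shipped study configuration, 20 of 20).
* Closed-form limits are used as operator oracles: `R = 1` (S1) and
  `V = 0` (S2/S3) reproduce the best position exactly; the acceptance
  rate at `Δc = t·ln 2` is 1/2; temperature follows `t0·α^k`.
* Metric computations are cross-checked against an instance-counting
  oracle and a brute-force rank-pair AUC.

## Synthetic data generator

The generator emulates the statistical structure a clinical wrapper
study assumes: labels `Bernoulli(class_balance)` (default 0.3,
minority-positive as in screening cohorts); *informative* features
`N(0,1)` under class 0 and `N(effect_size, 1)` under class 1;
*redundant* features `ρ·source + √(1−ρ²)·N(0,1)` correlated with an
informative source; *noise* features `N(0,1)` independent of the label;
missing entries planted completely at random at `missing_rate` and
imputed through the standard path. Ground-truth roles are retained so a
selected mask can be scored by `recovery_score` (recall of informative
features, selection rate among noise features).

What it does **not** emulate: mixed categorical/boolean clinical
attributes (generated features are all Gaussian), non-Gaussian assay
distributions, informative missingness, label noise, and
measured/not-measured flag structure. Passing recovery tests therefore
show the optimizer finds planted additive-Gaussian signal, not that it
handles every pathology of real clinical tables; the file readers cover
the encoding side separately.

## Study configurations

Chosen once as the package's study design:

* **Oracle equivalence (d = 8)**: n = 300, two informative features at
  effect size 3, class balance 0.3; selection with N = 16, 30 outer
  iterations, 40 SA iterations, 3-fold CV k-NN fitness; 20 runs. With
  only 255 possible masks, memoisation caps the CV cost, so the budget
  is generous rather than minimal.
* **Recovery (d = 20)**: n = 500, five informative features at effect
  size 2; N = 12, 15 outer iterations, 20 SA iterations, `w = 0.9`
  (mild parsimony pressure so accuracy-neutral noise features are
  dropped); 10 runs.
* Distribution checks use 10^4 draws; CV-based tests use 2–3 folds on
  n = 60–500 fixtures.

## Known limitations

* The objective treats CV accuracy as the selection criterion; no
  nested CV, so reported fitnesses are model-selection scores, not
  unbiased generalisation estimates.
* No class-imbalance correction (resampling/weighting) during search.
* Macro averaging is the multiclass default; one-vs-rest ROC curves are
  computed only for binary targets.
* SA perturbs the continuous position only; there are no discrete
  bit-flip moves, so at very small `step` the refinement rarely crosses
  the 0.5 decode threshold.
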