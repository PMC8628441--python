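# Methods

`sepsisrules` implements a rule-discovery-and-analysis pipeline for
in-hospital mortality prediction in sepsis-like ICU cohorts. This note
records the model, the algorithmic and numerical choices, what the synthetic
cohort generator does and does not emulate, and the problem sizes the test
suite runs at.

## The rule model

A *rule* is a conjunction of threshold conditions on named predictors,

    r(x) = prod_j 1{x_j in s_j},    s_j a half-line such as {x <= 100},

mapping a complete patient vector to {0, 1}; a patient with r(x) = 1
*endorses* the rule. The bedside qSOFA pattern (SBP <= 100 mmHg,
RR >= 22 /min, GCS < 15) is exactly such a rule. Thresholds are compared
with exact IEEE `<=`/`<`/`>`/`>=` — no epsilon — because rules are reported
and re-parsed at printed precision.

Given a rule set r = (r_1, ..., r_q), the death probability model is
logistic in the endorsements:

    p(y | x) = 1 / (1 + exp(-y (w' r(x) + b))),    y in {-1, +1},

and rule discovery = choosing the rule set; rule pruning = choosing a
sparse w.

## Rule generation

Candidate rules are read from a bootstrap random forest of shallow
classification trees (Gini splits, `mtry` = ceil(sqrt(p)) features per
split, leaves >= `min_node` = 10 subjects). Every root-to-node path — not
only leaves — contributes a candidate (configurable with `rules_from`).

Three refinements, all on by default and all configurable:

- **Depth mixing** (`depth_mix`). Tree depths cycle 1..`max_depth`
  (default 3) across the ensemble instead of every tree being grown to the
  maximum. Shallow trees contribute short high-support rules, deeper trees
  contribute interactions; this follows the original rule-ensemble
  prescription of varying tree size. No tree ever exceeds `max_depth`.
- **Sub-rule closure** (`subrule_closure`). The candidate pool is closed
  under deleting one condition. Tree paths already provide every *prefix*
  of a path; closure adds the remaining sub-conjunctions, so a true
  2-condition pattern does not have to survive selection with a spurious
  extra split attached.
- **Exact simplification and deduplication.** Each candidate is reduced to
  its minimal equivalent form on the training table (conditions whose
  removal leaves the endorsement vector unchanged are dropped), infeasible
  conjunctions are discarded, and among candidates with identical
  endorsement columns only the one with fewest conditions is kept —
  identical columns are indistinguishable to the penalized fit, which
  would otherwise split their weight arbitrarily.

## Rule pruning

Weights solve the ℓ1-penalized average logistic loss

    min_{w,b}  (1/N) sum_i log(1 + exp(-y_i (w' r(x_i) + b)))  +  lam ||w||_1,

with the intercept unpenalized. The solver is a proximal-Newton scheme:
an IRLS quadratic model of the loss at the current point, minimized over
the active set (nonzero weights plus subgradient violators) by cyclic
coordinate descent with Gram-matrix updates, followed by an
objective-decrease safeguard (step halving). Convergence is declared on
the max-norm subgradient optimality violation (`tol`, default 1e-7); a
solve that cannot reach tolerance raises rather than returning silently.
`lambda_max`, the smallest penalty with an all-zero solution, is computed
in closed form from the gradient at the null model (w = 0,
b = log(N+/N-)), and the automatic grid is geometric over
`[lambda_min_ratio * lambda_max, lambda_max]` with 100 points.

The solver is cross-checked in the tests against an independent convex
solve (split-variable box-constrained L-BFGS-B) to an objective gap below
1e-6.

## Tuning

The tree count and penalty are chosen by stratified k-fold
cross-validation (default 10 folds) on the misclassification rate at the
0.5 probability threshold. Inside each fold the forest is regrown and
rules re-extracted from the training split only, so CV error is honest
about the discovery step, not just the weighting; the lam grid is anchored
at the full-data lambda_max (as in standard penalized-path software) so
fold errors aggregate on a common grid. Selection uses the
one-standard-error rule by default: the largest penalty whose mean CV
error is within one SE of the minimum, at the tree count achieving the
minimum. Ties prefer fewer trees, then a larger penalty. Path solves
inside CV run at a relaxed tolerance (`cv_tol` = 1e-4); classification
error is insensitive at that level, and the final fit runs at `tol`.

Rules with nonzero weight form the fitted ensemble; each carries its
training support and a direction equal to the sign of its weight
(positive = endorsing increases death risk). The direction is an output of
the fit, not an input.

## Rule analysis

Each discovered rule splits the cohort into endorsers and non-endorsers.
Time runs from ICU admission; deaths contribute their event day
(the outcome window opens on day 2), survivors are right-censored at
hospital discharge. Kaplan-Meier estimation and the two-group log-rank
test are delegated to `lifelines`; ties use the standard hypergeometric
variance. The 95% bands use Greenwood's variance on the log-survival
scale, clipped to [0, 1] — the source analyses do not name a CI method,
and the log-scale Greenwood band is a conventional default.

*Decomposition* removes each condition of a rule in turn and re-tests the
revised rule. When the complete rule's p-value is smaller than every
ablation's, the conditions act synergistically: no single condition
carries the rule. *Filtering* retains a rule iff (i) its complete-rule
log-rank p < `alpha_complete` (default 0.001), (ii) its support lies in
`support_range` (default 0.05–0.95), and (iii) optionally every evaluable
ablation p exceeds the complete p. The published workflow this follows
reports such a filter but not its exact thresholds, so all three criteria
are explicit configuration with the stated defaults, and every discarded
rule carries the first criterion it failed.

## Prediction analysis

The prediction model is an unpenalized logistic regression on the binary
endorsement matrix of the retained rules (damped Newton MLE). Constant
columns are dropped; on detected separation (any |coef| > 15 on the
endorsement scale) or non-convergence, the model is refit with a small
ridge penalty (1e-2) and flagged. Discrimination is the mean (SD) test-set
AUC over repeated stratified 70/30 splits, 100 repeats by default, AUC in
Mann-Whitney form on the test split only. One-class test draws are redrawn
and counted.

DeLong's test for correlated AUCs (structural components with midranks) is
computed on one canonical seed-fixed split, because it requires paired
scores on a common test set; the repeat-wise AUC distributions are
reported alongside, surfacing both readings of a "mean AUC plus one
DeLong p" protocol. Calibration uses equal-width probability bins
(default 10) with per-bin mean prediction, observed event rate, and count;
empty bins are omitted. qSOFA (one point each for SBP <= 100, RR >= 22,
GCS < 15) is the one clinical score implemented.

## Synthetic cohorts

Real sepsis cohorts for this task sit behind credentialed access, so the
package ships a generator with known ground truth:

- **Predictors.** Truncated Gaussian marginals per predictor; defaults are
  the pooled mean/SD of worst-within-24h measurements in a published-style
  sepsis ICU population of 2021 patients (675 deaths), with physiologic
  truncation bounds. Correlation, when supplied, enters through a Gaussian
  copula, which preserves the marginals; the default is independence
  because joint moments are not reported for such tables.
- **Outcome.** Death is Bernoulli with log-odds
  `intercept + sum_k w_k r_k(x)` over *planted rules* — conjunctions with
  known weights — rather than linear effects, so discovery-recovery
  experiments have exact ground truth and `bayes_auc` (the AUC of the true
  risk score, estimated by Monte Carlo) is a ceiling for any fitted model.
  The default intercept -0.69 reproduces the 675/2021 (33.4%) prevalence
  when no rules are planted.
- **Times.** Discharge day is lognormal moment-matched to a survivor
  length-of-stay of 11.9 (SD 10.7) days; death day is
  `2 + (Geometric(1/6) - 1)` capped at discharge, so every death occurs on
  or after day 2 and the mean death day is near the non-survivor
  length-of-stay of 8 days. These shapes make KM curves qualitatively
  comparable to real sepsis cohorts without claiming fidelity.
- **Missingness** is MCAR only, applied cell-wise to predictors and never
  to outcomes.

What passing tests on these cohorts do *not* show: robustness to
informative missingness, to realistic predictor dependence, to
measurement error in worst-value extraction, or to cohort-selection
effects — none of which the generator emulates.

## Preprocessing

Worst-value-within-24h extraction keeps, per patient and variable, the
minimum (GCS, MAP, arterial pH, albumin, platelets, hematocrit), the
maximum (heart rate, respiratory rate, creatinine, bilirubin, WBC,
temperature), or the value farthest outside a reference interval
(potassium 3.7–5.1, sodium 135–145), falling back to the largest deviation
from the interval midpoint when all values are in range. The direction map
is configurable per variable; it encodes the usual clinical reading of
these measurements and is a package decision, not a reported fact.

kNN imputation (default k = 5) replaces each missing cell by the mean of
that column over the k nearest rows, with Euclidean distance on the
z-scored columns the two rows share; only rows observing the target column
donate, and distance ties break by row order after a stable sort. Z-scoring
removes unit dominance across variables with wildly different scales.

## Numerical and degenerate-input conventions

- Rules evaluate only on complete inputs; a missing referenced value is an
  error, never silently 0.
- A rule endorsed by everyone or no one cannot be survival-screened; in
  decomposition such an ablation is reported "not evaluable" rather than
  failing the run, and in filtering the rule is discarded for support.
- `delong_test` of a score vector against itself (or any monotone
  transform) returns difference 0 and p = 1 exactly.
- Stage seeds derive from the master seed and the stage name (CRC32 mix),
  so changing evaluation settings never perturbs discovery.

## Problem sizes in the test suite

The statistical validation suite runs at deliberately modest sizes chosen
to keep the full suite in the ten-minute range on one CPU while leaving
each check adequately powered: sparse-logistic oracle instances at N = 20;
log-rank permutation fixtures at n = 60 with 20 000 draws; DeLong
bootstrap fixtures at n = 100 with 20 000 reps; planted-rule recovery on
20 cohorts of n = 2000 with a single 100-tree grid point, a 30-value
penalty grid and 5-fold CV; null-control discovery on five n = 1000
cohorts; the log-rank type-I simulation at 1000 replicates of n = 100; and
the synergy-decomposition simulation at 100 replicates of n = 500. The
log-rank permutation comparison allows 3 Monte-Carlo SEs plus 0.01
absolute, the extra term covering the O(1/n) chi-square approximation
error of the asymptotic test at n = 60 (the same allowance is applied to
the DeLong/bootstrap comparison).

## Known limitations

- Rule discovery is data-dependent: on real cohorts the discovered set,
  its size, and downstream AUCs will differ from any synthetic run.
- The candidate pool is limited to conjunctions over axis-aligned
  thresholds reachable by the forest; disjunctions and categorical set
  conditions are out of scope.
- The CV misclassification criterion at threshold 0.5 can be insensitive
  at extreme prevalence; prevalence in the intended cohorts is ~1/3.
- The permutation and bootstrap oracles in the tests are validation
  devices, not exposed APIs.
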