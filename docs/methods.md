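# Methods

This note records the modelling assumptions, numerical choices and open
design decisions behind `intervalscore`, in the order the pipeline runs.

## Binning

Continuous variables are cut at empirical quantiles (linear
interpolation) into the largest number of equal-count intervals that is
≤ `max_bins` (default 10) and leaves at least five training points in
every interval; the interval count is decremented until the occupancy
rule holds. Intervals are half-open `[τ_{k−1}, τ_k)` with the extremes
open-ended, so any real value falls in exactly one interval at
prediction time. Ordinal variables follow the same rule with thresholds
rounded to integers; duplicate thresholds from heavy ties are collapsed
(an empty interval is unlearnable). Binary variables are catalogued by
their two values sorted ascending, categorical variables by first
appearance in the training data. Unseen categorical levels at prediction
time score zero points and raise a warning.

Interactions reuse the marginal thresholds of their two variables and
are vectorized column-major (`vec index = k + l·n1`), recorded in the
expanded data's column map.

## Difference structure

The total-variation matrix **D** holds one ±1 row per adjacent interval
pair: `m−1` rows for an `m`-interval main effect, `k(l−1) + l(k−1)` rows
for a `k×l` interaction grid (both directions), and one row for a binary
effect. Categorical levels have no natural adjacency; we connect each
level to the first-catalogued (reference) level — a star — so the
penalty still ties the effect together. This is a convention, not a
derived fact, and `build_difference_structure` is the single place to
change it. For main-effects-only schemes the square per-variable
first-difference operator `D_full` and its inverse `R` (block lower
triangular of ones) link the two encodings: `w̃ = Rŵ` and
`Z̃w̃ = Ẑŵ` exactly.

## LP engine

The ℓ1 penalty is linearized with one auxiliary variable per difference
row and the LP is solved with HiGHS through `scipy.optimize.linprog`
(default tolerances, sparse constraint matrix). The offset `b` is
unpenalized. The LP is always feasible (slack absorbs everything). The
trade-off γ has no canonical value; the default grid {0.1, 1, 10, 100}
is resolved by stratified-CV AUC of the unreweighted fit before any
reweighting, ties to the smaller γ. LP optima can be non-unique, so
tests compare objectives, never coefficient vectors.

Reweighting uses χ̃ᵢᵢ = 1/(ϵ₁ + a|(Dw̃)ᵢ|) with ϵ₁ = 5·10⁻⁴, stopping
when the mean absolute coefficient change drops below ϵ₂ = 10⁻⁸ or
after 10 iterations.

## Elastic-net engine

The budget-constrained problem is solved through its Lagrangian form —
a standard elastic net handled by scikit-learn's coordinate descent —
with a bisection on the ℓ1 penalty to meet the budget `t`; the fixed
ridge 0.05 makes the objective strictly convex, so `‖ŵ(λ)‖₁` is
continuous and monotone and the bisection is well posed. When the
unconstrained ridge solution (closed form, unpenalized intercept)
already satisfies the budget, it is returned directly. The default
budget is chosen by sweeping the penalized path (15 log-spaced
penalties) under CV and converting the winner to the budget it achieves
on the full data — equivalent to a budget grid but without a bisection
per grid point. An explicit `t_grid` overrides this.

Reweighting multiplies the columns of Ẑ by χ̂ᵢᵢ = a|ŵᵢ| (no additive
floor, exactly as the update is defined), solves on the rescaled data
and maps back by ŵ ← χ̂v; a coefficient at zero therefore removes its
column permanently (zero-trap). Cap: 25 iterations, same ϵ₂. The
cumulative encoding needs an order, so categorical variables use their
catalogued level order under this engine — a convention to keep them
usable; interactions are rejected (the interval-domain problem would
become a generalized elastic net).

## Tuning and pruning

The reweighting value `a` (sentinel −1 = none) is cross-validated on a
fixed stratified split (default 10 folds, seeded; folds are redrawn up
to five times if a fold ends up single-class). Per grid point and fold
the model is fit, reweighted, centered, rounded and calibrated, and we
record held-out AUC, calibration slope/bias, and the variable/interval
counts. The automatic choice is the fewest-interval candidate whose CV
AUC reaches `cutoff × max CV AUC` (default cutoff 0.80); ties go to the
larger `a`, then to the slope closest to 1. The curve can be printed
and the choice overridden (`choose_weight` / `--choose-weight`), which
is the non-interactive counterpart of a tuning slider.

Under a difference penalty an effect whose interval weights are all
*equal* (not necessarily zero) carries no information — the constant is
an unidentifiable gauge. Each effect's weights are therefore centered
to minimum 0 (the shift is absorbed by the later recalibration) and the
effect is pruned when the centered weights are all below `1e-6` relative
tolerance. The fit-prune loop repeats until the effect set is stable;
it terminates because the count strictly decreases. In automatic mode
the `a` chosen in the first tuning pass is reused across loop passes:
re-running the full CV grid each pass multiplies cost without changing
the trade-off already fixed, and in interactive use would re-prompt the
user mid-loop. Thresholds are computed once on the full training data
and shared across CV folds (fold-specific binning would change the
design dimension per fold); fold metrics are therefore slightly
optimistic about the binning step itself.

## Rounding, merging, risk profile

Integer points are `s = round(m·w̃)` for a multiplier `m` searched over
50 log-spaced values spanning largest-point magnitudes of roughly 0.5 to
10; the smallest `m` whose rounded training AUC keeps ≥ 90% of the
unrounded AUC (with every |point| ≤ 10) wins, falling back to the
AUC-maximizing candidate. Adjacent equal-point intervals of
continuous/ordinal effects are merged and their thresholds removed —
this cannot change any observation's total score. Effects rounding to
all zeros are dropped. The offset is not rounded; the final logistic
recalibration (scikit-learn, ridge 1/(2·10³) on the slope, unpenalized
intercept, finite under separation) re-estimates the score→risk map and
tabulates it for every achievable total score (the contiguous range
between the per-effect minima and maxima summed), so prediction is a
pure table lookup.

## Assessment

AUC is the Mann–Whitney probability of concordance with half credit for
ties (scikit-learn's implementation; the test suite cross-checks an
O(n²) pairwise count). Accuracy is evaluated at the risk-0.5 operating
point. The calibration curve groups observations by distinct predicted
risk, takes each group's positive fraction as empirical risk, and fits
a size-weighted least-squares line; group-count weights are used (not
inverse variance — a stated choice). The calibration error
`e = ∫₀¹ |(slope−1)p + bias| dp` is evaluated in closed form by
splitting the affine integrand at its root when it crosses zero inside
the unit interval.

## Synthetic generator

`GenerativeTruth` draws independent variables (uniform for continuous,
so quantile thresholds land predictably) and labels from a Bernoulli
through the logistic link of a known piecewise-constant score, making
every pipeline stage testable against ground truth and providing a
Bayes-reference AUC (Monte-Carlo AUC of the true score) as the recovery
ceiling. The standard recovery fixture uses a dominant marker (±1.5
log-odds at 0.5, odds ratio ≈ 20) plus a moderate two-step adjunct
(±0.6) and three noise variables — the typical scorecard regime of one
decisive predictor refined by secondary ones. What the generator does
*not* emulate: correlated predictors, non-uniform marginals, label
noise beyond the logistic link, missing values, or distribution shift;
passing recovery tests therefore demonstrates correctness of the
machinery, not robustness on messy clinical data.

## Known limitations

* The automatic cutoff rule compares raw CV AUC against a fraction of
  the best CV AUC; since AUC is floored at 0.5, a single-split model of
  a dominant variable is almost always admissible and, being sparsest,
  is selected. On the standard recovery fixture this collapses the
  model to the dominant split (mean held-out AUC ≈ 0.79 against a
  Bayes ceiling ≈ 0.85, of which ≈ 0.04 is the inherent ceiling of a
  one-split model and the rest threshold quantization at decile
  granularity). Semi-automatic use — inspecting the tuning curve and
  picking a smaller `a` — recovers the richer model; the automatic rule
  is deliberately left as specified rather than patched.
* Problem sizes: the acceptance experiments use n = 600 training rows,
  10 seeds, ≤ 12-column LP oracle instances — sizes chosen so the whole
  suite re-runs in minutes on one CPU while leaving the conclusions
  unchanged at larger n.
* LP solutions are vertex solutions and may be non-unique; downstream
  logic depends only on objectives and on the pruning/rounding of the
  returned optimum.
* Missing values are not handled (records should be complete); no
  >2-way interactions; no confidence intervals on AUC.
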