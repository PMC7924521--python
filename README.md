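# intervalscore

Clinical-style scoring systems — a handful of variables, each cut into
value intervals that earn integer points, the summed points mapped to a
risk — are prized for being usable at the bedside and auditable by
experts, but they are usually hand-crafted rules of thumb.
`intervalscore` learns such interval-coded scorecards directly from
labelled tabular data with sparse convex optimization, for anyone (e.g.
biostatisticians, epidemiologists, ML practitioners who need auditable
models) who wants a data-driven scoring system rather than a black box.

## The model

Given data **X** ∈ ℝ^(N×N_d) and labels **y** ∈ {−1, +1}^N, every
variable is split into intervals by thresholds τ placed at equal-count
training quantiles (≥5 points per interval, at most `max_bins` intervals;
ordinal thresholds are integers, binary/categorical variables get one
interval per level; two-way interactions use the marginal interval grid).
The one-hot expansion **Z̃** of this binning carries one weight per
interval, and two convex engines fit those weights:

* **LP engine** — a soft-margin classifier with a total-variation penalty,

      min ‖χ̃ D w̃‖₁ + γ εᵀ1   s.t.  Y(Z̃w̃ + b) ≥ 1 − ε,  ε ≥ 0,

  where **D** differences the weights of adjacent intervals (both grid
  directions for interactions), so the optimum is piecewise constant
  across intervals. Solved as a linear program (HiGHS).

* **Elastic-net engine** — on the cumulative encoding **Ẑ** (a value
  activates its interval and all preceding ones; main effects only),
  coefficients ŵ live in the difference domain and a plain ℓ1 budget
  plays the total-variation role:

      min ‖Ẑŵ + b − y‖₂² + 0.05‖ŵ‖₂²   s.t.  ‖ŵ‖₁ ≤ t.

  Interval weights are recovered as w̃ = Rŵ with R the block
  cumulative-sum matrix.

**Iterative reweighting** (the complexity dial): re-solve with weights
derived from the current solution — χ̃ᵢᵢ = 1/(ϵ₁ + a|(Dw̃)ᵢ|) on the LP
penalty rows (≤10 iterations), or column scalings χ̂ᵢᵢ = a|ŵᵢ| on Ẑ for
the elastic net (≤25 iterations) — driving small differences to exact
zero. The value *a* is chosen from a grid by stratified cross-validation:
the candidate with the fewest intervals among those whose CV AUC reaches
a cutoff fraction (default 0.80) of the best CV AUC, with variables whose
interval profile collapses to a constant pruned and the fit repeated
until stable. Optional preselection screens effects first (linear-SVM
trend scores per effect, then a sparse elastic net over them). Finally
the surviving weights are scaled, rounded to integer points (merging
adjacent equal-point intervals) and a lightly regularized logistic
regression maps each achievable total score to a risk.

## Worked example

```python
import intervalscore as ics

truth = ics.recovery_truth()            # 2 informative + 3 noise variables
X, y, _ = ics.make_piecewise_dataset(truth, 600, seed=1234)
problem = ics.ICSProblem(
    X_train=X, y_train=y, var_types=["continuous"] * 5,
    var_names=["marker_a", "marker_b", "noise_1", "noise_2", "noise_3"],
    method="lp", options=ics.Options(seed=0),
)
model = ics.run_ics(problem)
print(ics.render_scorecard(model, format="txt"))
print(ics.assess(model, X, y, split="train").summary())
```

prints

```
=== Interval coded scorecard ===
marker_a:  < 0.4984: +0 | >= 0.4984: +1
--- risk profile ---
score +0: risk 20.3%
score +1: risk 84.3%
target class: label 1 (vs -1)
[train] AUC       0.821
[train] accuracy  0.820
[train] slope     1.000
[train] bias      0.000
[train] cal.err   0.0001
[train] intervals 2  variables 1
```

All three noise variables were discarded; the dominant marker kept one
threshold (its true split is at 0.5), a patient above it scores +1, and
the risk profile translates the total into a probability of the target
class (20% below the split, 84% above). AUC/accuracy summarize
discrimination; calibration slope ≈ 1 and bias ≈ 0 mean the predicted
risks match observed frequencies, and `cal.err` is the integrated
absolute gap to the ideal calibration line. See `examples/` for engine
comparison and held-out assessment, and the CLI for file-based use:

```bash
ics fit --data train.csv --label-col outcome --config config.yaml --out model.json
ics predict --model model.json --data new.csv --out scored.csv
ics assess --model model.json --data test.csv --label-col outcome
ics render --model model.json --format svg --out scorecard.svg
```

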