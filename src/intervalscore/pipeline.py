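"""End-to-end scorecard construction.

The flow mirrors the general interval-coded-scoring recipe:

1. bin every variable (``build_scheme``);
2. expand the data (one-hot for the LP engine, cumulative for the
   elastic-net engine) and build the difference structure;
3. fit once without reweighting, pick the engine hyperparameter
   (gamma or the l1 budget t) by cross-validated AUC;
4. cross-validate the reweighting value ``a`` (complexity/performance
   trade-off curve) and choose it automatically via the cutoff rule or
   take the user's choice;
5. reweight, prune effects whose interval weights have collapsed to a
   constant, and repeat until the effect set is stable;
6. scale and round interval weights to integer points, merging adjacent
   intervals with equal points;
7. recalibrate with logistic regression mapping the integer total score
   to a risk, tabulated for every achievable score.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import ElasticNet, LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import LinearSVC

from . import assessment as _assess
from .binning import (
    BinningScheme,
    VariableBinning,
    build_difference_structure,
    build_scheme,
    en_encode,
    lp_encode,
)
from .en_core import ENFit, fit_en, reweight_en
from .lp_core import LPFit, ReweightConfig, fit_lp, reweight_lp
from .problem import ICSProblem, Options, validate_problem

PRUNE_TOL = 1e-6
MAX_ABS_POINTS = 10
ROUND_AUC_FRACTION = 0.9
FORMAT_VERSION = 1


# ---------------------------------------------------------------------------
# score model


@dataclass
class EffectPoints:
    """Integer points of one effect, with its own (possibly merged) bins."""

    name: str
    kind: str  # "main" | "interaction"
    columns: tuple[int, ...]  # 1-based data columns
    margins: list[VariableBinning]
    points: np.ndarray  # 1-d (main) or 2-d (interaction, shape n1 x n2)

    def row_points(self, X: np.ndarray) -> np.ndarray:
        cols = [c - 1 for c in self.columns]
        idx = [m.interval_index(X[:, c]) for m, c in zip(self.margins, cols)]
        if self.kind == "main":
            i = idx[0]
            out = np.where(i >= 0, self.points[np.clip(i, 0, None)], 0)
            if np.any(i < 0):
                warnings.warn(
                    f"unseen level(s) in effect {self.name}: scored 0 points"
                )
            return out.astype(int)
        i1, i2 = idx
        ok = (i1 >= 0) & (i2 >= 0)
        out = np.zeros(X.shape[0], dtype=int)
        out[ok] = self.points[i1[ok], i2[ok]]
        return out

    def to_dict(self) -> dict:
        d = {
            "name": self.name,
            "kind": self.kind,
            "columns": list(self.columns),
            "points": np.asarray(self.points).tolist(),
            "margins": [
                {
                    "var_type": m.var_type,
                    "thresholds": np.asarray(m.thresholds).tolist(),
                    "levels": None if m.levels is None else np.asarray(m.levels).tolist(),
                    "n_intervals": int(m.n_intervals),
                }
                for m in self.margins
            ],
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "EffectPoints":
        margins = [
            VariableBinning(
                var_type=m["var_type"],
                thresholds=np.asarray(m["thresholds"], dtype=float),
                levels=None if m["levels"] is None else np.asarray(m["levels"], dtype=float),
                n_intervals=int(m["n_intervals"]),
            )
            for m in d["margins"]
        ]
        return cls(
            name=d["name"],
            kind=d["kind"],
            columns=tuple(d["columns"]),
            margins=margins,
            points=np.asarray(d["points"], dtype=int),
        )


@dataclass
class ScoreModel:
    """A fitted integer scorecard with its logistic risk profile."""

    method: str
    effects: list[EffectPoints]
    b0: float
    b1: float
    risk_table: dict[int, float]
    label_map: dict
    provenance: dict = field(default_factory=dict)

    @property
    def n_variables(self) -> int:
        return len({c for e in self.effects for c in e.columns})

    @property
    def n_intervals(self) -> int:
        return sum(int(np.asarray(e.points).size) for e in self.effects)

    def total_score(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        s = np.zeros(X.shape[0], dtype=int)
        for e in self.effects:
            s += e.row_points(X)
        return s

    def risk_of_score(self, scores: np.ndarray) -> np.ndarray:
        return np.array([self.risk_table[int(s)] for s in np.asarray(scores)])

    def apply(self, X: np.ndarray):
        """Per-row (total score, risk, predicted class in original coding)."""
        scores = self.total_score(X)
        risks = self.risk_of_score(scores)
        pred = np.where(
            risks >= 0.5, self.label_map["positive"], self.label_map["negative"]
        )
        return scores, risks, pred

    def map_labels(self, y: np.ndarray) -> np.ndarray:
        y = np.asarray(y, dtype=float).ravel()
        return np.where(y == self.label_map["positive"], 1.0, -1.0)

    def to_dict(self) -> dict:
        return {
            "format_version": FORMAT_VERSION,
            "method": self.method,
            "effects": [e.to_dict() for e in self.effects],
            "offset_policy": "per-effect minimum absorbed before rounding",
            "logistic": {"b0": self.b0, "b1": self.b1},
            "risk_table": {str(k): v for k, v in self.risk_table.items()},
            "label_map": self.label_map,
            "provenance": self.provenance,
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "ScoreModel":
        return cls(
            method=d["method"],
            effects=[EffectPoints.from_dict(e) for e in d["effects"]],
            b0=float(d["logistic"]["b0"]),
            b1=float(d["logistic"]["b1"]),
            risk_table={int(k): float(v) for k, v in d["risk_table"].items()},
            label_map={k: float(v) for k, v in d["label_map"].items()},
            provenance=d.get("provenance", {}),
        )

    @classmethod
    def from_json(cls, source) -> "ScoreModel":
        if hasattr(source, "read"):
            return cls.from_dict(json.load(source))
        text = str(source)
        if text.lstrip().startswith("{"):
            return cls.from_dict(json.loads(text))
        with open(text) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class TuningCurve:
    """Cross-validation summary per reweighting value."""

    grid: list[float]
    auc: list[float]
    cal_slope: list[float]
    cal_bias: list[float]
    n_variables: list[float]
    n_intervals: list[float]
    chosen_index: int
    cutoff: float

    @property
    def chosen_a(self) -> float:
        return self.grid[self.chosen_index]

    def table(self) -> str:
        head = f"{'a':>8} {'AUC':>7} {'slope':>7} {'bias':>7} {'#vars':>6} {'#intv':>6}"
        rows = [head]
        for i, a in enumerate(self.grid):
            mark = "*" if i == self.chosen_index else " "
            rows.append(
                f"{a:>8.3g} {self.auc[i]:>7.3f} {self.cal_slope[i]:>7.3f} "
                f"{self.cal_bias[i]:>7.3f} {self.n_variables[i]:>6.1f} "
                f"{self.n_intervals[i]:>6.1f} {mark}"
            )
        return "\n".join(rows)


@dataclass
class PreselectionState:
    """Intermediate objects of the screening pass."""

    omega: np.ndarray
    X2: np.ndarray
    candidate_groups: list[tuple[int, ...]]
    selected_groups: list[tuple[int, ...]]
    dropped_degenerate: list[tuple[int, ...]] = field(default_factory=list)


# ---------------------------------------------------------------------------
# helpers


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


def _stratified_folds(y: np.ndarray, k: int, seed: int):
    """Stratified fold indices; re-drawn with a new seed (up to 5 tries)
    if any fold ends up single-class."""
    y_bin = (np.asarray(y) > 0).astype(int)
    k = min(k, int(np.bincount(y_bin).min()))
    if k < 2:
        raise ValueError("not enough samples of each class for cross-validation")
    for attempt in range(5):
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed + attempt)
        folds = list(skf.split(np.zeros(len(y_bin)), y_bin))
        ok = all(
            len(np.unique(y_bin[tr])) == 2 and len(np.unique(y_bin[va])) == 2
            for tr, va in folds
        )
        if ok:
            return folds
    raise ValueError("could not draw stratified folds with both classes present")


def _interval_weights(fit, Z, diff) -> np.ndarray:
    """Interval-domain weights: LP fits carry them directly; EN fits are
    mapped back through the block cumulative-sum matrix R."""
    if isinstance(fit, LPFit):
        return fit.w.copy()
    return diff.R @ fit.w_hat


def _center_per_effect(w_tilde: np.ndarray, block_slices) -> tuple[np.ndarray, float]:
    """Shift each effect's weights so its minimum is 0; the shifts are an
    unidentifiable gauge under the difference penalty and are absorbed into
    the offset."""
    w = w_tilde.copy()
    shift = 0.0
    for blk in block_slices:
        if blk.stop > blk.start:
            m = w[blk].min()
            w[blk] -= m
            shift += m
    return w, shift


def _active_effects(w_centered: np.ndarray, block_slices, tol: float = PRUNE_TOL):
    scale = max(1.0, np.abs(w_centered).max() if w_centered.size else 1.0)
    return [
        i
        for i, blk in enumerate(block_slices)
        if np.abs(w_centered[blk]).max() > tol * scale
    ]


# ---------------------------------------------------------------------------
# engines


def _base_fit(method, Z_fit, diff, y, hyper):
    if method == "lp":
        return fit_lp(Z_fit, diff, y, hyper)
    return fit_en(Z_fit, y, hyper)


def _reweighted_fit(method, Z_fit, diff, y, hyper, a, base):
    if a == -1.0:
        return base
    if method == "lp":
        return reweight_lp(Z_fit, diff, y, hyper, ReweightConfig(a=a), base)
    return reweight_en(Z_fit, y, hyper, ReweightConfig(a=a, max_iter=25), base)


def _decision_values(fit, Z_lp, R=None):
    if isinstance(fit, LPFit):
        return Z_lp @ fit.w + fit.b
    return Z_lp @ (R @ fit.w_hat) + fit.b


def select_hyperparameter(
    method: str,
    Z_fit,
    Z_lp: np.ndarray,
    diff,
    y: np.ndarray,
    grid,
    cv_folds: int,
    seed: int,
):
    """Pick gamma (lp) or the l1 budget t (en) by cross-validated AUC of
    the unreweighted fit; ties go to the smaller value (simpler model).

    For the en engine the sweep runs over the penalized path and the
    winning penalty is converted to the budget it achieves on the full
    data, avoiding a bisection per grid point.
    """
    folds = _stratified_folds(y, cv_folds, seed)
    Zf = Z_fit.Z if hasattr(Z_fit, "Z") else Z_fit

    if method == "lp":
        mean_auc = []
        for gamma in grid:
            aucs = []
            for tr, va in folds:
                f = fit_lp(Zf[tr], diff, y[tr], gamma)
                dec = Z_lp[va] @ f.w + f.b
                _, auc = _assess.roc_auc(dec, y[va])
                aucs.append(auc)
            mean_auc.append(np.mean(aucs))
        best = int(np.argmax(mean_auc))
        return float(grid[best]), {"grid": list(grid), "cv_auc": mean_auc}

    # en: sweep the penalized path (or an explicit budget grid when given)
    from .en_core import _penalized_fit, _ridge_solution, RIDGE_EPS

    R = diff.R
    if grid is not None:
        mean_auc = []
        for t in grid:
            aucs = []
            for tr, va in folds:
                f = fit_en(Zf[tr], y[tr], t)
                dec = Z_lp[va] @ (R @ f.w_hat) + f.b
                try:
                    _, auc = _assess.roc_auc(dec, y[va])
                except ValueError:
                    auc = 0.5
                aucs.append(auc)
            mean_auc.append(np.mean(aucs))
        best = int(np.argmax(mean_auc))
        return float(grid[best]), {"grid": list(grid), "cv_auc": mean_auc}

    lam_hi = max(1.0, 4.0 * np.abs(Zf.T @ (y - y.mean())).max())
    lams = np.geomspace(lam_hi, lam_hi * 1e-4, 15)
    mean_auc = []
    for lam in lams:
        aucs = []
        for tr, va in folds:
            w, b = _penalized_fit(Zf[tr], y[tr], lam, RIDGE_EPS)
            dec = Z_lp[va] @ (R @ w) + b
            try:
                _, auc = _assess.roc_auc(dec, y[va])
            except ValueError:
                auc = 0.5
            aucs.append(auc)
        mean_auc.append(np.mean(aucs))
    best = int(np.argmax(mean_auc))
    w_full, _ = _penalized_fit(Zf, y, lams[best], RIDGE_EPS)
    t = float(np.abs(w_full).sum())
    if t == 0.0:
        w_r, _ = _ridge_solution(Zf, y, RIDGE_EPS)
        t = 0.01 * float(np.abs(w_r).sum())
    return t, {"grid": [float(l) for l in lams], "cv_auc": mean_auc}


# ---------------------------------------------------------------------------
# rounding / merging


def scale_and_round(
    w_tilde: np.ndarray,
    expanded,
    y: np.ndarray,
    max_abs_points: int = MAX_ABS_POINTS,
    auc_fraction: float = ROUND_AUC_FRACTION,
):
    """Convert interval weights to integer points.

    The multiplier m is searched over 50 log-spaced values chosen so the
    largest resulting point magnitude spans roughly 0.5 to ``max_abs_points``;
    the smallest m whose rounded scores keep at least ``auc_fraction`` of
    the unrounded training AUC (with every |point| <= ``max_abs_points``)
    wins, falling back to the AUC-maximizing m.

    Returns ``(s, chosen_m)`` with s integer, aligned with the expanded
    (one-hot) columns.  Weights are assumed centered per effect.
    """
    Z = expanded.Z
    maxabs = float(np.abs(w_tilde).max())
    if maxabs <= 0:
        return np.zeros_like(w_tilde, dtype=int), 1.0
    try:
        _, auc_ref = _assess.roc_auc(Z @ w_tilde, y)
    except ValueError:
        auc_ref = 0.5
    grid = np.geomspace(0.5 / maxabs, max_abs_points / maxabs, 50)
    best_m, best_auc = None, -np.inf
    for m in grid:
        s = np.round(m * w_tilde)
        if np.abs(s).max() > max_abs_points or np.abs(s).max() == 0:
            continue
        try:
            _, auc = _assess.roc_auc(Z @ s, y)
        except ValueError:
            auc = 0.5
        if auc > best_auc:
            best_m, best_auc = m, auc
        if auc >= auc_fraction * auc_ref:
            return s.astype(int), float(m)
    if best_m is None:
        return np.zeros_like(w_tilde, dtype=int), 1.0
    return np.round(best_m * w_tilde).astype(int), float(best_m)


def _merge_effect(vb: VariableBinning, points: np.ndarray):
    """Join adjacent equal-point intervals of continuous/ordinal effects,
    removing the thresholds between them."""
    if vb.var_type not in ("continuous", "ordinal") or len(points) < 2:
        return vb, np.asarray(points, dtype=int)
    keep_pts = [int(points[0])]
    keep_tau = []
    for k in range(1, len(points)):
        if int(points[k]) != keep_pts[-1]:
            keep_pts.append(int(points[k]))
            keep_tau.append(vb.thresholds[k - 1])
    merged = VariableBinning(
        var_type=vb.var_type,
        thresholds=np.asarray(keep_tau, dtype=float),
        levels=None,
        n_intervals=len(keep_pts),
    )
    return merged, np.asarray(keep_pts, dtype=int)


def build_effect_points(
    scheme: BinningScheme,
    s: np.ndarray,
    block_slices,
    var_names: list[str],
) -> list[EffectPoints]:
    """Package rounded points per effect, merging equal-point neighbours
    and dropping all-zero effects."""
    out = []
    for e_idx, effect in enumerate(scheme.effects):
        pts = s[block_slices[e_idx]]
        if np.all(pts == 0):
            continue
        if len(effect) == 1:
            vb = scheme.variables[effect[0]]
            vb2, pts2 = _merge_effect(vb, pts)
            out.append(
                EffectPoints(
                    name=var_names[effect[0]],
                    kind="main",
                    columns=(effect[0] + 1,),
                    margins=[vb2],
                    points=pts2,
                )
            )
        else:
            vb1 = scheme.variables[effect[0]]
            vb2 = scheme.variables[effect[1]]
            grid = pts.reshape((vb1.n_intervals, vb2.n_intervals), order="F")
            out.append(
                EffectPoints(
                    name=f"{var_names[effect[0]]} x {var_names[effect[1]]}",
                    kind="interaction",
                    columns=(effect[0] + 1, effect[1] + 1),
                    margins=[vb1, vb2],
                    points=grid.astype(int),
                )
            )
    return out


# ---------------------------------------------------------------------------
# risk calibration


def calibrate_risk(total_scores: np.ndarray, y: np.ndarray, score_range=None):
    """Logistic regression of class on total score, lightly ridge-penalized
    on the slope (unpenalized intercept) so separation stays finite.

    Returns ``(b0, b1, risk_table)``; the table covers every achievable
    total score (contiguous range) when ``score_range`` is given, else the
    observed range.
    """
    scores = np.asarray(total_scores, dtype=float).ravel()
    y01 = (np.asarray(y, dtype=float).ravel() > 0).astype(int)
    prevalence = y01.mean()
    if score_range is None:
        score_range = (int(scores.min()), int(scores.max()))
    lo, hi = score_range
    if len(np.unique(scores)) < 2 or len(np.unique(y01)) < 2:
        warnings.warn("degenerate score/label distribution: prevalence-only risk")
        p = min(max(prevalence, 1e-12), 1 - 1e-12)
        b0 = float(np.log(p / (1 - p)))
        table = {s: prevalence for s in range(lo, hi + 1)}
        return b0, 0.0, table
    lr = LogisticRegression(C=1000.0, solver="lbfgs", max_iter=10_000)
    lr.fit(scores[:, None], y01)
    b0 = float(lr.intercept_[0])
    b1 = float(lr.coef_[0, 0])
    table = {s: float(_sigmoid(b0 + b1 * s)) for s in range(lo, hi + 1)}
    return b0, b1, table


# ---------------------------------------------------------------------------
# preselection


def preselect(problem: ICSProblem) -> PreselectionState:
    """Four-step screening: (1) linear SVM on the one-hot expansion, (2)
    per-effect trend columns Z^p omega^p, (3) elastic-net path on the trend
    matrix with cross-validated AUC, (4) keep effects with nonzero
    coefficients at the sparsest acceptable penalty."""
    problem = validate_problem(problem)
    opts = problem.options
    groups0 = [tuple(i - 1 for i in g) for g in problem.groups]
    scheme = build_scheme(problem.X_train, problem.var_types, groups0, opts.max_bins)
    expanded = lp_encode(problem.X_train, scheme)
    y = problem.y_train

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        svm = LinearSVC(C=1.0, loss="hinge", max_iter=100_000, tol=1e-6)
        svm.fit(expanded.Z, y)
    omega = svm.coef_.ravel()

    cols, kept_groups, dropped = [], [], []
    for e_idx, blk in enumerate(expanded.block_slices):
        col = expanded.Z[:, blk] @ omega[blk]
        if np.allclose(col, 0.0):
            dropped.append(problem.groups[e_idx])
            continue
        cols.append(col)
        kept_groups.append(problem.groups[e_idx])
    if not cols:
        return PreselectionState(omega, np.zeros((problem.n_obs, 0)),
                                 problem.groups, problem.groups, dropped)
    X2 = np.column_stack(cols)

    folds = _stratified_folds(y, opts.cv_folds, opts.seed)
    lam_hi = max(1.0, 4.0 * np.abs(X2.T @ (y - y.mean())).max())
    lams = np.geomspace(lam_hi, lam_hi * 1e-4, 20)
    n = X2.shape[0]
    results = []
    for lam in lams:
        aucs = []
        for tr, va in folds:
            en = ElasticNet(
                alpha=lam / n, l1_ratio=0.5, fit_intercept=True,
                max_iter=50_000, tol=1e-8,
            )
            en.fit(X2[tr], y[tr])
            dec = en.predict(X2[va])
            try:
                _, auc = _assess.roc_auc(dec, y[va])
            except ValueError:
                auc = 0.5
            aucs.append(auc)
        en_full = ElasticNet(
            alpha=lam / n, l1_ratio=0.5, fit_intercept=True,
            max_iter=50_000, tol=1e-8,
        )
        en_full.fit(X2, y)
        nnz = int(np.sum(np.abs(en_full.coef_) > 1e-10))
        results.append((float(np.mean(aucs)), nnz, en_full.coef_.copy()))

    max_auc = max(r[0] for r in results)
    admissible = [r for r in results if r[0] >= opts.cutoff[0] * max_auc and r[1] > 0]
    if not admissible:
        admissible = [max(results, key=lambda r: r[0])]
    best = min(admissible, key=lambda r: (r[1], -r[0]))
    selected = [g for g, c in zip(kept_groups, best[2]) if abs(c) > 1e-10]
    if not selected:
        selected = kept_groups
    return PreselectionState(omega, X2, problem.groups, selected, dropped)


# ---------------------------------------------------------------------------
# reweighting-value tuning


def tune_weight(
    problem: ICSProblem,
    hyper: float | None = None,
    grid=None,
    cutoff: float | None = None,
    groups: list[tuple[int, ...]] | None = None,
) -> TuningCurve:
    """Cross-validate the reweighting value ``a`` over its grid.

    Per grid point and fold: base fit, reweight, center/prune, round to
    integer points, calibrate, then measure AUC and calibration slope/bias
    on the held-out fold plus the model's variable and interval counts.
    The automatic choice is the candidate with the fewest intervals among
    those whose CV AUC reaches ``cutoff`` times the best CV AUC; ties go
    to the larger ``a``, then to the slope closest to 1.
    """
    problem = validate_problem(problem)
    opts = problem.options
    grid = list(grid if grid is not None else opts.weight_grid)
    cutoff = float(cutoff if cutoff is not None else opts.cutoff[1])
    groups1 = groups if groups is not None else problem.groups
    groups0 = [tuple(i - 1 for i in g) for g in groups1]
    X, y = problem.X_train, problem.y_train
    scheme = build_scheme(X, problem.var_types, groups0, opts.max_bins)
    Z_lp = lp_encode(X, scheme)
    Z_fit = Z_lp if problem.method == "lp" else en_encode(X, scheme)
    diff = build_difference_structure(scheme, problem.method)
    if hyper is None:
        hyper, _ = select_hyperparameter(
            problem.method, Z_fit, Z_lp.Z, diff, y,
            opts.gamma_grid if problem.method == "lp" else opts.t_grid,
            opts.cv_folds, opts.seed,
        )

    folds = _stratified_folds(y, opts.cv_folds, opts.seed)
    # base (a = -1) fit per fold, shared across the grid
    base_fits = []
    for tr, va in folds:
        Zf = Z_fit.Z[tr]
        base_fits.append(_base_fit(problem.method, Zf, diff, y[tr], hyper))

    auc_g, slope_g, bias_g, nvar_g, nint_g = [], [], [], [], []
    for a in grid:
        aucs, slopes, biases, nvars, nints = [], [], [], [], []
        for (tr, va), base in zip(folds, base_fits):
            fit = _reweighted_fit(
                problem.method, Z_fit.Z[tr], diff, y[tr], hyper, a, base
            )
            w_tilde = _interval_weights(fit, None, diff)
            w_c, _ = _center_per_effect(w_tilde, Z_lp.block_slices)
            Z_tr = lp_encode(X[tr], scheme)
            s, _ = scale_and_round(w_c, Z_tr, y[tr])
            effects = build_effect_points(scheme, s, Z_lp.block_slices, problem.var_names)
            nvars.append(len({c for e in effects for c in e.columns}))
            nints.append(sum(np.asarray(e.points).size for e in effects))
            scores_tr = Z_tr.Z @ s
            lo, hi_ = _achievable_range(s, Z_lp.block_slices)
            b0, b1, table = calibrate_risk(scores_tr, y[tr], (lo, hi_))
            scores_va = (Z_lp.Z[va] @ s).astype(int)
            risks_va = np.array([table[int(v)] for v in scores_va])
            try:
                _, auc = _assess.roc_auc(scores_va.astype(float), y[va])
            except ValueError:
                auc = np.nan
            aucs.append(auc)
            try:
                a_cal, b_cal = _assess.calibration_curve(risks_va, y[va])
            except ValueError:
                a_cal, b_cal = np.nan, np.nan
            slopes.append(a_cal)
            biases.append(b_cal)
        auc_g.append(float(np.nanmean(aucs)))
        slope_g.append(float(np.nanmean(slopes)))
        bias_g.append(float(np.nanmean(biases)))
        nvar_g.append(float(np.mean(nvars)))
        nint_g.append(float(np.mean(nints)))

    max_auc = np.nanmax(auc_g)
    admissible = [i for i in range(len(grid)) if auc_g[i] >= cutoff * max_auc]
    if not admissible:
        admissible = [int(np.nanargmax(auc_g))]

    def _key(i):
        slope_pen = abs(slope_g[i] - 1.0) if np.isfinite(slope_g[i]) else np.inf
        return (nint_g[i], -grid[i], slope_pen)

    chosen = min(admissible, key=_key)
    return TuningCurve(
        grid=grid, auc=auc_g, cal_slope=slope_g, cal_bias=bias_g,
        n_variables=nvar_g, n_intervals=nint_g,
        chosen_index=chosen, cutoff=cutoff,
    )


def _achievable_range(s: np.ndarray, block_slices):
    lo = hi = 0
    for blk in block_slices:
        if blk.stop > blk.start:
            lo += int(s[blk].min())
            hi += int(s[blk].max())
    return lo, hi


# ---------------------------------------------------------------------------
# main driver


def run_ics(problem: ICSProblem, choose_weight: float | None = None) -> ScoreModel:
    """Build a scorecard from a problem description.

    ``choose_weight`` overrides the automatic cutoff rule with a specific
    reweighting value (the non-interactive counterpart of the tuning
    slider); ``None`` with ``options.auto`` unset also falls back to the
    automatic rule, after printing the tuning curve.
    """
    problem = validate_problem(problem)
    opts = problem.options
    X, y = problem.X_train, problem.y_train
    provenance: dict = {"seed": opts.seed, "method": problem.method}

    groups1 = problem.groups
    if opts.preselect:
        state = preselect(problem)
        groups1 = state.selected_groups
        provenance["preselected_groups"] = [list(g) for g in groups1]

    groups0 = [tuple(i - 1 for i in g) for g in groups1]
    scheme = build_scheme(X, problem.var_types, groups0, opts.max_bins)
    Z_lp = lp_encode(X, scheme)
    Z_fit = Z_lp if problem.method == "lp" else en_encode(X, scheme)
    diff = build_difference_structure(scheme, problem.method)

    if Z_lp.Z.shape[1] == 0 or all(
        scheme.variables[p].n_intervals <= 1 for g in groups0 for p in g
    ):
        warnings.warn("no informative intervals: intercept-only model")
        return _intercept_only(problem, provenance)

    hyper, hyper_info = select_hyperparameter(
        problem.method, Z_fit, Z_lp.Z, diff, y,
        opts.gamma_grid if problem.method == "lp" else opts.t_grid,
        opts.cv_folds, opts.seed,
    )
    provenance["hyperparameter"] = hyper
    provenance["hyperparameter_cv"] = hyper_info

    if choose_weight is not None:
        a = float(choose_weight)
    else:
        curve = tune_weight(problem, hyper=hyper, groups=groups1)
        if opts.show or not opts.auto:
            print(curve.table())
        a = curve.chosen_a
        provenance["tuning_curve"] = {
            "grid": curve.grid, "cv_auc": curve.auc,
            "n_intervals": curve.n_intervals,
        }
    provenance["chosen_a"] = a

    # reweight-and-prune loop; the chosen a is reused across passes
    iteration_log = []
    current_groups0 = list(groups0)
    for _pass in range(max(1, len(groups0))):
        base = _base_fit(problem.method, Z_fit.Z, diff, y, hyper)
        fit = _reweighted_fit(problem.method, Z_fit.Z, diff, y, hyper, a, base)
        w_tilde = _interval_weights(fit, Z_fit, diff)
        w_c, _ = _center_per_effect(w_tilde, Z_lp.block_slices)
        active = _active_effects(w_c, Z_lp.block_slices)
        iteration_log.append(
            {"n_effects": len(current_groups0), "n_active": len(active),
             "fit_iterations": getattr(fit, "n_iterations", 1)}
        )
        if len(active) == len(current_groups0):
            break
        if not active:
            warnings.warn("all effects pruned: intercept-only model")
            provenance["iterations"] = iteration_log
            return _intercept_only(problem, provenance)
        current_groups0 = [current_groups0[i] for i in active]
        scheme = BinningScheme(
            {p: scheme.variables[p] for g in current_groups0 for p in g},
            current_groups0,
        )
        Z_lp = lp_encode(X, scheme)
        Z_fit = Z_lp if problem.method == "lp" else en_encode(X, scheme)
        diff = build_difference_structure(scheme, problem.method)
    provenance["iterations"] = iteration_log

    s, m = scale_and_round(w_c, Z_lp, y)
    provenance["round_multiplier"] = m
    effects = build_effect_points(scheme, s, Z_lp.block_slices, problem.var_names)
    if not effects:
        warnings.warn("all points rounded to zero: intercept-only model")
        return _intercept_only(problem, provenance)

    scores = Z_lp.Z @ s
    lo, hi = _achievable_range(s, Z_lp.block_slices)
    b0, b1, table = calibrate_risk(scores, y, (lo, hi))
    return ScoreModel(
        method=problem.method,
        effects=effects,
        b0=b0,
        b1=b1,
        risk_table=table,
        label_map=problem.label_map,
        provenance=provenance,
    )


def _intercept_only(problem: ICSProblem, provenance: dict) -> ScoreModel:
    y01 = (problem.y_train > 0).astype(float)
    prevalence = float(y01.mean())
    p = min(max(prevalence, 1e-12), 1 - 1e-12)
    return ScoreModel(
        method=problem.method,
        effects=[],
        b0=float(np.log(p / (1 - p))),
        b1=0.0,
        risk_table={0: prevalence},
        label_map=problem.label_map,
        provenance=provenance,
    )
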