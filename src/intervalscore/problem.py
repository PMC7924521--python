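"""Problem description and validation for interval coded scoring.

An :class:`ICSProblem` bundles the training (and optional test) data with the
per-column variable types, the effects to consider (main effects and two-way
interactions), the core method (``lp`` or ``en``) and tuning options.  Only
the training data and labels are mandatory; everything else has defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

VAR_TYPES = ("binary", "categorical", "ordinal", "continuous")


class ProblemError(ValueError):
    """Raised when a problem description is inconsistent."""


@dataclass
class Options:
    """Tuning options.

    Parameters
    ----------
    max_bins:
        Upper bound on the number of intervals per continuous/ordinal
        variable (each interval must still hold at least five training
        points).
    preselect:
        Run the SVM-trend / elastic-net screening pass before the main fit.
    auto:
        Pick the reweighting value automatically from the cross-validation
        curve instead of asking the user.
    cutoff:
        Pair of fractions in (0, 1]: the tolerated AUC loss relative to the
        best cross-validated AUC for (preselection, reweighting).  The
        sparsest candidate within the cutoff is selected.
    weight_grid:
        Candidate reweighting values ``a``; the sentinel ``-1`` means "no
        reweighting" and must be present.
    gamma_grid:
        Candidate slack trade-offs for the LP method.
    t_grid:
        Candidate l1 budgets for the elastic-net method; ``None`` derives a
        log-spaced grid from the unconstrained solution at fit time.
    cv_folds:
        Stratified folds used for every cross-validated choice.
    seed:
        Seed for fold shuffling (and nothing else).
    show:
        Print the tuning curve during fitting.
    """

    max_bins: int = 10
    preselect: bool = False
    auto: bool = True
    cutoff: tuple[float, float] = (0.75, 0.80)
    weight_grid: tuple[float, ...] = (-1.0, 0.1, 0.5, 1.0, 2.0, 5.0, 10.0)
    gamma_grid: tuple[float, ...] = (0.1, 1.0, 10.0, 100.0)
    t_grid: tuple[float, ...] | None = None
    cv_folds: int = 10
    seed: int = 0
    show: bool = False

    def validate(self) -> "Options":
        if self.max_bins < 1:
            raise ProblemError("max_bins must be a positive integer")
        if not all(0.0 < c <= 1.0 for c in self.cutoff):
            raise ProblemError("cutoff fractions must lie in (0, 1]")
        if len(self.weight_grid) == 0 or len(self.gamma_grid) == 0:
            raise ProblemError("hyperparameter grids must be non-empty")
        if -1.0 not in self.weight_grid:
            raise ProblemError("weight_grid must contain the sentinel -1 (no reweighting)")
        if self.cv_folds < 2:
            raise ProblemError("cv_folds must be at least 2")
        return self


@dataclass
class ICSProblem:
    """A binary classification problem to be turned into a scorecard.

    ``groups`` lists the candidate effects as tuples of **1-based** column
    indices: ``(p,)`` is the main effect of column p, ``(p1, p2)`` the
    two-way interaction.  When omitted, all main effects are used.
    """

    X_train: np.ndarray
    y_train: np.ndarray
    X_test: np.ndarray | None = None
    y_test: np.ndarray | None = None
    var_types: list[str] | None = None
    var_names: list[str] | None = None
    groups: list[tuple[int, ...]] | None = None
    method: str = "lp"
    options: Options = field(default_factory=Options)
    # filled in by validate_problem
    label_map: dict | None = None
    _validated: bool = False

    @property
    def n_obs(self) -> int:
        return self.X_train.shape[0]

    @property
    def n_vars(self) -> int:
        return self.X_train.shape[1]


def _as_2d(X, name):
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ProblemError(f"{name} must be a 2-d array, got ndim={X.ndim}")
    return X


def infer_var_types(X: np.ndarray) -> list[str]:
    """Guess variable types: two values -> binary, all-integer with few
    levels -> ordinal, otherwise continuous."""
    types = []
    for j in range(X.shape[1]):
        col = X[:, j]
        vals = np.unique(col[~np.isnan(col)])
        if len(vals) <= 2:
            types.append("binary" if len(vals) == 2 else "continuous")
        elif np.allclose(vals, np.round(vals)) and len(vals) <= 10:
            types.append("ordinal")
        else:
            types.append("continuous")
    return types


def validate_problem(raw: ICSProblem) -> ICSProblem:
    """Normalize and check a problem description.

    Labels are mapped to {-1, +1}: the numerically larger of the two
    original values becomes the +1 ("target") class, and the mapping is
    recorded in ``label_map`` for reporting at prediction time.
    Idempotent: validating a validated problem returns it unchanged.
    """
    if raw._validated:
        return raw

    X = _as_2d(raw.X_train, "X_train")
    y = np.asarray(raw.y_train, dtype=float).ravel()
    n, n_d = X.shape
    if y.shape[0] != n:
        raise ProblemError(
            f"X_train has {n} rows but y_train has {y.shape[0]} entries"
        )
    uniq = np.unique(y)
    if len(uniq) != 2:
        raise ProblemError(
            f"y_train must contain exactly 2 distinct values, found {len(uniq)}"
        )
    lo, hi = float(uniq[0]), float(uniq[1])
    label_map = {"negative": lo, "positive": hi}
    y_pm = np.where(y == hi, 1.0, -1.0)

    X_test = raw.X_test
    y_test = raw.y_test
    if X_test is not None:
        X_test = _as_2d(X_test, "X_test")
        if X_test.shape[1] != n_d:
            raise ProblemError(
                f"X_test has {X_test.shape[1]} columns, train schema has {n_d}"
            )
        if y_test is not None:
            y_test = np.asarray(y_test, dtype=float).ravel()
            if y_test.shape[0] != X_test.shape[0]:
                raise ProblemError(
                    f"X_test has {X_test.shape[0]} rows but y_test has "
                    f"{y_test.shape[0]} entries"
                )
            bad = set(np.unique(y_test)) - {lo, hi}
            if bad:
                raise ProblemError(f"y_test contains unseen label values {sorted(bad)}")
            y_test = np.where(y_test == hi, 1.0, -1.0)

    var_types = raw.var_types if raw.var_types is not None else infer_var_types(X)
    if len(var_types) != n_d:
        raise ProblemError(
            f"var_types has {len(var_types)} entries for {n_d} columns"
        )
    for t in var_types:
        if t not in VAR_TYPES:
            raise ProblemError(f"unknown variable type {t!r}")

    var_names = raw.var_names if raw.var_names is not None else [
        f"x{j + 1}" for j in range(n_d)
    ]
    if len(var_names) != n_d:
        raise ProblemError(
            f"var_names has {len(var_names)} entries for {n_d} columns"
        )

    groups = raw.groups
    if groups is None:
        groups = [(j,) for j in range(1, n_d + 1)]
    norm_groups: list[tuple[int, ...]] = []
    for g in groups:
        g = tuple(int(i) for i in (g if isinstance(g, (tuple, list)) else (g,)))
        if len(g) not in (1, 2):
            raise ProblemError(f"group {g} must be a single column or a pair")
        for i in g:
            if not 1 <= i <= n_d:
                raise ProblemError(f"group index {i} out of range [1, {n_d}]")
        if len(g) == 2 and g[0] == g[1]:
            raise ProblemError(f"interaction group {g} must use distinct columns")
        norm_groups.append(g)

    method = raw.method.lower()
    if method not in ("lp", "en"):
        raise ProblemError(f"method must be 'lp' or 'en', got {raw.method!r}")
    if method == "en" and any(len(g) == 2 for g in norm_groups):
        raise ProblemError(
            "enICS only supports main effects; remove interaction groups "
            "or use method='lp'"
        )

    options = raw.options.validate()

    return replace(
        raw,
        X_train=X,
        y_train=y_pm,
        X_test=X_test,
        y_test=y_test,
        var_types=list(var_types),
        var_names=list(var_names),
        groups=norm_groups,
        method=method,
        options=options,
        label_map=label_map,
        _validated=True,
    )
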