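"""Interval construction and binary expansions.

Every variable is cut into intervals by thresholds computed from the
training sample: continuous variables at equal-count quantiles (each
interval must contain at least five training points), ordinal variables
likewise but with integer thresholds, binary variables into their two
values and categorical variables into one interval per observed level.

Two binary expansions of the data are provided:

* the *one-hot* (lp) encoding: within each effect exactly one indicator
  fires, marking the interval (or interaction-grid cell) the value falls in;
* the *cumulative* (en) encoding: an observation activates its own interval
  and every preceding one, so the block is a prefix of ones and fitted
  coefficients live in the adjacent-difference domain.

The module also builds the difference matrix D (rows = adjacent-interval
weight differences, the object the total-variation penalty acts on) and the
reconstruction matrix R mapping difference-domain weights back to interval
weights by per-variable cumulative summation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

MIN_POINTS_PER_INTERVAL = 5


@dataclass
class VariableBinning:
    """Intervals of one variable: thresholds for continuous/ordinal,
    catalogued levels for binary/categorical."""

    var_type: str
    thresholds: np.ndarray  # shape (n_intervals - 1,); empty for cat/binary
    levels: np.ndarray | None  # catalogued values for binary/categorical
    n_intervals: int

    def interval_index(self, x: np.ndarray) -> np.ndarray:
        """0-based interval index per value; -1 marks an unseen level."""
        x = np.asarray(x, dtype=float)
        if self.var_type in ("binary", "categorical"):
            idx = np.full(x.shape, -1, dtype=int)
            for k, level in enumerate(self.levels):
                idx[x == level] = k
            return idx
        # half-open [tau_{k-1}, tau_k), open-ended extremes
        return np.searchsorted(self.thresholds, x, side="right")

    def interval_labels(self) -> list[str]:
        if self.var_type in ("binary", "categorical"):
            return [_fmt(v) for v in self.levels]
        if self.n_intervals == 1:
            return ["any"]
        taus = [_fmt(t) for t in self.thresholds]
        labels = [f"< {taus[0]}"]
        labels += [f"[{taus[k]}, {taus[k + 1]})" for k in range(len(taus) - 1)]
        labels.append(f">= {taus[-1]}")
        return labels


def _fmt(v: float) -> str:
    return f"{int(v)}" if float(v).is_integer() else f"{v:.4g}"


@dataclass
class BinningScheme:
    """Per-variable binnings plus the ordered effect list.

    ``effects`` holds tuples of 0-based column indices: ``(p,)`` for a main
    effect, ``(p1, p2)`` for an interaction; interaction grids reuse the
    marginal thresholds of the two variables.
    """

    variables: dict[int, VariableBinning]
    effects: list[tuple[int, ...]]

    def effect_size(self, effect: tuple[int, ...]) -> int:
        """Number of expanded columns the effect contributes."""
        size = 1
        for p in effect:
            size *= self.variables[p].n_intervals
        return size

    def n_expanded(self) -> int:
        return sum(self.effect_size(e) for e in self.effects)


@dataclass
class ExpandedData:
    """Binary design matrix with a column -> (effect, interval) map."""

    Z: np.ndarray
    column_map: list[tuple]  # (effect_idx, k) or (effect_idx, k, l)
    encoding: str  # "lp" | "en"
    scheme: BinningScheme
    block_slices: list[slice] = field(default_factory=list)


@dataclass
class DifferenceStructure:
    """Total-variation structure of an expanded design.

    ``D`` stacks one row per adjacent-interval pair (+1/-1 in the same
    effect block).  For main effects only, ``D_full`` is the per-variable
    square first-difference operator (first row picks the first interval's
    weight) and ``R = D_full^{-1}`` is block lower-triangular of ones, so
    interval weights are recovered as ``w_tilde = R @ w_hat``.
    """

    D: np.ndarray
    D_full: np.ndarray | None = None
    R: np.ndarray | None = None

    @property
    def n_rows(self) -> int:
        return self.D.shape[0]


def compute_thresholds(
    x: np.ndarray, var_type: str, max_bins: int
) -> VariableBinning:
    """Bin one training variable.

    Continuous variables are split at empirical quantiles (linear
    interpolation) into the largest number of equal-count intervals
    ``<= max_bins`` for which every interval keeps at least five training
    points; duplicate thresholds from heavy ties are collapsed.  Ordinal
    thresholds are additionally rounded to integers.  Binary/categorical
    variables get one interval per catalogued value (binary levels sorted
    ascending, categorical by first appearance).
    """
    x = np.asarray(x, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("cannot bin an empty variable")
    if max_bins < 1:
        raise ValueError("max_bins must be >= 1")

    if var_type == "binary":
        levels = np.unique(x)
        if len(levels) > 2:
            raise ValueError(
                f"binary variable has {len(levels)} distinct values"
            )
        if len(levels) == 1:
            warnings.warn("constant binary variable: single interval")
            return VariableBinning("binary", np.empty(0), levels, 1)
        return VariableBinning("binary", np.empty(0), levels, 2)

    if var_type == "categorical":
        _, first_pos = np.unique(x, return_index=True)
        levels = x[np.sort(first_pos)]  # first-appearance order
        if len(levels) == 1:
            warnings.warn("constant categorical variable: single interval")
        return VariableBinning("categorical", np.empty(0), levels, len(levels))

    if var_type not in ("continuous", "ordinal"):
        raise ValueError(f"unknown variable type {var_type!r}")

    if np.all(x == x[0]):
        warnings.warn("constant variable: effect will carry a single interval")
        return VariableBinning(var_type, np.empty(0), None, 1)

    n = x.size
    n_p = min(max_bins, max(1, n // MIN_POINTS_PER_INTERVAL))
    while n_p > 1:
        qs = np.arange(1, n_p) / n_p
        taus = np.quantile(x, qs, method="linear")
        if var_type == "ordinal":
            taus = np.round(taus)
        taus = np.unique(taus)
        idx = np.searchsorted(taus, x, side="right")
        counts = np.bincount(idx, minlength=len(taus) + 1)
        if counts.min() >= MIN_POINTS_PER_INTERVAL:
            return VariableBinning(var_type, taus, None, len(taus) + 1)
        n_p -= 1
    return VariableBinning(var_type, np.empty(0), None, 1)


def build_scheme(
    X: np.ndarray,
    var_types: list[str],
    groups: list[tuple[int, ...]],
    max_bins: int,
) -> BinningScheme:
    """Bin every variable that appears in ``groups`` (0-based indices)."""
    needed = sorted({p for g in groups for p in g})
    variables = {
        p: compute_thresholds(X[:, p], var_types[p], max_bins) for p in needed
    }
    return BinningScheme(variables, [tuple(g) for g in groups])


def _interaction_block(
    vb1: VariableBinning, vb2: VariableBinning, i1: np.ndarray, i2: np.ndarray
) -> np.ndarray:
    """Column-major vectorized grid indicator: vec index = k + l * n1."""
    n1, n2 = vb1.n_intervals, vb2.n_intervals
    Z = np.zeros((i1.size, n1 * n2))
    ok = (i1 >= 0) & (i2 >= 0)
    Z[np.nonzero(ok)[0], i1[ok] + i2[ok] * n1] = 1.0
    return Z


def lp_encode(X: np.ndarray, scheme: BinningScheme) -> ExpandedData:
    """One-hot expansion: per effect, exactly one indicator per row.

    Unseen categorical levels at transform time yield an all-zero block
    (with a warning); they contribute no points.
    """
    X = np.asarray(X, dtype=float)
    blocks, column_map, block_slices = [], [], []
    start = 0
    for e_idx, effect in enumerate(scheme.effects):
        if len(effect) == 1:
            vb = scheme.variables[effect[0]]
            idx = vb.interval_index(X[:, effect[0]])
            if np.any(idx < 0):
                warnings.warn(
                    f"unseen level(s) in column {effect[0] + 1}: zero block"
                )
            B = np.zeros((X.shape[0], vb.n_intervals))
            ok = idx >= 0
            B[np.nonzero(ok)[0], idx[ok]] = 1.0
            column_map += [(e_idx, k) for k in range(vb.n_intervals)]
        else:
            vb1 = scheme.variables[effect[0]]
            vb2 = scheme.variables[effect[1]]
            i1 = vb1.interval_index(X[:, effect[0]])
            i2 = vb2.interval_index(X[:, effect[1]])
            B = _interaction_block(vb1, vb2, i1, i2)
            column_map += [
                (e_idx, k, l)
                for l in range(vb2.n_intervals)
                for k in range(vb1.n_intervals)
            ]
        blocks.append(B)
        block_slices.append(slice(start, start + B.shape[1]))
        start += B.shape[1]
    Z = np.hstack(blocks) if blocks else np.zeros((X.shape[0], 0))
    return ExpandedData(Z, column_map, "lp", scheme, block_slices)


def en_encode(X: np.ndarray, scheme: BinningScheme) -> ExpandedData:
    """Cumulative expansion (main effects only): block = [1, I(x >= tau_1),
    ..., I(x >= tau_{Np-1})], a non-increasing prefix of ones."""
    if any(len(e) != 1 for e in scheme.effects):
        raise ValueError("cumulative encoding supports main effects only")
    X = np.asarray(X, dtype=float)
    blocks, column_map, block_slices = [], [], []
    start = 0
    for e_idx, (p,) in enumerate(scheme.effects):
        vb = scheme.variables[p]
        idx = vb.interval_index(X[:, p])
        if np.any(idx < 0):
            warnings.warn(f"unseen level(s) in column {p + 1}: base interval only")
            idx = np.where(idx < 0, 0, idx)
        # prefix of ones of length idx+1
        B = (np.arange(vb.n_intervals)[None, :] <= idx[:, None]).astype(float)
        blocks.append(B)
        column_map += [(e_idx, k) for k in range(vb.n_intervals)]
        block_slices.append(slice(start, start + vb.n_intervals))
        start += vb.n_intervals
    Z = np.hstack(blocks) if blocks else np.zeros((X.shape[0], 0))
    return ExpandedData(Z, column_map, "en", scheme, block_slices)


def _main_effect_diff_rows(n: int, offset: int, n_cols: int) -> list[np.ndarray]:
    rows = []
    for k in range(n - 1):
        r = np.zeros(n_cols)
        r[offset + k] = -1.0
        r[offset + k + 1] = 1.0
        rows.append(r)
    return rows


def _categorical_diff_rows(n: int, offset: int, n_cols: int) -> list[np.ndarray]:
    # no natural adjacency: connect each level to the first-catalogued
    # (reference) level
    rows = []
    for k in range(1, n):
        r = np.zeros(n_cols)
        r[offset] = -1.0
        r[offset + k] = 1.0
        rows.append(r)
    return rows


def build_difference_structure(
    scheme: BinningScheme, encoding: str = "lp"
) -> DifferenceStructure:
    """Assemble D (and, for main-effects-only schemes, D_full and R).

    Main effects with m intervals contribute m-1 rows; an interaction grid
    k x l contributes k(l-1) horizontal plus l(k-1) vertical rows;
    categorical effects use a reference-level star (first catalogued level).
    Single-interval effects contribute no rows.
    """
    n_cols = scheme.n_expanded()
    rows: list[np.ndarray] = []
    offset = 0
    for effect in scheme.effects:
        if len(effect) == 1:
            vb = scheme.variables[effect[0]]
            m = vb.n_intervals
            if vb.var_type == "categorical":
                rows += _categorical_diff_rows(m, offset, n_cols)
            else:
                rows += _main_effect_diff_rows(m, offset, n_cols)
            offset += m
        else:
            n1 = scheme.variables[effect[0]].n_intervals
            n2 = scheme.variables[effect[1]].n_intervals
            # vec index = k + l * n1 (column-major)
            for l in range(n2):  # vertical: adjacent rows, same column
                for k in range(n1 - 1):
                    r = np.zeros(n_cols)
                    r[offset + k + l * n1] = -1.0
                    r[offset + k + 1 + l * n1] = 1.0
                    rows.append(r)
            for l in range(n2 - 1):  # horizontal: adjacent columns, same row
                for k in range(n1):
                    r = np.zeros(n_cols)
                    r[offset + k + l * n1] = -1.0
                    r[offset + k + (l + 1) * n1] = 1.0
                    rows.append(r)
            offset += n1 * n2
    D = np.array(rows) if rows else np.zeros((0, n_cols))

    D_full = R = None
    if all(len(e) == 1 for e in scheme.effects):
        D_full = np.zeros((n_cols, n_cols))
        R = np.zeros((n_cols, n_cols))
        offset = 0
        for effect in scheme.effects:
            m = scheme.variables[effect[0]].n_intervals
            blk = slice(offset, offset + m)
            D_full[blk, blk] = np.eye(m) - np.eye(m, k=-1)
            R[blk, blk] = np.tril(np.ones((m, m)))
            offset += m
    return DifferenceStructure(D, D_full, R)
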