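"""Elastic-net core: budget-constrained elastic net on the cumulative encoding.

On the cumulative expansion Z_hat, coefficients w_hat live in the
adjacent-difference domain, so the plain l1 constraint ``||w_hat||_1 <= t``
induces the same piecewise-constant structure the LP path obtains through
its total-variation penalty.  The problem solved is

    min_{w, b}  ||Z_hat w + b - y||_2^2 + ridge_eps ||w||_2^2
    s.t.        ||w||_1 <= t

with labels y in {-1, +1} treated as regression targets and the offset b
unpenalized.  The small fixed ridge (0.05) stabilizes the lasso part.

The constrained problem is solved through its penalized (Lagrangian) form —
a standard elastic net handled by coordinate descent — with a bisection on
the l1 penalty to meet the budget: ||w(lambda)||_1 is continuous and
non-increasing in lambda because the ridge makes the objective strictly
convex.

Iterative reweighting multiplies the columns of Z_hat by chi_jj = a |w_j|
computed from the current solution, solves again on the rescaled data and
maps the solution back via w <- chi v.  Columns whose weight reaches zero
are scaled to zero and stay excluded.  Stops on mean absolute change
< eps2 or after 25 iterations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import ElasticNet

from .binning import ExpandedData
from .lp_core import ReweightConfig

RIDGE_EPS = 0.05


@dataclass
class ENFit:
    w_hat: np.ndarray
    b: float
    t: float
    objective: float  # ||Zw + b - y||^2 + ridge_eps ||w||^2
    ridge_eps: float = RIDGE_EPS
    n_iterations: int = 1
    history: list = field(default_factory=list)


def _ridge_solution(Z: np.ndarray, y: np.ndarray, ridge_eps: float):
    """Unconstrained minimizer of ||Zw + b - y||^2 + ridge_eps ||w||^2 with
    unpenalized b, via normal equations on centered data."""
    z_mean = Z.mean(axis=0)
    y_mean = y.mean()
    Zc = Z - z_mean
    yc = y - y_mean
    A = Zc.T @ Zc + ridge_eps * np.eye(Z.shape[1])
    w = np.linalg.solve(A, Zc.T @ yc)
    b = y_mean - z_mean @ w
    return w, float(b)


def _objective(Z, y, w, b, ridge_eps):
    r = Z @ w + b - y
    return float(r @ r + ridge_eps * (w @ w))


def _penalized_fit(Z: np.ndarray, y: np.ndarray, lam: float, ridge_eps: float):
    """min ||Zw + b - y||^2 + ridge_eps ||w||^2 + lam ||w||_1 via sklearn's
    coordinate descent (objective rescaled to sklearn's 1/(2n) convention)."""
    n = Z.shape[0]
    a1 = lam / (2.0 * n)
    a2 = ridge_eps / n
    alpha = a1 + a2
    model = ElasticNet(
        alpha=alpha,
        l1_ratio=a1 / alpha,
        fit_intercept=True,
        max_iter=200_000,
        tol=1e-12,
    )
    model.fit(Z, y)
    return model.coef_.copy(), float(model.intercept_)


def fit_en(
    Z_hat: ExpandedData | np.ndarray,
    y: np.ndarray,
    t: float,
    ridge_eps: float = RIDGE_EPS,
    budget_tol: float = 1e-9,
) -> ENFit:
    """Solve the budget-constrained elastic net at l1 budget ``t``."""
    Z = Z_hat.Z if isinstance(Z_hat, ExpandedData) else np.asarray(Z_hat, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if t < 0:
        raise ValueError("l1 budget t must be non-negative")
    if t == 0:
        b = float(y.mean())
        w = np.zeros(Z.shape[1])
        return ENFit(w, b, 0.0, _objective(Z, y, w, b, ridge_eps), ridge_eps)

    w_ridge, b_ridge = _ridge_solution(Z, y, ridge_eps)
    if np.abs(w_ridge).sum() <= t + budget_tol:
        # constraint inactive
        return ENFit(
            w_ridge, b_ridge, float(t),
            _objective(Z, y, w_ridge, b_ridge, ridge_eps), ridge_eps,
        )

    # bracket: lam=0 exceeds the budget; grow lam_hi until ||w||_1 <= t
    lam_lo, lam_hi = 0.0, max(1.0, 4.0 * np.abs(Z.T @ (y - y.mean())).max())
    w_hi, b_hi = _penalized_fit(Z, y, lam_hi, ridge_eps)
    for _ in range(60):
        if np.abs(w_hi).sum() <= t:
            break
        lam_hi *= 4.0
        w_hi, b_hi = _penalized_fit(Z, y, lam_hi, ridge_eps)
    w, b = w_hi, b_hi
    for _ in range(80):
        lam_mid = 0.5 * (lam_lo + lam_hi)
        w_mid, b_mid = _penalized_fit(Z, y, lam_mid, ridge_eps)
        if np.abs(w_mid).sum() > t:
            lam_lo = lam_mid
        else:
            lam_hi, w, b = lam_mid, w_mid, b_mid
        if lam_hi - lam_lo <= 1e-12 * max(1.0, lam_hi):
            break
    return ENFit(w, b, float(t), _objective(Z, y, w, b, ridge_eps), ridge_eps)


def reweight_en(
    Z_hat: ExpandedData | np.ndarray,
    y: np.ndarray,
    t: float,
    cfg: ReweightConfig,
    w_init: ENFit,
) -> ENFit:
    """Iteratively reweighted elastic net (25-iteration cap).

    The column scaling chi = a|w| has no additive floor: a coefficient at
    zero removes its column for all later iterations.
    """
    if cfg.a == -1.0:
        return w_init
    Z = Z_hat.Z if isinstance(Z_hat, ExpandedData) else np.asarray(Z_hat, dtype=float)
    w = w_init.w_hat
    fit = w_init
    history = []
    for it in range(cfg.max_iter):
        chi = cfg.a * np.abs(w)
        inner = fit_en(Z * chi[None, :], y, t, ridge_eps=fit.ridge_eps)
        w_new = chi * inner.w_hat
        delta = float(np.mean(np.abs(w_new - w))) if w.size else 0.0
        history.append(delta)
        w = w_new
        fit = ENFit(
            w_hat=w,
            b=inner.b,
            t=float(t),
            objective=_objective(Z, y, w, inner.b, fit.ridge_eps),
            ridge_eps=fit.ridge_eps,
        )
        if delta < cfg.eps2:
            break
    fit.n_iterations = len(history)
    fit.history = history
    return fit
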