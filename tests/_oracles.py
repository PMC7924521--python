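"""Independent reference solvers used only by the tests.

These deliberately take a different algorithmic route from the package:
sequential quadratic programming (SLSQP) on smooth split-variable
reformulations, closed-form normal equations, brute-force pairwise
counting and adaptive quadrature.
"""

import numpy as np


def lp_reference(Z, D, y, gamma, row_weights=None):
    """Reference optimum of the total-variation hinge LP via its dual.

    The primal  min ||D w||_1 + gamma 1'eps  s.t. Y(Zw + b) >= 1 - eps,
    eps >= 0  has the hand-derived dual

        max 1'alpha   s.t.  Z' Y alpha = D' beta,  y' alpha = 0,
                            0 <= alpha <= gamma,  -1 <= beta <= 1,

    solved here as an equality-form LP.  Strong duality makes the optimal
    values coincide, so any construction error in the primal would show up
    as a gap.  Returns only the optimal value (dual variables are not the
    primal solution).
    """
    Z = np.asarray(Z, dtype=float)
    D = np.asarray(D, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if row_weights is not None:
        D = D * np.asarray(row_weights, dtype=float)[:, None]
    n, ns = Z.shape
    nds = D.shape[0]
    # variables [alpha (n), beta (nds)]
    c = np.concatenate([-np.ones(n), np.zeros(nds)])  # maximize sum(alpha)
    A_eq = np.vstack([
        np.hstack([Z.T * y[None, :], -D.T]),
        np.concatenate([y, np.zeros(nds)])[None, :],
    ])
    b_eq = np.zeros(ns + 1)
    bounds = [(0.0, gamma)] * n + [(-1.0, 1.0)] * nds
    from scipy.optimize import linprog

    res = linprog(c, A_eq=A_eq, b_eq=b_eq, bounds=bounds, method="highs")
    assert res.success, res.message
    return -res.fun


def _project_l1_ball(v, t):
    """Euclidean projection onto {x : ||x||_1 <= t} (Duchi et al. 2008)."""
    if np.abs(v).sum() <= t:
        return v
    u = np.sort(np.abs(v))[::-1]
    css = np.cumsum(u)
    rho = np.nonzero(u * np.arange(1, len(u) + 1) > css - t)[0][-1]
    theta = (css[rho] - t) / (rho + 1.0)
    return np.sign(v) * np.maximum(np.abs(v) - theta, 0.0)


def generalized_en_reference(Z_tilde, D_full, y, t, ridge_eps,
                             max_iter=200_000, tol=1e-15):
    """Reference optimum of the generalized elastic net in the interval
    domain: min ||Z w + b - y||^2 + eps ||D w||^2 s.t. ||D w||_1 <= t.

    Substituting u = D w (D square, invertible) gives a smooth convex
    problem over the l1 ball, solved by accelerated projected gradient —
    a first-order route fully independent of coordinate descent.
    """
    Z = np.asarray(Z_tilde, dtype=float)
    D = np.asarray(D_full, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    R = np.linalg.inv(D)
    A = Z @ R
    n, m = A.shape
    ones = np.ones(n)
    H = np.block([[A.T @ A + ridge_eps * np.eye(m), A.T @ ones[:, None]],
                  [ones @ A, np.array([[float(n)]])]])
    L = 2.0 * np.linalg.eigvalsh(H).max()

    def objective(u, b):
        r = A @ u + b - y
        return float(r @ r + ridge_eps * (u @ u))

    u = np.zeros(m)
    b = float(y.mean())
    u_prev, b_prev = u.copy(), b
    f_prev = objective(u, b)
    tk = 1.0
    for it in range(max_iter):
        t_next = 0.5 * (1 + np.sqrt(1 + 4 * tk * tk))
        beta = (tk - 1) / t_next
        uy = u + beta * (u - u_prev)
        by = b + beta * (b - b_prev)
        r = A @ uy + by - y
        gu = 2.0 * (A.T @ r + ridge_eps * uy)
        gb = 2.0 * r.sum()
        u_prev, b_prev, tk = u, b, t_next
        u = _project_l1_ball(uy - gu / L, t)
        b = by - gb / L
        if it % 50 == 0:
            f = objective(u, b)
            if abs(f_prev - f) < tol * max(1.0, abs(f)):
                break
            f_prev = f
    return objective(u, b), R @ u, b


def ridge_reference(Z, y, ridge_eps):
    """Closed-form unconstrained ridge with unpenalized intercept."""
    Z = np.asarray(Z, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = Z.shape
    A = np.zeros((p + 1, p + 1))
    A[:p, :p] = Z.T @ Z + ridge_eps * np.eye(p)
    A[:p, p] = Z.sum(axis=0)
    A[p, :p] = Z.sum(axis=0)
    A[p, p] = n
    rhs = np.concatenate([Z.T @ y, [y.sum()]])
    sol = np.linalg.solve(A, rhs)
    return sol[:p], sol[p]


def concordance_auc(scores, y):
    """O(n^2) pairwise AUC with half credit for ties."""
    scores = np.asarray(scores, dtype=float)
    pos = scores[np.asarray(y) > 0]
    neg = scores[np.asarray(y) <= 0]
    total = 0.0
    for p in pos:
        total += np.sum(p > neg) + 0.5 * np.sum(p == neg)
    return total / (len(pos) * len(neg))


def weighted_ls_reference(x, ye, w):
    """Weighted least squares slope/intercept by normal equations."""
    W = np.diag(w)
    A = np.column_stack([x, np.ones_like(x)])
    coef = np.linalg.solve(A.T @ W @ A, A.T @ W @ ye)
    return coef[0], coef[1]
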