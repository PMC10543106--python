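"""Independent brute-force oracles the implementation is checked against.

Everything here is deliberately naive — per-pair loops, direct formulas,
generic QP solves — and shares no code with the package internals.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize
from scipy.stats import rankdata


def spearman_bruteforce(x: np.ndarray, y: np.ndarray) -> float:
    """Rank both vectors (average ties), then plain Pearson."""
    rx, ry = rankdata(x), rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = np.sqrt((rx ** 2).sum() * (ry ** 2).sum())
    return float((rx * ry).sum() / denom) if denom > 0 else 0.0


def auc_bruteforce(y: np.ndarray, d: np.ndarray) -> float:
    """Count concordant (pos, neg) pairs, half credit for ties."""
    pos = d[y == 1]
    neg = d[y == -1]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def r2_mse_bruteforce(y: np.ndarray, p: np.ndarray) -> tuple[float, float]:
    ss_res = float(sum((yi - pi) ** 2 for yi, pi in zip(y, p)))
    ybar = sum(y) / len(y)
    ss_tot = float(sum((yi - ybar) ** 2 for yi in y))
    return 1.0 - ss_res / ss_tot, ss_res / len(y)


def bh_bruteforce(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up: sort, scale by m/k, cumulative min."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        k = rank_from_top
        val = p[order[k - 1]] * m / k
        running = min(running, val)
        adj[order[k - 1]] = running
    return adj


def adjusted_t_bruteforce(v: np.ndarray, group: np.ndarray,
                          gender: np.ndarray | None) -> tuple[float, float]:
    """Group-coefficient t via explicit normal equations."""
    from scipy.stats import t as tdist
    cols = [np.ones_like(v, dtype=float), np.asarray(group, dtype=float)]
    if gender is not None:
        cols.append(np.asarray(gender, dtype=float))
    X = np.column_stack(cols)
    n, k = X.shape
    beta = np.linalg.solve(X.T @ X, X.T @ v)
    resid = v - X @ beta
    sigma2 = float(resid @ resid) / (n - k)
    cov = sigma2 * np.linalg.inv(X.T @ X)
    t = beta[1] / np.sqrt(cov[1, 1])
    p = 2 * tdist.sf(abs(t), n - k)
    return float(t), float(p)


def svc_qp_objective(X: np.ndarray, y: np.ndarray, C: float) -> float:
    """Optimal primal objective of the soft-margin linear SVC, solved as a
    QP in (w, b, xi) with SLSQP."""
    n, p = X.shape

    def obj(z):
        w, xi = z[:p], z[p + 1:]
        return 0.5 * float(w @ w) + C * float(xi.sum())

    def grad(z):
        g = np.zeros_like(z)
        g[:p] = z[:p]
        g[p + 1:] = C
        return g

    cons = [
        {"type": "ineq",  # y_i (w.x_i + b) - 1 + xi_i >= 0
         "fun": lambda z: y * (X @ z[:p] + z[p]) - 1 + z[p + 1:]},
        {"type": "ineq", "fun": lambda z: z[p + 1:]},  # xi >= 0
    ]
    z0 = np.zeros(p + 1 + n)
    z0[p + 1:] = 1.0
    res = minimize(obj, z0, jac=grad, constraints=cons, method="SLSQP",
                   options={"maxiter": 500, "ftol": 1e-12})
    return float(res.fun)


def svr_qp_objective(X: np.ndarray, y: np.ndarray, C: float,
                     epsilon: float) -> float:
    """Optimal primal objective of epsilon-insensitive linear SVR
    (variables w, b, xi, xi*)."""
    n, p = X.shape

    def obj(z):
        w = z[:p]
        xi = z[p + 1:p + 1 + n]
        xis = z[p + 1 + n:]
        return 0.5 * float(w @ w) + C * float(xi.sum() + xis.sum())

    cons = [
        {"type": "ineq",  # y - (w.x + b) <= eps + xi
         "fun": lambda z: epsilon + z[p + 1:p + 1 + n] - (y - (X @ z[:p] + z[p]))},
        {"type": "ineq",  # (w.x + b) - y <= eps + xi*
         "fun": lambda z: epsilon + z[p + 1 + n:] - ((X @ z[:p] + z[p]) - y)},
        {"type": "ineq", "fun": lambda z: z[p + 1:]},
    ]
    z0 = np.zeros(p + 1 + 2 * n)
    z0[p] = float(np.mean(y))
    slack0 = np.abs(y - np.mean(y)) + 1.0
    z0[p + 1:p + 1 + n] = slack0
    z0[p + 1 + n:] = slack0
    res = minimize(obj, z0, constraints=cons, method="SLSQP",
                   options={"maxiter": 800, "ftol": 1e-12})
    return float(res.fun)
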