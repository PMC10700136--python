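"""Independent oracles used by the tests.

These deliberately avoid the library code paths they check: a plain
coordinate-descent LASSO, a brute-force step-up FDR adjustment, and a
grid-search maximizer of the Breslow Cox partial likelihood.
"""

from __future__ import annotations

import numpy as np


def lasso_coordinate_descent(
    X: np.ndarray, y: np.ndarray, lam: float, n_iter: int = 5000, tol: float = 1e-12
) -> tuple[np.ndarray, float]:
    """Minimize (1/2n)||y - Xb - b0||^2 + lam*||b||_1 by cyclic coordinate
    descent with an unpenalized intercept."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n, p = X.shape
    xm = X.mean(axis=0)
    ym = y.mean()
    Xc = X - xm
    yc = y - ym
    beta = np.zeros(p)
    col_ss = (Xc ** 2).sum(axis=0) / n
    resid = yc.copy()
    for _ in range(n_iter):
        max_delta = 0.0
        for j in range(p):
            if col_ss[j] == 0:
                continue
            rho = (Xc[:, j] @ resid) / n + col_ss[j] * beta[j]
            new = np.sign(rho) * max(abs(rho) - lam, 0.0) / col_ss[j]
            if new != beta[j]:
                resid -= Xc[:, j] * (new - beta[j])
                max_delta = max(max_delta, abs(new - beta[j]))
                beta[j] = new
        if max_delta < tol:
            break
    intercept = ym - xm @ beta
    return beta, intercept


def bh_stepup(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values straight from the definition:
    q_(i) = min_{j >= i} ( p_(j) * m / j ), capped at 1, in input order."""
    p = np.asarray(pvalues, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q_sorted = np.empty(m)
    for rank_idx in range(m):
        candidates = [
            p[order[j]] * m / (j + 1) for j in range(rank_idx, m)
        ]
        q_sorted[rank_idx] = min(1.0, min(candidates))
    q = np.empty(m)
    q[order] = q_sorted
    return q


def breslow_partial_loglik(
    beta: float, x: np.ndarray, time: np.ndarray, event: np.ndarray
) -> float:
    """Breslow log partial likelihood for a single covariate."""
    ll = 0.0
    eta = beta * x
    for i in np.flatnonzero(event == 1):
        risk = time >= time[i]
        ll += eta[i] - np.log(np.exp(eta[risk]).sum())
    return ll


def cox_grid_mle(
    x: np.ndarray, time: np.ndarray, event: np.ndarray,
    lo: float = -5.0, hi: float = 5.0, step: float = 1e-4,
) -> float:
    """Grid-search maximizer of the Breslow partial likelihood."""
    grid = np.arange(lo, hi + step, step)
    lls = np.array([breslow_partial_loglik(b, x, time, event) for b in grid])
    return float(grid[lls.argmax()])
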