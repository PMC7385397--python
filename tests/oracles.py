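"""Independent reference implementations used only to check the package.

These deliberately avoid the code paths they validate: the LASSO oracle
is a proximal-gradient (FISTA) solver, and the hypergeometric oracle
enumerates every possible draw.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


def fista_lasso(X: np.ndarray, y: np.ndarray, lam: float,
                n_iter: int = 20_000) -> np.ndarray:
    """Proximal-gradient minimizer of 1/(2n)||y - Xw||^2 + lam*||w||_1."""
    n, p = X.shape
    L = float(np.linalg.eigvalsh(X.T @ X / n).max())
    if L == 0:
        return np.zeros(p)
    w = np.zeros(p)
    z = w.copy()
    t = 1.0
    for _ in range(n_iter):
        grad = X.T @ (X @ z - y) / n
        step = z - grad / L
        w_new = np.sign(step) * np.maximum(np.abs(step) - lam / L, 0.0)
        t_new = (1.0 + np.sqrt(1.0 + 4.0 * t * t)) / 2.0
        z = w_new + (t - 1.0) / t_new * (w_new - w)
        w, t = w_new, t_new
    return w


def lasso_objective(X: np.ndarray, y: np.ndarray, w: np.ndarray,
                    lam: float) -> float:
    n = X.shape[0]
    resid = y - X @ w
    return float(0.5 / n * resid @ resid + lam * np.abs(w).sum())


def hypergeom_tail_by_enumeration(N: int, K: int, n: int, x: int) -> float:
    """P(overlap >= x) by enumerating all C(N, n) draws of a set of size n
    from a pool of N containing K marked elements."""
    marked = set(range(K))
    total = 0
    hits = 0
    for draw in combinations(range(N), n):
        total += 1
        if len(marked.intersection(draw)) >= x:
            hits += 1
    return hits / total if total else 1.0
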