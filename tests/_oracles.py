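"""Independent oracles used only by the test-suite.

These deliberately avoid the code paths they check: the Lasso oracle is a plain
cyclic coordinate-descent solver written against the Gram matrix, and the edit
distance oracle is the textbook exhaustive recursion (memoized on positions).
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np


def soft(x: float, t: float) -> float:
    return np.sign(x) * max(abs(x) - t, 0.0)


def lasso_cd_path(
    X: np.ndarray,
    y: np.ndarray,
    lambdas: np.ndarray,
    tol: float = 1e-12,
    max_sweeps: int = 100_000,
) -> np.ndarray:
    """Cyclic coordinate descent for (1/2n)||y-Xb||^2 + lam||b||_1, warm-started
    down a decreasing penalty grid.  Returns (len(lambdas), p) coefficients."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    G = X.T @ X / n
    c = X.T @ y / n
    beta = np.zeros(p)
    out = np.empty((len(lambdas), p))
    for i, lam in enumerate(lambdas):
        for _ in range(max_sweeps):
            delta = 0.0
            for j in range(p):
                bj = beta[j]
                rho = c[j] - G[j] @ beta + G[j, j] * bj
                new = soft(rho, lam) / G[j, j]
                if new != bj:
                    beta[j] = new
                    delta = max(delta, abs(new - bj))
            if delta < tol:
                break
        out[i] = beta
    return out


def first_activation_order(coefs: np.ndarray, tol: float = 1e-8) -> list[int]:
    """Feature order by first |coef| > tol along a (grid, p) path; ties by larger
    magnitude at the tied grid point, then by index."""
    keys = []
    active = np.abs(coefs) > tol
    for j in range(coefs.shape[1]):
        idx = np.flatnonzero(active[:, j])
        if idx.size:
            first = int(idx[0])
            keys.append((first, -abs(float(coefs[first, j])), j))
    return [j for _, _, j in sorted(keys)]


def levenshtein_recursive(a, b) -> int:
    """Exhaustive recursion over the edit lattice (memoized on positions)."""
    a, b = tuple(a), tuple(b)

    @lru_cache(maxsize=None)
    def rec(i: int, j: int) -> int:
        if i == len(a):
            return len(b) - j
        if j == len(b):
            return len(a) - i
        return min(
            rec(i + 1, j) + 1,
            rec(i, j + 1) + 1,
            rec(i + 1, j + 1) + (a[i] != b[j]),
        )

    return rec(0, 0)


def orthonormal_design(n: int, p: int, rng: np.random.Generator) -> np.ndarray:
    """Column-centered X with X^T X = n I (population-standardized by construction)."""
    G = rng.normal(size=(n, p + 1))
    G -= G.mean(axis=0)
    Q, _ = np.linalg.qr(G)
    return Q[:, :p] * np.sqrt(n)
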