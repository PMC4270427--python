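"""Independent numerical oracles used by the test suite.

These deliberately re-derive the model's equilibrium conditions from
scratch (no calls into the package's steady-state code) so that the
closed-form branches can be validated against an implementation-agnostic
root finder.
"""

from __future__ import annotations

import numpy as np


def equilibrium_residual(X: np.ndarray, k: float, d: float, T: float,
                         n: int, M: float) -> np.ndarray:
    """Vectorized residual of the equilibrium system, shape (N, 2).

    Written out independently: k (M - X1 - X2) Xi^n / (T^n + Xi^n) - d Xi.
    """
    x1, x2 = X[:, 0], X[:, 1]
    pool = M - x1 - x2
    Tn = T**n
    f1 = k * pool * np.abs(x1) ** n / (Tn + np.abs(x1) ** n) - d * x1
    f2 = k * pool * np.abs(x2) ** n / (Tn + np.abs(x2) ** n) - d * x2
    return np.stack([f1, f2], axis=1)


def newton_multistart(k: float, d: float, T: float, n: int, M: float,
                      n_grid: int = 50, iters: int = 80,
                      tol: float = 1e-11) -> np.ndarray:
    """All equilibria in the feasible simplex by damped Newton iteration
    from a dense grid of starts, with finite-difference Jacobians.

    Returns unique equilibrium points, shape (m, 2), deduplicated at 1e-7.
    """
    g = np.linspace(0.0, M, n_grid)
    xx, yy = np.meshgrid(g, g)
    X = np.stack([xx.ravel(), yy.ravel()], axis=1).astype(float)
    h = 1e-7 * max(1.0, M)

    for _ in range(iters):
        F = equilibrium_residual(X, k, d, T, n, M)
        # finite-difference Jacobian, batched
        e1 = np.array([h, 0.0])
        e2 = np.array([0.0, h])
        J11_J21 = (equilibrium_residual(X + e1, k, d, T, n, M)
                   - equilibrium_residual(X - e1, k, d, T, n, M)) / (2 * h)
        J12_J22 = (equilibrium_residual(X + e2, k, d, T, n, M)
                   - equilibrium_residual(X - e2, k, d, T, n, M)) / (2 * h)
        a, c = J11_J21[:, 0], J11_J21[:, 1]
        b, e = J12_J22[:, 0], J12_J22[:, 1]
        det = a * e - b * c
        ok = np.abs(det) > 1e-14
        dx1 = np.where(ok, (e * F[:, 0] - b * F[:, 1]) / det, 0.0)
        dx2 = np.where(ok, (-c * F[:, 0] + a * F[:, 1]) / det, 0.0)
        step = np.stack([dx1, dx2], axis=1)
        # damp large steps to stay near the simplex
        norm = np.linalg.norm(step, axis=1, keepdims=True)
        cap = 0.25 * max(1.0, M)
        step = np.where(norm > cap, step * cap / np.maximum(norm, 1e-300), step)
        X = X - step
        if np.max(norm) < 1e-14 * max(1.0, M):
            break

    F = equilibrium_residual(X, k, d, T, n, M)
    resid = np.linalg.norm(F, axis=1)
    scale = max(1.0, k * M, d * M)
    keep = (resid < tol * scale) & (X[:, 0] > -1e-9) & (X[:, 1] > -1e-9) \
        & (X.sum(axis=1) < M + 1e-6)
    pts = np.clip(X[keep], 0.0, None)
    if not len(pts):
        return pts.reshape(0, 2)
    # deduplicate
    uniq: list[np.ndarray] = []
    for p in pts:
        if not any(np.linalg.norm(p - q) < 1e-7 * max(1.0, M) for q in uniq):
            uniq.append(p)
    return np.array(uniq)


def scalar_root_scan(f, lo: float, hi: float, n_grid: int = 4000) -> list[float]:
    """Brute-force sign-change bisection roots of a scalar function."""
    xs = np.linspace(lo, hi, n_grid)
    fs = np.array([f(x) for x in xs])
    roots = []
    for i in range(len(xs) - 1):
        a, b = xs[i], xs[i + 1]
        fa, fb = fs[i], fs[i + 1]
        if fa == 0.0:
            roots.append(a)
            continue
        if fa * fb < 0:
            for _ in range(100):
                m = 0.5 * (a + b)
                fm = f(m)
                if fa * fm <= 0:
                    b = m
                else:
                    a, fa = m, fm
            roots.append(0.5 * (a + b))
    return roots
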