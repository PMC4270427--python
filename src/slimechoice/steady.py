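"""Steady states, stability and critical masses of the commitment model.

Setting the time derivatives to zero yields four families of equilibria:

* trivial (0, 0) — no decision; always stable with double eigenvalue -d.
* semi-trivial (X, 0) and (0, X) — exclusive exploitation of one option.
  For n = 2 the nonzero coordinate solves (k+d) X^2 - k M X + d T^2 = 0;
  a saddle-node at M1 creates the stable upper / unstable lower pair.
* homogeneous (X, X) — both options exploited equally.  For n = 2,
  (2k+d) X^2 - k M X + d T^2 = 0; born at a saddle-node at M2, the upper
  branch is unstable until the pitchfork at M3 and stable beyond it.
* non-homogeneous (X1, X2), X1 != X2, both positive — asymmetric
  exploitation.  For n = 2 the coordinates are the roots of
  X^2 - S X + T^2 = 0 with S = k M / (k + d); they exist for M > M3,
  always unstable, and merge with the homogeneous upper branch at
  (T, T) when M = M3 (a subcritical, symmetry-restoring pitchfork).

Closed-form critical masses for n = 2:

    M1 = (2 T / k) sqrt(d (k + d))      (semi-trivial saddle-node)
    M2 = (2 T / k) sqrt(d (2 k + d))    (homogeneous saddle-node)
    M3 = 2 T (k + d) / k                (symmetry-restoring pitchfork)

with M1 < M2 < M3 for every valid parameter set.  For n > 2 all branches
are located by bracketed scalar root-finding on the reduced equilibrium
conditions and the critical masses by bisection on branch counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import sqrt
from pathlib import Path
from typing import Iterable

import numpy as np
from scipy.optimize import brentq

from .model import ModelParams, State, jacobian, rhs

__all__ = [
    "SteadyState",
    "CriticalMasses",
    "semi_trivial",
    "homogeneous",
    "nonhomogeneous",
    "trivial",
    "critical_masses",
    "stability",
    "all_steady_states",
    "states_to_frame",
]

#: residual tolerance defining "is an equilibrium"
EQUILIBRIUM_TOL = 1e-9


@dataclass(frozen=True)
class SteadyState:
    X1: float
    X2: float
    branch: str
    stable: bool
    eigenvalues: tuple[complex, complex]
    degenerate: bool = False  # sits exactly at a limit point / pitchfork

    def as_state(self) -> State:
        return State(self.X1, self.X2)

    def mirrored(self) -> "SteadyState":
        swap = {"semi_trivial_upper": "semi_trivial_upper",
                "semi_trivial_lower": "semi_trivial_lower",
                "nonhomogeneous_plus": "nonhomogeneous_minus",
                "nonhomogeneous_minus": "nonhomogeneous_plus"}
        return SteadyState(self.X2, self.X1, swap.get(self.branch, self.branch),
                           self.stable, self.eigenvalues, self.degenerate)


@dataclass(frozen=True)
class CriticalMasses:
    """The three bifurcation masses, M1 < M2 < M3."""

    M1: float
    M2: float
    M3: float

    def __post_init__(self) -> None:
        if not (0 < self.M1 < self.M2 < self.M3):
            raise ValueError(f"critical masses must satisfy 0 < M1 < M2 < M3, got {self}")


def _eigenvalues(x1: float, x2: float, params: ModelParams) -> tuple[complex, complex]:
    """Eigenvalues of the 2x2 Jacobian via its characteristic quadratic.

    lambda^2 - tr*lambda + det = 0, solved exactly so that e.g. the trivial
    state yields the double eigenvalue -d without round-off.
    """
    J = jacobian((x1, x2), params)
    tr = J[0, 0] + J[1, 1]
    det = J[0, 0] * J[1, 1] - J[0, 1] * J[1, 0]
    disc = complex(tr * tr - 4.0 * det) ** 0.5
    lam1, lam2 = (tr + disc) / 2.0, (tr - disc) / 2.0
    return (_realify(lam1), _realify(lam2))


def _realify(z: complex) -> complex:
    return complex(z.real, 0.0) if z.imag == 0 else z


def _make_state(x1: float, x2: float, branch: str, params: ModelParams,
                degenerate: bool = False) -> SteadyState:
    lam = _eigenvalues(x1, x2, params)
    stable = (lam[0].real < 0) and (lam[1].real < 0)
    return SteadyState(x1, x2, branch, stable, lam, degenerate)


def trivial(params: ModelParams) -> SteadyState:
    """The no-decision state (0, 0); always stable, eigenvalue -d twice."""
    return _make_state(0.0, 0.0, "trivial", params)


# ---------------------------------------------------------------------------
# branch solvers


def _positive_quadratic_roots(a: float, b: float, c: float,
                              rel_tol: float = 1e-12) -> tuple[list[float], bool]:
    """Real positive roots of a x^2 + b x + c, with a degenerate flag when the
    discriminant vanishes to relative precision (double root at a limit point)."""
    disc = b * b - 4.0 * a * c
    scale = max(b * b, abs(4.0 * a * c), 1e-300)
    if disc < -rel_tol * scale:
        return [], False
    if abs(disc) <= rel_tol * scale:
        r = -b / (2.0 * a)
        return ([r], True) if r > 0 else ([], False)
    s = sqrt(disc)
    # numerically stable pairing
    q = -(b + np.copysign(s, b)) / 2.0
    roots = sorted({q / a, c / q} if q != 0 else {-b / a, 0.0}, reverse=True)
    return [r for r in roots if r > 0], False


def _scan_roots(f, lo: float, hi: float, n_grid: int = 800) -> list[float]:
    """Bracketed root scan of a scalar function on (lo, hi)."""
    xs = np.linspace(lo, hi, n_grid)
    fs = np.array([f(x) for x in xs])
    roots = []
    for i in range(len(xs) - 1):
        if fs[i] == 0.0:
            roots.append(xs[i])
        elif fs[i] * fs[i + 1] < 0:
            roots.append(brentq(f, xs[i], xs[i + 1], xtol=1e-14, rtol=8.9e-16))
    return sorted(set(roots), reverse=True)


def semi_trivial(params: ModelParams) -> list[SteadyState]:
    """Equilibria (X, 0): the upper (stable) and lower (unstable) branch.

    Empty below the first critical mass M1.  The mirrored (0, X) states are
    added by :func:`all_steady_states`.
    """
    k, d, T, n, M = params.k, params.d, params.T, params.n, params.M
    if M <= 0:
        return []
    if n == 2:
        roots, degen = _positive_quadratic_roots(k + d, -k * M, d * T * T)
    else:
        # reduced condition k (M - X) X^(n-1) = d (T^n + X^n) on (0, M)
        f = lambda x: k * (M - x) * x ** (n - 1) - d * (T**n + x**n)
        roots, degen = _scan_roots(f, 0.0, M), False
    labels = (["semi_trivial_upper", "semi_trivial_lower"] if len(roots) == 2
              else ["semi_trivial_upper"])
    return [_make_state(x, 0.0, lab, params, degenerate=degen)
            for x, lab in zip(roots, labels)]


def homogeneous(params: ModelParams) -> list[SteadyState]:
    """Equilibria (X, X): equal exploitation of both options.

    Empty below the second critical mass M2; the upper branch becomes stable
    only past the pitchfork at M3.
    """
    k, d, T, n, M = params.k, params.d, params.T, params.n, params.M
    if M <= 0:
        return []
    if n == 2:
        roots, degen = _positive_quadratic_roots(2 * k + d, -k * M, d * T * T)
    else:
        f = lambda x: k * (M - 2 * x) * x ** (n - 1) - d * (T**n + x**n)
        roots, degen = _scan_roots(f, 0.0, M / 2.0), False
    labels = (["homogeneous_upper", "homogeneous_lower"] if len(roots) == 2
              else ["homogeneous_upper"])
    return [_make_state(x, x, lab, params, degenerate=degen)
            for x, lab in zip(roots, labels)]


def nonhomogeneous(params: ModelParams) -> list[SteadyState]:
    """Asymmetric equilibria (X1, X2) with X1 != X2, both positive.

    For n = 2 the coordinates are the roots of X^2 - S X + T^2 with
    S = k M / (k + d) (so X1 X2 = T^2 and X1 + X2 = S exactly); they exist
    for M > M3 and are always unstable.  At M = M3 the pair merges with the
    homogeneous upper branch at (T, T).
    """
    k, d, T, n, M = params.k, params.d, params.T, params.n, params.M
    if M <= 0:
        return []
    if n == 2:
        S = k * M / (k + d)
        roots, degen = _positive_quadratic_roots(1.0, -S, T * T)
        if len(roots) == 1 and degen:
            # pitchfork point: the pair degenerates onto (T, T)
            x = roots[0]
            return [_make_state(x, x, "nonhomogeneous_plus", params, degenerate=True)]
        if len(roots) < 2:
            return []
        hi, lo = roots
        return [_make_state(hi, lo, "nonhomogeneous_plus", params),
                _make_state(lo, hi, "nonhomogeneous_minus", params)]
    return _nonhomogeneous_numeric(params)


def _nonhomogeneous_numeric(params: ModelParams) -> list[SteadyState]:
    """General-n asymmetric branch via a 1-D solve on the committed sum S.

    Both coordinates satisfy d (T^n + x^n) = k (M - S) x^(n-1) with the
    shared total S = X1 + X2; a pair of distinct roots whose sum equals S
    is an asymmetric equilibrium.
    """
    k, d, T, n, M = params.k, params.d, params.T, params.n, params.M

    def pair(S: float) -> tuple[float, float] | None:
        c = k * (M - S)
        if c <= 0:
            return None
        roots = _scan_roots(lambda x: c * x ** (n - 1) - d * (T**n + x**n),
                            0.0, max(M, 4 * T), n_grid=400)
        if len(roots) != 2 or abs(roots[0] - roots[1]) < 1e-10:
            return None
        return roots[0], roots[1]

    def residual(S: float) -> float | None:
        p = pair(S)
        return None if p is None else p[0] + p[1] - S

    Ss = np.linspace(1e-9, M * (1 - 1e-9), 600)
    res = [residual(S) for S in Ss]
    out: list[SteadyState] = []
    for i in range(len(Ss) - 1):
        a, b = res[i], res[i + 1]
        if a is None or b is None or a * b > 0:
            continue
        S_root = brentq(lambda S: residual(S), Ss[i], Ss[i + 1], xtol=1e-12)
        p = pair(S_root)
        if p is None:
            continue
        hi, lo = p
        if not any(abs(s.X1 - hi) < 1e-8 for s in out):
            out.append(_make_state(hi, lo, "nonhomogeneous_plus", params))
            out.append(_make_state(lo, hi, "nonhomogeneous_minus", params))
    return out


# ---------------------------------------------------------------------------
# critical masses


def critical_masses(params: ModelParams) -> CriticalMasses:
    """The three bifurcation masses of the model at these rates.

    Closed form for n = 2; bisection on branch existence for n > 2.  The
    ordering M1 < M2 < M3 holds for every valid (k, d, T, n).
    """
    k, d, T, n = params.k, params.d, params.T, params.n
    if n == 2:
        return CriticalMasses(
            M1=2.0 * T / k * sqrt(d * (k + d)),
            M2=2.0 * T / k * sqrt(d * (2.0 * k + d)),
            M3=2.0 * T * (k + d) / k,
        )
    hi = 10.0 * T * (k + d) / k  # generous upper bound
    M1 = _bisect_existence(lambda M: len(semi_trivial(params.with_mass(M))) > 0, hi)
    M2 = _bisect_existence(lambda M: len(homogeneous(params.with_mass(M))) > 0, hi)
    M3 = _bisect_existence(lambda M: len(nonhomogeneous(params.with_mass(M))) > 0, hi)
    return CriticalMasses(M1, M2, M3)


def _bisect_existence(exists, hi: float, tol: float = 1e-8) -> float:
    lo = 1e-9
    if not exists(hi):
        raise RuntimeError("branch not found below the search bound")
    while hi - lo > tol * max(1.0, hi):
        mid = 0.5 * (lo + hi)
        if exists(mid):
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# stability and inventory


def stability(state: State | SteadyState | tuple[float, float],
              params: ModelParams) -> tuple[tuple[complex, complex], bool]:
    """Eigenvalues of the Jacobian at an equilibrium and the stability flag.

    Rejects points that are not equilibria (rhs norm >= EQUILIBRIUM_TOL
    relative to the natural rate scale d*M).
    """
    if isinstance(state, SteadyState):
        x = (state.X1, state.X2)
    elif isinstance(state, State):
        x = (state.X1, state.X2)
    else:
        x = tuple(state)
    scale = max(1.0, params.d * params.M, params.k * params.M)
    if np.linalg.norm(rhs(x, params)) >= EQUILIBRIUM_TOL * scale:
        raise ValueError(f"point {x} is not an equilibrium of the model")
    lam = _eigenvalues(x[0], x[1], params)
    return lam, (lam[0].real < 0 and lam[1].real < 0)


def all_steady_states(params: ModelParams) -> list[SteadyState]:
    """Complete inventory: trivial, semi-trivial (with mirrors), homogeneous
    and non-homogeneous equilibria, each annotated with stability.

    The count is 1, 5, 7 or 9 according to M relative to (M1, M2, M3).
    """
    out = [trivial(params)]
    for s in semi_trivial(params):
        out.append(s)
        out.append(s.mirrored())
    out.extend(homogeneous(params))
    for s in nonhomogeneous(params):
        if s.degenerate:
            continue  # at M = M3 the pair coincides with the homogeneous branch
        out.append(s)
    return out


def states_to_frame(states: Iterable[SteadyState], params: ModelParams):
    """Steady-state inventory as a DataFrame (CSV-ready)."""
    import pandas as pd

    rows = [{
        "k": params.k, "d": params.d, "T": params.T, "n": params.n, "M": params.M,
        "branch": s.branch, "X1": s.X1, "X2": s.X2, "stable": s.stable,
        "re_lambda1": s.eigenvalues[0].real, "re_lambda2": s.eigenvalues[1].real,
        "degenerate": s.degenerate,
    } for s in states]
    return pd.DataFrame(rows)


def write_states_csv(states: Iterable[SteadyState], params: ModelParams,
                     path: str | Path) -> None:
    states_to_frame(states, params).to_csv(path, index=False, float_format="%.10g")
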