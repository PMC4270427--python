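"""Bifurcation diagrams, existence boundaries and basins of attraction.

Sweeping the total mass M traces how the equilibrium inventory changes:
a single no-decision state below M1, bistability between no decision and
one-option exploitation on (M1, M3), and tristability (none / one / both)
past the symmetry-restoring pitchfork at M3.  In threshold-flux space the
loci M = M1, M2, M3 bound the parameter regions where each bifurcation
exists at a given mass.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.integrate import solve_ivp

from .model import ModelParams, jacobian, rhs
from . import steady
from .steady import SteadyState, critical_masses

__all__ = [
    "BifurcationDiagram",
    "ExistenceBoundaries",
    "BasinFractions",
    "branch_sweep",
    "existence_boundaries",
    "classify_regime",
    "basin_probe",
]

_BIF_TYPES = ("limit_point_1", "limit_point_2", "pitchfork")


@dataclass
class BifurcationDiagram:
    params: ModelParams  # base rates; M field is ignored
    masses: np.ndarray
    #: per-mass steady-state inventories
    inventories: list[list[SteadyState]]
    #: bifurcation type -> mass located by bisection
    bifurcations: dict[str, float]
    truncated: bool = False

    def to_frame(self):
        import pandas as pd

        rows = []
        for M, states in zip(self.masses, self.inventories):
            for s in states:
                rows.append({"M": M, "branch": s.branch, "X1": s.X1, "X2": s.X2,
                             "stable": s.stable})
        return pd.DataFrame(rows)

    def to_csv(self, path: str | Path) -> None:
        df = self.to_frame()
        for btype, mass in self.bifurcations.items():
            df.loc[len(df)] = {"M": mass, "branch": btype, "X1": np.nan,
                               "X2": np.nan, "stable": np.nan}
        df.to_csv(path, index=False, float_format="%.10g")


def branch_sweep(params: ModelParams, masses) -> BifurcationDiagram:
    """Steady-state inventory along an increasing mass grid, with the three
    bifurcation masses located by bisection on branch-count changes.

    The located masses agree with the closed-form critical masses to the
    bisection tolerance (1e-6 in M).  If the grid does not reach past M3
    the diagram is returned with ``truncated=True`` and only the detectable
    points reported.
    """
    masses = np.asarray(masses, dtype=float)
    if len(masses) < 10 or np.any(np.diff(masses) <= 0):
        raise ValueError("mass grid must be increasing with at least 10 points")

    inventories = [steady.all_steady_states(params.with_mass(M)) for M in masses]

    indicators = {
        "limit_point_1": lambda M: len(steady.semi_trivial(params.with_mass(M))) > 0,
        "limit_point_2": lambda M: len(steady.homogeneous(params.with_mass(M))) > 0,
        "pitchfork": lambda M: any(not s.degenerate for s in
                                   steady.nonhomogeneous(params.with_mass(M))),
    }
    flags = {name: np.array([ind(M) for M in masses])
             for name, ind in indicators.items()}

    bifurcations: dict[str, float] = {}
    for name, flag in flags.items():
        change = np.nonzero(flag[1:] != flag[:-1])[0]
        if len(change):
            i = change[0]
            bifurcations[name] = _bisect_onset(indicators[name],
                                               masses[i], masses[i + 1])

    truncated = len(bifurcations) < 3
    return BifurcationDiagram(params, masses, inventories, bifurcations, truncated)


def _bisect_onset(exists, lo: float, hi: float, tol: float = 1e-6) -> float:
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if exists(mid):
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


@dataclass
class ExistenceBoundaries:
    """Critical threshold T as a function of flux k at fixed mass M.

    ``T1 >= T2 >= T3`` pointwise; parameter pairs (k, T) below the third
    curve admit all three bifurcations at this mass.
    """

    M: float
    d: float
    n: int
    k: np.ndarray
    T1: np.ndarray
    T2: np.ndarray
    T3: np.ndarray

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"k": self.k, "T1": self.T1, "T2": self.T2,
                             "T3": self.T3})

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.10g")


def existence_boundaries(k_grid, M: float, d: float = 1.0,
                         n: int = 2) -> ExistenceBoundaries:
    """Solve M = M_i(k, T) for T along a flux grid (closed form for n = 2).

    T1(k) = k M / (2 sqrt(d (k+d))), T2(k) = k M / (2 sqrt(d (2k+d))),
    T3(k) = k M / (2 (k+d)); each curve is the locus where the respective
    bifurcation mass equals M.
    """
    k = np.asarray(k_grid, dtype=float)
    if np.any(k <= 0) or M <= 0:
        raise ValueError("k grid and M must be positive")
    if n == 2:
        T1 = k * M / (2.0 * np.sqrt(d * (k + d)))
        T2 = k * M / (2.0 * np.sqrt(d * (2.0 * k + d)))
        T3 = k * M / (2.0 * (k + d))
    else:
        from scipy.optimize import brentq

        def invert(ki, which):
            def f(T):
                cm = critical_masses(ModelParams(k=ki, d=d, T=T, n=n, M=M))
                return getattr(cm, which) - M
            return brentq(f, 1e-6 * M, 10 * M, xtol=1e-10)

        T1 = np.array([invert(ki, "M1") for ki in k])
        T2 = np.array([invert(ki, "M2") for ki in k])
        T3 = np.array([invert(ki, "M3") for ki in k])
    return ExistenceBoundaries(M=M, d=d, n=n, k=k, T1=T1, T2=T2, T3=T3)


def classify_regime(params: ModelParams, rel_tol: float = 1e-9) -> dict:
    """Which stable regimes coexist at this mass.

    Below M1 only the trivial state exists; on (M1, M3) the trivial state
    coexists with one-option exploitation (bistable modulo mirror symmetry);
    past M3 the both-options state joins (tristability).  Masses within
    ``rel_tol`` of a critical mass are labelled degenerate.
    """
    cm = critical_masses(params)
    M = params.M
    for mass, name in ((cm.M1, "limit_point_1"), (cm.M2, "limit_point_2"),
                       (cm.M3, "pitchfork")):
        if abs(M - mass) <= rel_tol * max(1.0, mass):
            return {"labels": ("degenerate",), "at": name, "critical_masses": cm}
    if M < cm.M1:
        labels = ("trivial_only",)
    elif M < cm.M3:
        labels = ("trivial", "one_option")
    else:
        labels = ("trivial", "one_option", "both_options")
    return {"labels": labels, "critical_masses": cm}


@dataclass
class BasinFractions:
    """Empirical basin-of-attraction sizes from random initial conditions."""

    fractions: dict[str, float]
    n_samples: int
    n_nonconverged: int
    attractors: list[SteadyState] = field(repr=False, default_factory=list)


def basin_probe(params: ModelParams, n_samples: int = 200, seed: int = 0,
                t_end: float | None = None, match_tol: float = 1e-4) -> BasinFractions:
    """Fraction of uniformly drawn initial conditions converging to each
    stable equilibrium.

    Initial conditions are uniform on the feasible triangle
    {X1, X2 >= 0, X1 + X2 <= M}.  Trajectories stop when the derivative
    norm drops below 1e-8 or at t_end = 500/d; runs that have not settled
    near a stable state by then are counted as non-converged.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(seed)
    if t_end is None:
        t_end = 500.0 / params.d

    stable_states = [s for s in steady.all_steady_states(params) if s.stable]
    labels = _attractor_labels(stable_states)

    # uniform on the triangle via reflection of the unit square
    u = rng.random((n_samples, 2))
    over = u.sum(axis=1) > 1.0
    u[over] = 1.0 - u[over]
    starts = u * params.M

    def settled(t, x):
        return float(np.linalg.norm(rhs(x, params))) - 1e-8
    settled.terminal = True
    settled.direction = -1

    counts = {lab: 0 for lab in labels}
    nonconv = 0
    for x0 in starts:
        sol = solve_ivp(lambda t, x: rhs(x, params), (0.0, t_end), x0,
                        method="LSODA", rtol=1e-9, atol=1e-11, events=settled,
                        jac=lambda t, x: jacobian(x, params))
        xf = sol.y[:, -1]
        dists = [np.hypot(xf[0] - s.X1, xf[1] - s.X2) for s in stable_states]
        j = int(np.argmin(dists))
        if dists[j] <= match_tol * max(1.0, params.M):
            counts[labels[j]] += 1
        else:
            nonconv += 1

    fractions = {lab: c / n_samples for lab, c in counts.items()}
    fractions["nonconverged"] = nonconv / n_samples
    return BasinFractions(fractions=fractions, n_samples=n_samples,
                          n_nonconverged=nonconv, attractors=stable_states)


def _attractor_labels(states: list[SteadyState]) -> list[str]:
    labels = []
    for s in states:
        if s.branch.startswith("semi_trivial"):
            side = "option1" if s.X1 > s.X2 else "option2"
            labels.append(f"{s.branch}_{side}")
        else:
            labels.append(s.branch)
    return labels
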