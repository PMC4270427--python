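"""Deterministic two-option commitment model.

A collective of total mass ``M`` (for a plasmodium, its size) distributes
itself between two identical options.  ``X1`` and ``X2`` are the masses
committed to options 1 and 2; the uncommitted pool is ``M - X1 - X2``.
Recruitment to option *i* is proportional to the pool and to a sigmoidal
(quorum) function of the mass already committed to that option only —
information is purely local — while commitment decays at a constant rate:

    dXi/dt = k * (M - X1 - X2) * F(Xi) - d * Xi,   F(x) = x^n / (T^n + x^n)

``k`` is the commitment flux rate, ``d`` the decay rate, ``T`` the feedback
threshold (half-saturation mass) and ``n >= 2`` the sigmoid exponent.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml
from scipy.integrate import solve_ivp

__all__ = [
    "ModelParams",
    "State",
    "Trajectory",
    "feedback",
    "feedback_deriv",
    "rhs",
    "jacobian",
    "integrate",
]


@dataclass(frozen=True)
class ModelParams:
    """Full parameterization shared by every analysis stage.

    Parameters
    ----------
    k : float
        Commitment flux rate per unit time (> 0).
    d : float
        Commitment decay rate per unit time (> 0).  Default 1: time can
        always be rescaled so that decay sets the unit.
    T : float
        Feedback threshold in mass units (> 0); the committed mass at which
        the quorum function reaches one half.
    n : int
        Sigmoid exponent, integer >= 2.  Results are qualitatively
        insensitive to the exact exponent; 2 is the default.
    M : float
        Total system mass >= 0.  In the foraging experiments this is
        identified with the plasmodium diameter in cm.
    """

    k: float
    T: float
    M: float
    d: float = 1.0
    n: int = 2

    def __post_init__(self) -> None:
        if not (self.k > 0):
            raise ValueError(f"flux rate k must be > 0, got {self.k}")
        if not (self.d > 0):
            raise ValueError(f"decay rate d must be > 0, got {self.d}")
        if not (self.T > 0):
            raise ValueError(f"threshold T must be > 0, got {self.T}")
        if int(self.n) != self.n or self.n < 2:
            raise ValueError(f"exponent n must be an integer >= 2, got {self.n}")
        if not (self.M >= 0):
            raise ValueError(f"total mass M must be >= 0, got {self.M}")
        object.__setattr__(self, "n", int(self.n))

    def with_mass(self, M: float) -> "ModelParams":
        """Same rates and threshold at a different total mass."""
        return replace(self, M=M)

    def to_dict(self) -> dict:
        return {"k": self.k, "d": self.d, "T": self.T, "n": self.n, "M": self.M}

    @classmethod
    def from_dict(cls, data: dict) -> "ModelParams":
        return cls(k=float(data["k"]), d=float(data.get("d", 1.0)),
                   T=float(data["T"]), n=int(data.get("n", 2)),
                   M=float(data["M"]))

    def save(self, path: str | Path) -> None:
        """Write the parameter set as a flat key-value YAML file."""
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "ModelParams":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass(frozen=True)
class State:
    """Committed masses (X1, X2); both non-negative, X1 + X2 <= M."""

    X1: float
    X2: float

    def __post_init__(self) -> None:
        if self.X1 < 0 or self.X2 < 0:
            raise ValueError(f"committed masses must be >= 0, got {self}")

    def as_array(self) -> np.ndarray:
        return np.array([self.X1, self.X2], dtype=float)

    @property
    def committed(self) -> float:
        return self.X1 + self.X2

    def swapped(self) -> "State":
        return State(self.X2, self.X1)


def feedback(x, T: float, n: int = 2):
    """Sigmoidal quorum response F(x) = x^n / (T^n + x^n).

    Monotone non-decreasing, F(0) = 0, F(T) = 1/2, F -> 1 as x -> inf.
    Accepts scalars or arrays in ``x``.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("committed mass x must be >= 0")
    if not T > 0:
        raise ValueError("threshold T must be > 0")
    if n < 2:
        raise ValueError("exponent n must be >= 2")
    xn = x**n
    out = xn / (T**n + xn)
    return out if out.ndim else float(out)


def feedback_deriv(x, T: float, n: int = 2):
    """dF/dx = n T^n x^(n-1) / (T^n + x^n)^2; the n>=2 limit at x=0 is 0."""
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("committed mass x must be >= 0")
    Tn = T**n
    out = n * Tn * x ** (n - 1) / (Tn + x**n) ** 2
    return out if out.ndim else float(out)


def rhs(state: State | Sequence[float], params: ModelParams) -> np.ndarray:
    """Time derivatives (dX1/dt, dX2/dt) of the commitment dynamics.

    Recruitment k*(M - X1 - X2)*F(Xi) vanishes when the pool is empty, so
    both derivatives are <= 0 on the line X1 + X2 = M: the simplex
    {X1, X2 >= 0, X1 + X2 <= M} is forward-invariant.
    """
    x = state.as_array() if isinstance(state, State) else np.asarray(state, float)
    pool = params.M - x.sum()
    # adaptive solvers probe marginally negative masses; F extends by 0 there
    return params.k * pool * feedback(np.maximum(x, 0.0), params.T, params.n) \
        - params.d * x


def jacobian(state: State | Sequence[float], params: ModelParams) -> np.ndarray:
    """2x2 Jacobian of :func:`rhs` at ``state``.

    Row i: d(rhs_i)/dXi = k*pool*F'(Xi) - k*F(Xi) - d on the diagonal,
    and -k*F(Xi) off the diagonal (the pool couples the two options).
    """
    x = state.as_array() if isinstance(state, State) else np.asarray(state, float)
    pool = params.M - x.sum()
    xc = np.maximum(x, 0.0)
    F = np.asarray(feedback(xc, params.T, params.n))
    Fp = np.asarray(feedback_deriv(xc, params.T, params.n))
    k, d = params.k, params.d
    return np.array([
        [k * pool * Fp[0] - k * F[0] - d, -k * F[0]],
        [-k * F[1], k * pool * Fp[1] - k * F[1] - d],
    ])


@dataclass
class Trajectory:
    """Time-stamped solution of the commitment ODE."""

    t: np.ndarray
    X1: np.ndarray
    X2: np.ndarray
    params: ModelParams

    @property
    def terminal(self) -> State:
        return State(float(self.X1[-1]), float(self.X2[-1]))

    def terminal_rhs_norm(self) -> float:
        return float(np.linalg.norm(rhs(self.terminal, self.params)))

    def to_csv(self, path: str | Path) -> None:
        import pandas as pd

        pd.DataFrame({"t": self.t, "X1": self.X1, "X2": self.X2}).to_csv(
            path, index=False, float_format="%.10g")


def integrate(params: ModelParams, initial: State | Sequence[float],
              t_end: float, rtol: float = 1e-7, atol: float = 1e-9,
              n_points: int = 200) -> Trajectory:
    """Integrate the commitment ODE from ``initial`` to ``t_end``.

    Uses an adaptive stiff-capable scheme (LSODA).  Raises RuntimeError on
    solver failure rather than returning a truncated trajectory.
    """
    if t_end <= 0:
        raise ValueError("t_end must be > 0")
    x0 = initial.as_array() if isinstance(initial, State) else np.asarray(initial, float)
    if x0.min() < 0 or x0.sum() > params.M * (1 + 1e-12) + 1e-12:
        raise ValueError("initial state outside the feasible simplex")

    sol = solve_ivp(lambda t, x: rhs(x, params), (0.0, t_end), x0,
                    method="LSODA", rtol=rtol, atol=atol,
                    t_eval=np.linspace(0.0, t_end, n_points),
                    jac=lambda t, x: jacobian(x, params))
    if not sol.success:
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    # clip solver-tolerance-level negativity only
    X = np.clip(sol.y, 0.0, None)
    return Trajectory(t=sol.t, X1=X[0], X2=X[1], params=params)
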