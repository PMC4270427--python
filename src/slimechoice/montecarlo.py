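"""Stochastic mass-recruitment simulator of the two-option model.

Mass moves in discrete units delta between the uncommitted pool and the two
options.  At each step the four possible events — add to option 1, remove
from option 1, add to option 2, remove from option 2 — occur with
probabilities proportional to the deterministic model's propensities

    A_i = k (M - X1 - X2) F(X_i)      (recruitment toward option i)
    R_i = d X_i                       (decay of commitment to option i)

normalized by their current sum.  A realisation starts from small random
commitments, runs for a fixed step budget (default 70 000, enough to reach
the stationary regime) and its final state is classified as "one" option
chosen if at least 60% of the total mass sits on a single option, "two" if
the committed mass dominates but is split, and "none" when most of the
mass never moved.

Two implementations are provided: a readable pure-Python realisation
runner (:func:`run_realisation`) that can record full trajectories, and a
numba-compiled batch kernel used for outcome-probability estimation and
grid fitting, where ~1e10 elementary steps are routine.  Both follow the
same event semantics; tests compare them statistically.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit

from .model import ModelParams, State, feedback

__all__ = [
    "MCConfig",
    "MCOutcome",
    "OutcomeDistribution",
    "AbsorbingStateError",
    "step_probabilities",
    "run_realisation",
    "classify",
    "outcome_distribution",
    "simulate_batch",
]

OUTCOMES = ("none", "one", "two")

#: fraction of the moved mass that must sit on one option to call it chosen
MAJORITY_FRACTION = 0.6
#: minimum committed fraction of M for a decision to have been made at all
MOVED_FRACTION = 0.5


class AbsorbingStateError(RuntimeError):
    """All four event propensities vanish (exactly uncommitted state)."""


@dataclass(frozen=True)
class MCConfig:
    """Simulation settings around a :class:`ModelParams`.

    mass_unit defaults to M/1000 so that the default 70 000-step budget
    reaches the stationary regime with ample margin.  init_fraction bounds
    the initial random commitments as a fraction of M (uniform on
    [0, init_fraction*M] per option); the default 0.5 spreads starts over
    the feasible simplex so that realisations sample the coexisting
    attraction basins, mirroring the variable initial exploration of a
    plasmodium, and avoids the absorbing fully-uncommitted state.
    """

    params: ModelParams
    mass_unit: float | None = None
    n_steps: int = 70_000
    init_fraction: float = 0.5
    seed: int = 0
    n_realisations: int = 1000

    def __post_init__(self) -> None:
        if self.n_steps < 1 or self.n_realisations < 1:
            raise ValueError("n_steps and n_realisations must be >= 1")
        if not (0 < self.init_fraction <= 1):
            raise ValueError("init_fraction must lie in (0, 1]")
        if self.mass_unit is not None and not (0 < self.mass_unit < self.params.M):
            raise ValueError("mass_unit must lie in (0, M)")

    @property
    def delta(self) -> float:
        return self.params.M / 1000.0 if self.mass_unit is None else self.mass_unit

    def with_mass(self, M: float) -> "MCConfig":
        return replace(self, params=self.params.with_mass(M))


@dataclass(frozen=True)
class MCOutcome:
    X1: float
    X2: float
    classification: str
    steps_used: int


@dataclass(frozen=True)
class OutcomeDistribution:
    """Empirical probabilities of choosing zero, one or two options."""

    M: float
    p0: float
    p1: float
    p2: float
    n_realisations: int
    se: tuple[float, float, float] = field(default=(0.0, 0.0, 0.0))

    def as_array(self) -> np.ndarray:
        return np.array([self.p0, self.p1, self.p2])


def step_probabilities(state: State | tuple[float, float],
                       config: MCConfig) -> np.ndarray:
    """The four event probabilities (add1, remove1, add2, remove2).

    Propensities are normalized by their current sum so the four
    probabilities always sum to one; the exactly-uncommitted state, where
    every propensity vanishes, raises :class:`AbsorbingStateError`.
    """
    x1, x2 = (state.X1, state.X2) if isinstance(state, State) else state
    p = config.params
    pool = p.M - x1 - x2
    A = p.k * pool * np.asarray(feedback([x1, x2], p.T, p.n))
    R = p.d * np.array([x1, x2])
    props = np.array([A[0], R[0], A[1], R[1]])
    total = props.sum()
    if total <= 0.0:
        raise AbsorbingStateError(
            "all propensities vanish: state is exactly uncommitted")
    return props / total


def classify(x1: float, x2: float, M: float) -> str:
    """Outcome rule on the final state.

    "none" when most of the mass never moved (committed fraction below
    1/2); otherwise "one" when at least 60% of the moved mass sits on a
    single option, and "two" when the moved mass is spread between the
    options.  The majority rule is taken relative to the moved mass
    because the stationary uncommitted pool of the model is generically
    nonzero (decay continually returns mass to the pool), so an exclusive
    one-option decision need not capture 60% of the total mass — for
    fluxes with k/(k+d) <= 0.6 it never could.  The three classes are
    exhaustive and mutually exclusive.
    """
    committed = x1 + x2
    if committed < MOVED_FRACTION * M:
        return "none"
    if max(x1, x2) >= MAJORITY_FRACTION * committed:
        return "one"
    return "two"


def run_realisation(config: MCConfig, rng: np.random.Generator,
                    record: bool = False) -> MCOutcome | tuple[MCOutcome, np.ndarray]:
    """One stochastic realisation (pure-Python reference implementation).

    Initial commitments are uniform on [0, init_fraction*M] per option.
    Each step draws one of the four events from :func:`step_probabilities`
    and moves one mass unit, clipping at the boundaries (an add-event with
    a pool below delta transfers the remaining pool; a remove-event on a
    commitment below delta removes all of it), so positivity and
    X1 + X2 <= M hold exactly at every step.  The run terminates early
    once the uncommitted pool drops below delta.
    """
    p = config.params
    delta = config.delta
    x1 = rng.random() * config.init_fraction * p.M
    x2 = rng.random() * config.init_fraction * p.M
    traj = [(x1, x2)] if record else None

    steps_used = config.n_steps
    for step in range(config.n_steps):
        pool = p.M - x1 - x2
        if pool < delta:
            steps_used = step
            break
        try:
            probs = step_probabilities((x1, x2), config)
        except AbsorbingStateError:
            # fully uncommitted state reached by decay: nothing can move
            steps_used = step
            break
        u = rng.random()
        c = np.cumsum(probs)
        if u < c[0]:
            x1 += min(delta, pool)
        elif u < c[1]:
            x1 -= min(delta, x1)
        elif u < c[2]:
            x2 += min(delta, pool)
        else:
            x2 -= min(delta, x2)
        if record:
            traj.append((x1, x2))

    outcome = MCOutcome(x1, x2, classify(x1, x2, p.M), steps_used)
    if record:
        return outcome, np.array(traj)
    return outcome


# ---------------------------------------------------------------------------
# fast batch kernel


@njit(cache=True, fastmath=True)
def _batch_kernel(k, d, T, n, M, delta, n_steps, init_fraction, seeds):  # pragma: no cover - numba
    B = seeds.shape[0]
    X1 = np.empty(B)
    X2 = np.empty(B)
    steps_used = np.empty(B, dtype=np.int64)
    max_violation = 0.0
    squared = n == 2
    for i in range(B):
        np.random.seed(seeds[i])
        ki, Ti, Mi, di = k[i], T[i], M[i], d
        dlt = delta[i]
        Tn = Ti**n
        x1 = np.random.random() * init_fraction * Mi
        x2 = np.random.random() * init_fraction * Mi
        used = n_steps
        for step in range(n_steps):
            pool = Mi - x1 - x2
            if pool < dlt:
                used = step
                break
            if squared:
                a = x1 * x1
                b = x2 * x2
            else:
                a = x1**n
                b = x2**n
            kp = ki * pool
            A1 = kp * a / (Tn + a)
            A2 = kp * b / (Tn + b)
            R1 = di * x1
            R2 = di * x2
            total = A1 + R1 + A2 + R2
            if total <= 0.0:
                used = step
                break
            u = np.random.random() * total
            if u < A1:
                x1 += dlt if dlt < pool else pool
            elif u < A1 + R1:
                x1 -= dlt if dlt < x1 else x1
            elif u < A1 + R1 + A2:
                x2 += dlt if dlt < pool else pool
            else:
                x2 -= dlt if dlt < x2 else x2
            # track worst constraint violation across all steps
            v = -(x1 if x1 < x2 else x2)
            if v > max_violation:
                max_violation = v
            v = (x1 + x2) - Mi
            if v > max_violation:
                max_violation = v
        X1[i] = x1
        X2[i] = x2
        steps_used[i] = used
    return X1, X2, steps_used, max_violation


def _realisation_seeds(seed: int, n: int) -> np.ndarray:
    """Deterministic 32-bit seed vector for the batch kernel."""
    return np.random.SeedSequence(seed).generate_state(n).astype(np.uint32)


def simulate_batch(config: MCConfig, seeds: np.ndarray | None = None):
    """Run ``n_realisations`` independent realisations through the compiled
    kernel.  Returns (X1, X2, steps_used, max_violation) where
    max_violation is the largest positivity/conservation breach observed at
    any step of any realisation (exactly 0.0 when the clipping rules hold).
    """
    p = config.params
    if seeds is None:
        seeds = _realisation_seeds(config.seed, config.n_realisations)
    B = len(seeds)
    ones = np.ones(B)
    return _batch_kernel(ones * p.k, p.d, ones * p.T, p.n, ones * p.M,
                         ones * config.delta, config.n_steps,
                         config.init_fraction, np.asarray(seeds, np.uint32))


def outcome_distribution(config: MCConfig,
                         seeds: np.ndarray | None = None) -> OutcomeDistribution:
    """Empirical outcome probabilities (p0, p1, p2) over independent
    realisations, with binomial standard errors sqrt(p(1-p)/n).
    """
    X1, X2, _, _ = simulate_batch(config, seeds=seeds)
    M = config.params.M
    n = len(X1)
    committed = X1 + X2
    none = committed < MOVED_FRACTION * M
    one = ~none & (np.maximum(X1, X2) >= MAJORITY_FRACTION * committed)
    two = ~none & ~one
    # disjoint exhaustive masks: the three proportions sum to 1 exactly
    p0, p1, p2 = (float(m.sum()) / n for m in (none, one, two))
    se = tuple(float(np.sqrt(p * (1 - p) / n)) for p in (p0, p1, p2))
    return OutcomeDistribution(M=M, p0=float(p0), p1=float(p1), p2=float(p2),
                               n_realisations=n, se=se)


def outcome_distributions_over_masses(config: MCConfig, masses) -> list[OutcomeDistribution]:
    """Outcome distributions along a mass sweep (shared settings, one seed
    stream per mass derived from the config seed)."""
    streams = np.random.SeedSequence(config.seed).spawn(len(masses))
    out = []
    for M, stream in zip(masses, streams):
        seeds = stream.generate_state(config.n_realisations).astype(np.uint32)
        out.append(outcome_distribution(config.with_mass(M), seeds=seeds))
    return out
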