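"""Grid fitting of the simulator to experiment outcome tables.

The simulator alone cannot account for every source of variation in the
trials, so predictions are a mixture: with weight lambda the simulator's
outcome distribution at each mass, with weight (1 - lambda) a uniform
distribution over the three outcomes.  The fit minimizes the summed
squared error between mixture predictions and observed outcome
proportions over an exhaustive (k, T, lambda) grid — the protocol used
for the three strains, with k from 0.5 to 3.5 and T from 0.5 to 2 in
steps of 0.1, lambda in steps of 0.01, and 1000 simulator realisations
per (k, T) pair and mass.

Simulator distributions are cached per (k, T, M) and shared across the
lambda search (lambda enters only linearly) and, optionally, across
fits; every (k, T) cell reuses one common stream of realisation seeds
per mass (common random numbers), which smooths the stochastic objective
surface across the grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .data import ExperimentTable, mixture_probabilities
from .model import ModelParams
from .montecarlo import MCConfig, outcome_distribution

__all__ = [
    "FitResult",
    "SimulatorCache",
    "predicted_distribution",
    "objective",
    "closed_form_lambda",
    "grid_fit",
    "default_k_grid",
    "default_T_grid",
    "default_lambda_grid",
]


def default_k_grid() -> np.ndarray:
    return np.round(np.arange(0.5, 3.5 + 1e-9, 0.1), 10)


def default_T_grid() -> np.ndarray:
    return np.round(np.arange(0.5, 2.0 + 1e-9, 0.1), 10)


def default_lambda_grid() -> np.ndarray:
    return np.round(np.arange(0.0, 1.0 + 1e-9, 0.01), 10)


def predicted_distribution(p_sim, lam: float) -> np.ndarray:
    """Mixture prediction lambda * p_sim + (1 - lambda)/3.

    ``p_sim`` is one simulator outcome distribution (or a stack of them);
    the output rows sum to one whenever the input rows do.
    """
    return mixture_probabilities(p_sim, lam)


def objective(predicted, observed) -> float:
    """Summed squared error between predicted and observed outcome
    proportions over all masses and the three outcomes."""
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if predicted.shape != observed.shape:
        raise ValueError(
            f"mass grids differ: predicted {predicted.shape} vs observed {observed.shape}")
    return float(((predicted - observed) ** 2).sum())


def closed_form_lambda(p_sim, q_obs) -> float:
    """Least-squares optimal mixing proportion for fixed simulator output.

    Writing a = p_sim - 1/3 and b = q_obs - 1/3, the objective is
    sum (lambda a - b)^2, minimized at lambda = <a,b>/<a,a>, clipped to
    [0, 1].
    """
    a = np.asarray(p_sim, float) - 1.0 / 3.0
    b = np.asarray(q_obs, float) - 1.0 / 3.0
    denom = (a * a).sum()
    if denom == 0.0:
        return 0.0
    return float(np.clip((a * b).sum() / denom, 0.0, 1.0))


class SimulatorCache:
    """Outcome distributions keyed by (k, T, M), shareable across fits.

    The cache also owns the common-random-number seed streams: one stream
    of realisation seeds per mass, derived from ``seed`` and reused for
    every (k, T) cell.
    """

    def __init__(self, template: MCConfig, seed: int = 0):
        self.template = template
        self.seed = seed
        self._store: dict[tuple[float, float, float], np.ndarray] = {}
        self._mass_seeds: dict[float, np.ndarray] = {}

    def _seeds_for_mass(self, M: float) -> np.ndarray:
        if M not in self._mass_seeds:
            stream = np.random.SeedSequence((self.seed, int(round(M * 1e6))))
            self._mass_seeds[M] = stream.generate_state(
                self.template.n_realisations).astype(np.uint32)
        return self._mass_seeds[M]

    def distribution(self, k: float, T: float, M: float) -> np.ndarray:
        key = (round(float(k), 10), round(float(T), 10), round(float(M), 10))
        if key not in self._store:
            params = ModelParams(k=k, d=self.template.params.d, T=T,
                                 n=self.template.params.n, M=M)
            cfg = MCConfig(params=params, mass_unit=self.template.mass_unit,
                           n_steps=self.template.n_steps,
                           init_fraction=self.template.init_fraction,
                           seed=self.seed,
                           n_realisations=self.template.n_realisations)
            dist = outcome_distribution(cfg, seeds=self._seeds_for_mass(M))
            self._store[key] = dist.as_array()
        return self._store[key]


@dataclass
class FitResult:
    strain: str
    k_hat: float
    T_hat: float
    lambda_hat: float
    sse: float
    k_grid: np.ndarray = field(repr=False)
    T_grid: np.ndarray = field(repr=False)
    lambda_grid: np.ndarray = field(repr=False)
    n_realisations: int = 0
    seed: int = 0
    surface: pd.DataFrame | None = field(default=None, repr=False)

    def to_dict(self) -> dict:
        return {"strain": self.strain, "k": self.k_hat, "T": self.T_hat,
                "lambda": self.lambda_hat, "sse": self.sse,
                "n_realisations": self.n_realisations, "seed": self.seed,
                "k_grid": [float(v) for v in self.k_grid],
                "T_grid": [float(v) for v in self.T_grid],
                "lambda_step": float(np.diff(self.lambda_grid).mean())}

    def save(self, path: str | Path) -> None:
        import json

        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def grid_fit(experiment: ExperimentTable,
             k_grid=None, T_grid=None, lambda_grid=None,
             mc_template: MCConfig | None = None,
             seed: int = 0,
             cache: SimulatorCache | None = None,
             keep_surface: bool = False) -> FitResult:
    """Exhaustive (k, T, lambda) grid search minimizing the squared error.

    For each (k, T) the simulator outcome distribution is computed once
    per experimental mass (from the cache when provided); the lambda grid
    is then scanned in closed vector form.  Deterministic given the seed.
    """
    if len(experiment.masses) < 2:
        raise ValueError("experiment must cover at least 2 masses")
    k_grid = default_k_grid() if k_grid is None else np.asarray(k_grid, float)
    T_grid = default_T_grid() if T_grid is None else np.asarray(T_grid, float)
    lambda_grid = (default_lambda_grid() if lambda_grid is None
                   else np.asarray(lambda_grid, float))
    if not (len(k_grid) and len(T_grid) and len(lambda_grid)):
        raise ValueError("empty parameter grid")

    if cache is None:
        if mc_template is None:
            mc_template = MCConfig(params=ModelParams(k=1.0, T=1.0, M=1.0),
                                   n_realisations=1000)
        cache = SimulatorCache(mc_template, seed=seed)

    q = experiment.proportions()          # (n_mass, 3)
    b = q - 1.0 / 3.0
    masses = experiment.masses

    best = None
    rows = []
    for k in k_grid:
        for T in T_grid:
            p_sim = np.stack([cache.distribution(k, T, M) for M in masses])
            a = p_sim - 1.0 / 3.0
            # sse(lambda) = sum (lambda*a - b)^2, vectorized over the grid
            aa = (a * a).sum()
            ab = (a * b).sum()
            bb = (b * b).sum()
            sse_lam = lambda_grid**2 * aa - 2.0 * lambda_grid * ab + bb
            if not np.all(np.isfinite(sse_lam)):
                raise ValueError(f"non-finite objective at (k={k}, T={T})")
            j = int(np.argmin(sse_lam))
            if keep_surface:
                rows.append({"k": k, "T": T, "lambda": lambda_grid[j],
                             "sse": sse_lam[j]})
            if best is None or sse_lam[j] < best[0]:
                best = (float(sse_lam[j]), float(k), float(T),
                        float(lambda_grid[j]))

    sse, k_hat, T_hat, lambda_hat = best
    return FitResult(strain=experiment.strain, k_hat=k_hat, T_hat=T_hat,
                     lambda_hat=lambda_hat, sse=sse,
                     k_grid=k_grid, T_grid=T_grid, lambda_grid=lambda_grid,
                     n_realisations=cache.template.n_realisations, seed=seed,
                     surface=pd.DataFrame(rows) if keep_surface else None)
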