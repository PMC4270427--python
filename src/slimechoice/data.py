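"""Experiment outcome tables: synthetic generation, reading and writing.

The experimental design behind the model: three strains of Physarum
polycephalum (Japanese, Australian, American), ten plasmodium sizes given
as diameters 4, 3.2, 2.6, 2.3, 2, 1.8, 1.7, 1.3, 1 and 0.8 cm, 65
replicates per strain and size (1950 trials in total), each trial scored
as having chosen zero, one or two of two identical food sources.

The synthetic generator draws outcomes from exactly the statistical model
the fitting stage assumes: for each mass the simulator's outcome
distribution is mixed with a uniform distribution over the three outcomes
with weight lambda, and replicates are independent categorical draws from
the mixture.  Tables round-trip through CSV/TSV in long format (one row
per replicate) or aggregated format (outcome counts per mass); the
supplementary-style spreadsheet layout can be ingested with a column
mapping.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .model import ModelParams
from .montecarlo import MCConfig, OUTCOMES, outcome_distribution

__all__ = [
    "DIAMETERS_CM",
    "REPLICATES",
    "StrainSpec",
    "DesignSpec",
    "ExperimentTable",
    "TableValidationError",
    "generate_experiment",
    "read_table",
    "write_table",
    "PAPER_STRAINS",
]

#: the ten plasmodium diameters (cm) used in the experiments
DIAMETERS_CM = (4.0, 3.2, 2.6, 2.3, 2.0, 1.8, 1.7, 1.3, 1.0, 0.8)
#: replicates per strain and size
REPLICATES = 65

_OUTCOME_ALIASES = {
    "none": "none", "zero": "none", "0": "none", "no": "none",
    "one": "one", "single": "one", "1": "one",
    "two": "two", "both": "two", "2": "two",
}


class TableValidationError(ValueError):
    """An outcome table violates its consistency contract."""


@dataclass(frozen=True)
class StrainSpec:
    """Ground-truth parameters of one strain for synthetic generation.

    The triples fitted to the three real strains are available as
    :data:`PAPER_STRAINS`.
    """

    label: str
    k: float
    T: float
    lam: float
    d: float = 1.0
    n: int = 2
    mass_unit: float | None = None  # None -> M/1000 per mass
    n_steps: int = 70_000
    init_fraction: float = 0.5
    n_realisations: int = 1000

    def __post_init__(self) -> None:
        ModelParams(k=self.k, d=self.d, T=self.T, n=self.n, M=1.0)  # validate rates
        if not (0.0 <= self.lam <= 1.0):
            raise ValueError(f"mixing proportion lambda must be in [0, 1], got {self.lam}")

    def mc_config(self, M: float, seed: int = 0) -> MCConfig:
        return MCConfig(params=ModelParams(k=self.k, d=self.d, T=self.T,
                                           n=self.n, M=M),
                        mass_unit=self.mass_unit, n_steps=self.n_steps,
                        init_fraction=self.init_fraction, seed=seed,
                        n_realisations=self.n_realisations)


#: best-fit (k, T, lambda) triples for the three strains
PAPER_STRAINS = {
    "Japan": StrainSpec("Japan", k=2.5, T=1.5, lam=0.9239),
    "Australian": StrainSpec("Australian", k=1.5, T=0.9, lam=0.8448),
    "American": StrainSpec("American", k=1.5, T=1.2, lam=0.9149),
}


@dataclass(frozen=True)
class DesignSpec:
    """Masses, replication and seed of a (synthetic) experiment.

    ``overdispersion`` (rho in [0, 1), default 0 = off) adds
    beta-binomial-style extra variability for robustness testing: per
    mass, the mixture probabilities are themselves drawn from a Dirichlet
    with concentration (1 - rho)/rho before the replicates are sampled,
    so outcomes are more variable than the exact mixture assumes.
    """

    masses: tuple[float, ...] = DIAMETERS_CM
    replicates: int = REPLICATES
    seed: int = 0
    overdispersion: float = 0.0

    def __post_init__(self) -> None:
        if len(set(self.masses)) != len(self.masses) or min(self.masses) <= 0:
            raise ValueError("masses must be positive and distinct")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if not (0.0 <= self.overdispersion < 1.0):
            raise ValueError("overdispersion must lie in [0, 1)")


@dataclass
class ExperimentTable:
    """Per-strain outcome counts by mass, with optional per-replicate rows.

    ``counts`` has columns (diameter_cm, n0, n1, n2, n); ``long`` — when
    present — has one row per replicate with columns
    (strain, diameter_cm, replicate, outcome).
    """

    strain: str
    counts: pd.DataFrame
    long: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        c = self.counts
        required = {"diameter_cm", "n0", "n1", "n2", "n"}
        if not required.issubset(c.columns):
            raise TableValidationError(f"counts table must have columns {sorted(required)}")
        bad = c[c[["n0", "n1", "n2"]].sum(axis=1) != c["n"]]
        if len(bad):
            masses = ", ".join(str(m) for m in bad["diameter_cm"])
            raise TableValidationError(
                f"outcome counts do not sum to n at diameter(s) {masses}")
        if c["diameter_cm"].duplicated().any():
            raise TableValidationError("duplicate diameter rows in counts table")

    @property
    def masses(self) -> np.ndarray:
        return self.counts["diameter_cm"].to_numpy()

    def proportions(self) -> np.ndarray:
        """Observed outcome proportions q_j(M), shape (n_masses, 3)."""
        c = self.counts
        return c[["n0", "n1", "n2"]].to_numpy(dtype=float) / c[["n"]].to_numpy(dtype=float)

    @classmethod
    def from_long(cls, df: pd.DataFrame, strain: str | None = None) -> "ExperimentTable":
        df = df.copy()
        required = {"strain", "diameter_cm", "replicate", "outcome"}
        if not required.issubset(df.columns):
            raise TableValidationError(f"long table must have columns {sorted(required)}")
        if strain is not None:
            df = df[df["strain"] == strain]
        labels = df["strain"].unique()
        if len(labels) != 1:
            raise TableValidationError(
                f"long table must hold one strain, found {sorted(map(str, labels))}")
        df["outcome"] = df["outcome"].map(_normalize_outcome)
        dup = df.duplicated(subset=["diameter_cm", "replicate"])
        if dup.any():
            raise TableValidationError("duplicate (diameter, replicate) keys in long table")
        rows = []
        for diam, grp in df.groupby("diameter_cm", sort=False):
            cnt = grp["outcome"].value_counts()
            rows.append({"diameter_cm": diam,
                         "n0": int(cnt.get("none", 0)),
                         "n1": int(cnt.get("one", 0)),
                         "n2": int(cnt.get("two", 0)),
                         "n": int(len(grp))})
        counts = pd.DataFrame(rows).sort_values("diameter_cm", ascending=False,
                                                ignore_index=True)
        return cls(strain=str(labels[0]), counts=counts, long=df.reset_index(drop=True))


def _normalize_outcome(value) -> str:
    key = str(value).strip().lower()
    if key not in _OUTCOME_ALIASES:
        raise TableValidationError(f"unknown outcome label {value!r}")
    return _OUTCOME_ALIASES[key]


def mixture_probabilities(p_sim: np.ndarray, lam: float) -> np.ndarray:
    """lambda * p_sim + (1 - lambda)/3 on the outcome simplex."""
    p_sim = np.asarray(p_sim, dtype=float)
    if np.any(p_sim < -1e-12) or abs(p_sim.sum(axis=-1).max() - 1.0) > 1e-8 \
            or abs(p_sim.sum(axis=-1).min() - 1.0) > 1e-8:
        raise ValueError("p_sim must lie on the probability simplex")
    if not (0.0 <= lam <= 1.0):
        raise ValueError("lambda must be in [0, 1]")
    return lam * p_sim + (1.0 - lam) / 3.0


def generate_experiment(strain: StrainSpec, design: DesignSpec = DesignSpec()
                        ) -> ExperimentTable:
    """Synthetic outcome table from the simulator/uniform mixture.

    For each mass the simulator's outcome distribution is estimated with
    the strain's settings, mixed with the uniform distribution via the
    strain's lambda, and the design's replicates drawn as independent
    categorical samples.  Deterministic under the design seed.
    """
    root = np.random.SeedSequence(design.seed)
    sim_streams = root.spawn(len(design.masses))
    draw_rng = np.random.default_rng(root.spawn(1)[0])

    long_rows = []
    for M, stream in zip(design.masses, sim_streams):
        seeds = stream.generate_state(strain.n_realisations).astype(np.uint32)
        dist = outcome_distribution(strain.mc_config(M), seeds=seeds)
        probs = mixture_probabilities(dist.as_array(), strain.lam)
        if design.overdispersion > 0.0:
            conc = (1.0 - design.overdispersion) / design.overdispersion
            probs = draw_rng.dirichlet(np.maximum(probs, 1e-12) * conc)
        draws = draw_rng.choice(3, size=design.replicates, p=probs)
        for rep, j in enumerate(draws):
            long_rows.append({"strain": strain.label, "diameter_cm": M,
                              "replicate": rep, "outcome": OUTCOMES[j]})
    return ExperimentTable.from_long(pd.DataFrame(long_rows))


# ---------------------------------------------------------------------------
# readers / writers


def read_table(path: str | Path, strain: str | None = None,
               column_map: dict[str, str] | None = None) -> ExperimentTable:
    """Read an outcome table from CSV/TSV (long or aggregated) or xlsx.

    ``column_map`` renames file columns to the canonical names
    (strain, diameter_cm, replicate, outcome) or
    (strain, diameter_cm, n0, n1, n2[, n]) — the adaptation point for
    supplementary-style spreadsheet layouts.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        df = pd.read_excel(path)
    else:
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
        df = pd.read_csv(path, sep=sep)
    if column_map:
        df = df.rename(columns=column_map)

    if "outcome" in df.columns:
        return ExperimentTable.from_long(df, strain=strain)
    required = {"diameter_cm", "n0", "n1", "n2"}
    if not required.issubset(df.columns):
        raise TableValidationError(
            f"cannot interpret columns {list(df.columns)}: need either an "
            f"'outcome' column (long format) or {sorted(required)} (aggregated)")
    if "strain" in df.columns:
        if strain is not None:
            df = df[df["strain"] == strain]
        labels = df["strain"].unique()
        if len(labels) != 1:
            raise TableValidationError(
                f"aggregated table must hold one strain, found {sorted(map(str, labels))}")
        label = str(labels[0])
    else:
        label = strain or "unknown"
    df = df.copy()
    if "n" not in df.columns:
        df["n"] = df[["n0", "n1", "n2"]].sum(axis=1)
    counts = df[["diameter_cm", "n0", "n1", "n2", "n"]].reset_index(drop=True)
    return ExperimentTable(strain=label, counts=counts)


def write_table(table: ExperimentTable, path: str | Path,
                format: str = "aggregated") -> None:
    """Write a table as CSV/TSV; ``format`` is "aggregated" or "long"
    (long requires per-replicate rows).  Output uses plain decimal points
    regardless of locale (pandas' default C formatting)."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    if format == "aggregated":
        df = table.counts.copy()
        df.insert(0, "strain", table.strain)
    elif format == "long":
        if table.long is None:
            raise ValueError("table has no per-replicate rows to write")
        df = table.long
    else:
        raise ValueError(f"unknown format {format!r}")
    df.to_csv(path, index=False, sep=sep)
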