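import numpy as np
import pandas as pd
import pytest
from scipy import stats

from slimechoice import (DIAMETERS_CM, DesignSpec, ExperimentTable, StrainSpec,
                         TableValidationError, generate_experiment, read_table,
                         write_table)
from slimechoice.data import mixture_probabilities


def quick_strain(lam: float, label: str = "synthetic") -> StrainSpec:
    """Strain with reduced simulator effort for table-structure tests."""
    return StrainSpec(label, k=2.5, T=1.5, lam=lam, n_realisations=100,
                      n_steps=20_000)


class TestStrainSpec:
    def test_invalid_lambda_rejected(self):
        with pytest.raises(ValueError):
            StrainSpec("bad", k=1.0, T=1.0, lam=1.5)

    def test_invalid_rates_rejected(self):
        with pytest.raises(ValueError):
            StrainSpec("bad", k=-1.0, T=1.0, lam=0.5)


class TestDesignSpec:
    def test_defaults_match_experimental_design(self):
        design = DesignSpec()
        assert design.masses == DIAMETERS_CM
        assert design.replicates == 65

    def test_invalid_rejected(self):
        with pytest.raises(ValueError):
            DesignSpec(masses=(1.0, 1.0))
        with pytest.raises(ValueError):
            DesignSpec(replicates=0)
        with pytest.raises(ValueError):
            DesignSpec(overdispersion=1.0)


class TestGenerateExperiment:
    def test_full_design_row_counts(self):
        table = generate_experiment(quick_strain(0.9), DesignSpec(seed=1))
        assert len(table.long) == 650            # 10 masses x 65 replicates
        assert table.counts["n"].sum() == 650
        assert len(table.counts) == 10
        # three strains reproduce the full 1950-trial design
        assert 3 * len(table.long) == 1950

    def test_overdispersion_inflates_between_mass_variability(self):
        # with rho > 0 the per-mass outcome proportions scatter more around
        # the common mixture than the exact-multinomial design allows
        def spread(rho):
            table = generate_experiment(
                quick_strain(0.0),
                DesignSpec(masses=(2.0, 1.8, 1.7, 1.3, 1.0), replicates=65,
                           seed=31, overdispersion=rho))
            return table.proportions().std(axis=0).sum()
        assert spread(0.5) > spread(0.0)

    def test_deterministic_under_seed(self):
        t1 = generate_experiment(quick_strain(0.7), DesignSpec(seed=5))
        t2 = generate_experiment(quick_strain(0.7), DesignSpec(seed=5))
        pd.testing.assert_frame_equal(t1.counts, t2.counts)

    def test_pure_uniform_mixture_is_multinomial_thirds(self):
        # lambda = 0 degenerates to uniform outcomes regardless of simulator
        design = DesignSpec(masses=(2.0, 1.0), replicates=65)
        for seed in range(20):
            table = generate_experiment(quick_strain(0.0),
                                        DesignSpec(masses=design.masses,
                                                   replicates=65, seed=seed))
            counts = table.counts[["n0", "n1", "n2"]].to_numpy().sum(axis=0)
            p = stats.chisquare(counts).pvalue
            assert p > 0.001

    def test_proportions_converge_to_mixture(self):
        # law of large numbers at 10^4 replicates per mass
        strain = StrainSpec("synthetic", k=2.5, T=1.5, lam=0.8,
                            n_realisations=2000)
        design = DesignSpec(masses=(4.0, 2.0), replicates=10_000, seed=9)
        table = generate_experiment(strain, design)
        for i, M in enumerate(design.masses):
            seeds = np.random.SeedSequence(design.seed).spawn(2)[i] \
                .generate_state(2000).astype(np.uint32)
            from slimechoice.montecarlo import outcome_distribution
            dist = outcome_distribution(strain.mc_config(M), seeds=seeds)
            target = mixture_probabilities(dist.as_array(), 0.8)
            got = table.proportions()[i]
            assert np.max(np.abs(got - target)) <= 0.02


class TestTableValidation:
    def test_count_mismatch_names_the_mass(self):
        counts = pd.DataFrame({"diameter_cm": [4.0, 2.0], "n0": [10, 5],
                               "n1": [50, 55], "n2": [6, 5], "n": [65, 65]})
        with pytest.raises(TableValidationError, match="4.0"):
            ExperimentTable(strain="x", counts=counts)

    def test_unknown_outcome_label(self):
        df = pd.DataFrame({"strain": ["s"], "diameter_cm": [4.0],
                           "replicate": [0], "outcome": ["maybe"]})
        with pytest.raises(TableValidationError, match="maybe"):
            ExperimentTable.from_long(df)

    def test_duplicate_replicate_keys(self):
        df = pd.DataFrame({"strain": ["s", "s"], "diameter_cm": [4.0, 4.0],
                           "replicate": [0, 0], "outcome": ["one", "two"]})
        with pytest.raises(TableValidationError, match="duplicate"):
            ExperimentTable.from_long(df)

    def test_outcome_vocabulary_normalized(self):
        df = pd.DataFrame({"strain": ["s"] * 3, "diameter_cm": [4.0] * 3,
                           "replicate": [0, 1, 2],
                           "outcome": ["Zero", "BOTH", "1"]})
        table = ExperimentTable.from_long(df)
        row = table.counts.iloc[0]
        assert (row["n0"], row["n1"], row["n2"]) == (1, 1, 1)


class TestReadWrite:
    @pytest.fixture
    def table(self):
        return generate_experiment(quick_strain(0.5),
                                   DesignSpec(masses=(2.0, 1.0),
                                              replicates=20, seed=2))

    @pytest.mark.parametrize("fmt,suffix", [("long", ".csv"),
                                            ("aggregated", ".csv"),
                                            ("long", ".tsv")])
    def test_round_trip(self, tmp_path, table, fmt, suffix):
        path = tmp_path / f"table{suffix}"
        write_table(table, path, format=fmt)
        back = read_table(path)
        assert back.strain == table.strain
        assert np.allclose(back.proportions(), table.proportions())

    def test_long_and_aggregated_agree(self, tmp_path, table):
        p_long = tmp_path / "long.csv"
        p_agg = tmp_path / "agg.csv"
        write_table(table, p_long, format="long")
        write_table(table, p_agg, format="aggregated")
        assert np.allclose(read_table(p_long).proportions(),
                           read_table(p_agg).proportions())

    def test_xlsx_ingestion_with_column_map(self, tmp_path, table):
        path = tmp_path / "raw.xlsx"
        df = table.long.rename(columns={"diameter_cm": "size (cm)",
                                        "outcome": "choice"})
        df.to_excel(path, index=False)
        back = read_table(path, column_map={"size (cm)": "diameter_cm",
                                            "choice": "outcome"})
        assert np.allclose(back.proportions(), table.proportions())

    def test_missing_file_and_bad_columns(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_table(tmp_path / "absent.csv")
        bad = tmp_path / "bad.csv"
        pd.DataFrame({"a": [1]}).to_csv(bad, index=False)
        with pytest.raises(TableValidationError):
            read_table(bad)
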