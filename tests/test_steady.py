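import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from slimechoice import (CriticalMasses, ModelParams, State, all_steady_states,
                         critical_masses, homogeneous, integrate,
                         nonhomogeneous, rhs, semi_trivial, stability, trivial)
from conftest import random_params
from _oracles import newton_multistart, scalar_root_scan


class TestSemiTrivial:
    def test_empty_below_first_critical_mass(self, japan):
        cm = critical_masses(japan)
        assert semi_trivial(japan.with_mass(0.9 * cm.M1)) == []

    def test_known_roots(self):
        # (k+d) X^2 - k M X + d T^2 = 0 at k=d=T=1, M=4: X = 1 +/- sqrt(2)/2
        p = ModelParams(k=1, d=1, T=1, n=2, M=4)
        states = semi_trivial(p)
        xs = sorted(s.X1 for s in states)
        assert xs == pytest.approx([1 - np.sqrt(2) / 2, 1 + np.sqrt(2) / 2])
        assert all(s.X2 == 0.0 for s in states)
        # the same roots from a brute-force scan of the scalar condition
        oracle = scalar_root_scan(
            lambda x: 1 * (4 - x) * x**2 / (1 + x**2) - x, 1e-6, 4.0)
        assert sorted(oracle) == pytest.approx(xs, abs=1e-9)

    def test_double_root_at_limit_point(self, japan):
        cm = critical_masses(japan)
        states = semi_trivial(japan.with_mass(cm.M1))
        assert len(states) == 1 and states[0].degenerate


class TestHomogeneous:
    def test_empty_below_second_critical_mass(self, japan):
        cm = critical_masses(japan)
        assert homogeneous(japan.with_mass(0.99 * cm.M2)) == []

    def test_known_roots(self):
        # (2k+d) X^2 - k M X + d T^2 = 0 at k=d=T=1, M=6: X = (6 +/- sqrt(24))/6
        p = ModelParams(k=1, d=1, T=1, n=2, M=6)
        xs = sorted(s.X1 for s in homogeneous(p))
        assert xs == pytest.approx([(6 - np.sqrt(24)) / 6, (6 + np.sqrt(24)) / 6])

    def test_large_mass_asymptote(self, japan):
        p = japan.with_mass(1e3 * japan.T)
        upper = max(homogeneous(p), key=lambda s: s.X1)
        assert upper.X1 * (2 * p.k + p.d) / (p.k * p.M) == pytest.approx(1.0, rel=1e-2)


class TestNonhomogeneous:
    def test_empty_at_or_below_pitchfork(self, japan):
        cm = critical_masses(japan)
        assert nonhomogeneous(japan.with_mass(0.99 * cm.M3)) == []

    def test_degenerate_merge_at_pitchfork(self, japan):
        cm = critical_masses(japan)
        states = nonhomogeneous(japan.with_mass(cm.M3))
        assert len(states) == 1 and states[0].degenerate
        # merges with the homogeneous upper branch exactly at (T, T)
        assert states[0].X1 == pytest.approx(japan.T, abs=1e-9)
        upper = max(homogeneous(japan.with_mass(cm.M3)), key=lambda s: s.X1)
        assert upper.X1 == pytest.approx(japan.T, abs=1e-9)

    def test_known_pair_and_branch_identities(self):
        p = ModelParams(k=2.5, d=1, T=1.5, n=2, M=6)
        states = nonhomogeneous(p)
        assert len(states) == 2
        S = p.k * p.M / (p.k + p.d)  # 30/7
        for s in states:
            assert s.X1 * s.X2 == pytest.approx(p.T**2, abs=1e-10)
            assert s.X1 + s.X2 == pytest.approx(S, abs=1e-10)
            assert not s.stable
        assert states[0].X1 == pytest.approx(states[1].X2)

    @settings(deadline=None, max_examples=25)
    @given(seed=st.integers(0, 10_000))
    def test_identities_on_random_draws(self, seed):
        p = random_params(np.random.default_rng(seed), M_factor=1.5)
        for s in nonhomogeneous(p):
            assert s.X1 * s.X2 == pytest.approx(p.T**2, abs=1e-10 * max(1, p.T**2))
            assert s.X1 + s.X2 == pytest.approx(p.k * p.M / (p.k + p.d), abs=1e-9)


class TestCriticalMasses:
    def test_strain_values(self):
        # closed forms at the strains' best-fit rates (d = 1, n = 2)
        assert critical_masses(ModelParams(k=2.5, T=1.5, M=1)).M3 == pytest.approx(4.2)
        assert critical_masses(ModelParams(k=1.5, T=0.9, M=1)).M3 == pytest.approx(3.0)
        assert critical_masses(ModelParams(k=1.5, T=1.2, M=1)).M3 == pytest.approx(4.0)

    @given(seed=st.integers(0, 10_000))
    def test_ordering(self, seed):
        p = random_params(np.random.default_rng(seed))
        cm = critical_masses(p)
        assert 0 < cm.M1 < cm.M2 < cm.M3

    def test_invalid_ordering_rejected(self):
        with pytest.raises(ValueError):
            CriticalMasses(M1=2.0, M2=1.0, M3=3.0)

    def test_branch_existence_flips_at_closed_forms(self, japan):
        cm = critical_masses(japan)
        eps = 1e-7
        assert semi_trivial(japan.with_mass(cm.M1 + eps)) \
            and not semi_trivial(japan.with_mass(cm.M1 - eps))
        assert homogeneous(japan.with_mass(cm.M2 + eps)) \
            and not homogeneous(japan.with_mass(cm.M2 - eps))
        assert nonhomogeneous(japan.with_mass(cm.M3 + eps)) \
            and not nonhomogeneous(japan.with_mass(cm.M3 - eps))


class TestStability:
    def test_trivial_double_eigenvalue(self, japan):
        s = trivial(japan)
        assert s.stable
        assert s.eigenvalues[0] == s.eigenvalues[1] == -japan.d

    def test_non_equilibrium_rejected(self, japan):
        with pytest.raises(ValueError):
            stability(State(1.0, 1.0), japan)

    def test_branch_stability_pattern(self, japan):
        cm = critical_masses(japan)
        # semi-trivial: upper stable, lower unstable (any M > M1)
        for M in (0.5 * (cm.M1 + cm.M2), 2 * cm.M3):
            st_states = semi_trivial(japan.with_mass(M))
            upper = max(st_states, key=lambda s: s.X1)
            lower = min(st_states, key=lambda s: s.X1)
            assert upper.stable and not lower.stable
        # homogeneous upper: unstable between M2 and M3, stable past M3
        mid = japan.with_mass(0.5 * (cm.M2 + cm.M3))
        assert not max(homogeneous(mid), key=lambda s: s.X1).stable
        past = japan.with_mass(1.3 * cm.M3)
        assert max(homogeneous(past), key=lambda s: s.X1).stable
        assert not min(homogeneous(past), key=lambda s: s.X1).stable
        # nonhomogeneous: always unstable
        assert all(not s.stable for s in nonhomogeneous(past))


class TestInventory:
    @pytest.mark.parametrize("factor,count", [(0.4, 1), (0.85, 5), (0.97, 7),
                                              (1.5, 9)])
    def test_counts_by_regime(self, japan, factor, count):
        # factors chosen relative to (M1, M2, M3) = (2.245, 2.939, 4.2)/M3
        cm = critical_masses(japan)
        masses = {0.4: 0.5 * cm.M1, 0.85: 0.5 * (cm.M1 + cm.M2),
                  0.97: 0.5 * (cm.M2 + cm.M3), 1.5: 1.5 * cm.M3}
        states = all_steady_states(japan.with_mass(masses[factor]))
        assert len(states) == count
        for s in states:
            assert np.linalg.norm(rhs((s.X1, s.X2), japan.with_mass(masses[factor]))) < 1e-9

    def test_matches_newton_oracle_small(self):
        rng = np.random.default_rng(123)
        for _ in range(20):
            p = random_params(rng)
            mine = np.array([[s.X1, s.X2] for s in all_steady_states(p)])
            oracle = newton_multistart(p.k, p.d, p.T, p.n, p.M)
            assert len(mine) == len(oracle)
            for pt in oracle:
                assert np.min(np.linalg.norm(mine - pt, axis=1)) < 1e-6


class TestGeneralExponent:
    def test_branches_are_equilibria_for_n3(self):
        p = ModelParams(k=2.0, d=1.0, T=1.2, n=3, M=5.0)
        states = all_steady_states(p)
        assert len(states) >= 5
        for s in states:
            assert np.linalg.norm(rhs((s.X1, s.X2), p)) < 1e-8

    def test_matches_newton_oracle_for_n3(self):
        p = ModelParams(k=2.0, d=1.0, T=1.2, n=3, M=5.0)
        mine = np.array([[s.X1, s.X2] for s in all_steady_states(p)])
        oracle = newton_multistart(p.k, p.d, p.T, p.n, p.M)
        assert len(mine) == len(oracle)
        for pt in oracle:
            assert np.min(np.linalg.norm(mine - pt, axis=1)) < 1e-6

    def test_critical_mass_ordering_for_n3(self):
        cm = critical_masses(ModelParams(k=2.0, d=1.0, T=1.2, n=3, M=1.0))
        assert 0 < cm.M1 < cm.M2 < cm.M3


class TestDynamicalConsistency:
    def test_terminal_states_are_stable_equilibria(self, japan):
        p = japan.with_mass(6.0)
        rng = np.random.default_rng(5)
        stable = [(s.X1, s.X2) for s in all_steady_states(p) if s.stable]
        unstable = [(s.X1, s.X2) for s in all_steady_states(p) if not s.stable]
        for _ in range(20):
            u = rng.random(2)
            if u.sum() > 1:
                u = 1 - u
            traj = integrate(p, tuple(u * p.M), t_end=600.0)
            if traj.terminal_rhs_norm() < 1e-9:
                x = traj.terminal.as_array()
                d_stable = min(np.linalg.norm(x - np.array(s)) for s in stable)
                d_unstable = min(np.linalg.norm(x - np.array(s)) for s in unstable)
                assert d_stable < 1e-5
                assert d_unstable > 1e-2
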