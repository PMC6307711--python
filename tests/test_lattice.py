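"""Unit and property tests for the stochastic lattice model."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from chiralgrowth import (
    LatticeConfig,
    LatticeState,
    Simulation,
    StrainParams,
    demographic_sampling,
    deterministic_update,
    directional_flux,
    drift_sampling,
    growth_increment,
    init_circular_colony,
    init_linear_front,
    migration_increment,
)
from chiralgrowth.lattice import front_row

from conftest import random_state_pair
from _reference import naive_deterministic_update


class TestStrainParams:
    def test_chirality_and_motility(self):
        p = StrainParams(g=0.1, ml=0.09, mr=0.01)
        assert p.chirality == pytest.approx(0.08)
        assert p.motility == pytest.approx(0.10)
        assert p.mirrored().chirality == pytest.approx(-0.08)

    @pytest.mark.parametrize("bad", [dict(g=-0.1), dict(g=0.1, ml=-0.01),
                                     dict(g=0.1, m0=0.5, ms=0.6)])
    def test_invalid_parameters_rejected(self, bad):
        with pytest.raises(ValueError):
            StrainParams(**bad)


class TestGrowthIncrement:
    @pytest.mark.parametrize("n_a, n_tot, expected", [
        (50, 200, 0.0),    # at carrying capacity
        (0, 100, 0.0),     # empty strain
        (50, 100, 2.5),    # g n (1 - n/N)
    ])
    def test_logistic_values(self, n_a, n_tot, expected):
        p = StrainParams(g=0.1)
        assert growth_increment(n_a, n_tot, p, N=200) == pytest.approx(expected)

    def test_invalid_state_rejected(self):
        p = StrainParams(g=0.1)
        with pytest.raises(ValueError):
            growth_increment(-1, 10, p, N=200)
        with pytest.raises(ValueError):
            growth_increment(10, 300, p, N=200)


class TestDirectionalFlux:
    def test_full_destination_blocks_migration(self):
        p = StrainParams(g=0.1, m0=0.02, ml=0.05)
        assert directional_flux(50, 50, 100, 80, 10, 5, p, N=100) == 0.0

    def test_left_bias_value(self):
        # purely left-dependent migration: n_src (1 - 0) * ml * n_left/N
        p = StrainParams(g=0.03, ml=0.045, mr=0.005)
        flux = directional_flux(100, 100, 0, 100, 0, 0, p, N=100)
        assert flux == pytest.approx(4.5)

    def test_no_migration_without_coefficients(self, rng):
        p = StrainParams(g=0.1)
        nb = rng.integers(0, 100, size=5)
        assert directional_flux(70, *nb, p, N=100) == 0.0


class TestMigrationIncrement:
    def test_uniform_field_balances(self):
        p = StrainParams(g=0.1, m0=0.01, ms=0.02, ml=0.05, mr=0.01)
        n = np.full((6, 8), 20.0)
        # interior rows: all fluxes cancel by symmetry
        M = migration_increment(n, n, p, N=100)
        assert np.allclose(M[1:-1], 0.0, atol=1e-12)

    def test_conserves_total_cells(self, rng):
        p = StrainParams(g=0.1, m0=0.01, ms=0.01, md=0.01, ml=0.06, mb=0.01,
                         mr=0.02)
        n1, n2 = random_state_pair(rng, 12, 9, N=40)
        M = migration_increment(n1, n1 + n2, p, N=40)
        assert abs(M.sum()) < 1e-9 * 40 * M.size

    def test_isolated_site_spreads_equally(self):
        p = StrainParams(g=0.0, m0=0.03)
        n = np.zeros((5, 5))
        n[2, 2] = 10.0
        M = migration_increment(n, n, p, N=100)
        assert M[2, 2] == pytest.approx(-4 * 0.03 * 10.0)
        for dy, dx in ((0, 1), (0, -1), (1, 0), (-1, 0)):
            assert M[2 + dy, 2 + dx] == pytest.approx(0.03 * 10.0)


class TestDeterministicUpdate:
    def test_all_zero_state(self, fig_strains):
        z = np.zeros((6, 6))
        r1, r2 = deterministic_update(z, z, *fig_strains, N=100)
        assert not r1.any() and not r2.any()

    def test_identity_without_growth_or_migration(self, rng):
        p = StrainParams(g=0.0)
        n1, n2 = random_state_pair(rng, 8, 8, N=30)
        r1, r2 = deterministic_update(n1, n2, p, p, N=30)
        assert np.array_equal(r1, n1.astype(float))
        assert np.array_equal(r2, n2.astype(float))

    def test_matches_naive_reference(self, rng, fig_strains):
        p1, p2 = fig_strains
        for _ in range(5):
            n1, n2 = random_state_pair(rng, 10, 10, N=200)
            r1, r2 = deterministic_update(n1, n2, p1, p2, N=200, warn=False)
            e1, e2 = naive_deterministic_update(n1, n2, p1, p2, N=200)
            np.testing.assert_allclose(r1, e1, atol=1e-10)
            np.testing.assert_allclose(r2, e2, atol=1e-10)

    def test_mirror_symmetry_bitwise(self, rng, fig_strains):
        p1, p2 = fig_strains
        n1, n2 = random_state_pair(rng, 10, 10, N=200)
        r1, r2 = deterministic_update(n1, n2, p1, p2, N=200, warn=False)
        m1, m2 = deterministic_update(n1[:, ::-1], n2[:, ::-1],
                                      p1.mirrored(), p2.mirrored(), N=200,
                                      warn=False)
        assert np.array_equal(m1, r1[:, ::-1])
        assert np.array_equal(m2, r2[:, ::-1])

    def test_rotation_equivariance(self, rng):
        # direction-relative coefficients make the four lattice directions
        # equivalent: rotating the configuration commutes with the update.
        # states supported away from the edges so that the x/y boundary
        # conditions cannot be probed
        p1 = StrainParams(g=0.2, m0=0.01, ms=0.02, md=0.01, ml=0.06, mb=0.03,
                          mr=0.02)
        p2 = StrainParams(g=0.1, ml=0.01, mr=0.07)
        n1 = np.zeros((12, 12))
        n2 = np.zeros((12, 12))
        a, b = random_state_pair(rng, 6, 6, N=50)
        n1[3:9, 3:9] = a
        n2[3:9, 3:9] = b
        r1, r2 = deterministic_update(n1, n2, p1, p2, N=50, warn=False)
        q1, q2 = deterministic_update(np.rot90(n1), np.rot90(n2), p1, p2,
                                      N=50, warn=False)
        np.testing.assert_allclose(q1, np.rot90(r1), atol=1e-12)
        np.testing.assert_allclose(q2, np.rot90(r2), atol=1e-12)

    @settings(max_examples=25, deadline=None)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_bounds_hold_for_random_states(self, seed):
        rng = np.random.default_rng(seed)
        p1 = StrainParams(g=0.1, ml=0.09, mr=0.01)
        p2 = StrainParams(g=0.1, ml=0.01, mr=0.09)
        n1, n2 = random_state_pair(rng, 8, 8, N=20)
        r1, r2 = deterministic_update(n1, n2, p1, p2, N=20, warn=False)
        assert (r1 >= 0).all() and (r2 >= 0).all()
        assert (r1 + r2 <= 20 + 1e-9).all()


class TestStochasticRounds:
    def test_absorbing_endpoints(self, rng):
        z = np.zeros((4, 4))
        assert not demographic_sampling(z, z, 100, rng).any()
        full = np.full((4, 4), 60.0)
        n = demographic_sampling(full, 40.0 + z, 100, rng)
        assert (n == 100).all()
        n1, n2 = drift_sampling(n, z, full, rng)
        assert not n1.any() and (n2 == 100).all()
        n1, n2 = drift_sampling(n, full, z, rng)
        assert (n1 == 100).all() and not n2.any()

    def test_binomial_moments(self, rng):
        N = 100
        rho1 = np.full(100_000, 25.0)
        rho2 = np.full(100_000, 25.0)
        n = demographic_sampling(rho1, rho2, N, rng)
        se = np.sqrt(N * 0.5 * 0.5 / n.size)
        assert abs(n.mean() - 50.0) < 3 * se
        n1, _ = drift_sampling(n, rho1, rho2, rng)
        se1 = np.sqrt(n.mean() * 0.25 / n.size)
        assert abs(n1.mean() - n.mean() / 2) < 3 * se1

    def test_invalid_probability_detected(self, rng):
        with pytest.raises(RuntimeError):
            demographic_sampling(np.full((2, 2), 80.0), np.full((2, 2), 80.0),
                                 100, rng)


class TestInitialConditions:
    def test_single_strain_initialization(self, small_config):
        state = init_linear_front(small_config, f0=0.0)
        assert not state.n1.any()
        assert (state.n2[:8] == small_config.N).all()

    def test_well_mixed_fraction(self, small_config):
        cfg = small_config
        state = init_linear_front(cfg, f0=0.5, rng=np.random.default_rng(0))
        total = state.n1[:8].sum() + state.n2[:8].sum()
        f = state.n1[:8].sum() / total
        se = np.sqrt(0.25 / total)
        assert abs(f - 0.5) < 4 * se

    def test_two_domains_topology(self, small_config):
        state = init_linear_front(small_config, f0=0.5, mode="two_domains")
        row1 = state.n1[0] > 0
        assert row1.sum() == small_config.width // 2
        # one contiguous domain on a periodic ring -> exactly two boundaries
        assert np.count_nonzero(row1 != np.roll(row1, 1)) == 2

    def test_geometry_errors(self, small_config):
        with pytest.raises(ValueError):
            init_linear_front(small_config, f0=1.5)
        with pytest.raises(ValueError):
            init_linear_front(small_config, f0=0.5, mode="single_patch",
                              patch_width=small_config.width + 1)
        with pytest.raises(ValueError):
            init_circular_colony(small_config, radius=100, f0=0.5)

    def test_circular_colony_population(self):
        cfg = LatticeConfig(width=201, height=201, N=50)
        state = init_circular_colony(cfg, radius=30, f0=0.5,
                                     rng=np.random.default_rng(1))
        cells = state.n1.sum() + state.n2.sum()
        expected = np.pi * 30 ** 2 * 50
        assert abs(cells - expected) / expected < 0.05
        assert state.r_front == pytest.approx(30.0)


class TestStep:
    def test_reproducible_runs(self, small_config, fig_strains):
        finals = []
        for _ in range(2):
            sim = Simulation(small_config, *fig_strains, seed=11)
            sim.init_linear_front(0.5)
            sim.run(60)
            finals.append((sim.state.n1.copy(), sim.state.n2.copy()))
        assert np.array_equal(finals[0][0], finals[1][0])
        assert np.array_equal(finals[0][1], finals[1][1])

    def test_absorbing_state_persists(self, small_config, fig_strains):
        sim = Simulation(small_config, *fig_strains, seed=3)
        sim.init_linear_front(0.0)
        sim.run(80)
        assert not sim.state.n1.any()

    def test_frozen_rows_untouched(self, small_config, fig_strains):
        sim = Simulation(small_config, *fig_strains, seed=5)
        sim.init_linear_front(0.5)
        sim.run(600)
        state = sim.state
        assert state.y_lo > 0  # window has advanced
        frozen1 = state.n1[:state.y_lo].copy()
        sim.run(100)
        assert np.array_equal(state.n1[:state.y_lo], frozen1[:state.y_lo])

    def test_neutral_competition_is_a_martingale(self):
        # identical strains: the expected global fraction stays at f0 while
        # its replicate-to-replicate variance grows with time
        p = StrainParams(g=0.2, ml=0.05, mr=0.05)
        cfg = LatticeConfig(width=30, height=80, N=20)
        early, late = [], []
        for rep in range(40):
            sim = Simulation(cfg, p, p, seed=100 + rep)
            sim.init_linear_front(0.5)
            sim.run(30)
            st = sim.state
            early.append(st.n1.sum() / max(st.n1.sum() + st.n2.sum(), 1))
            sim.run(120)
            st = sim.state
            late.append(st.n1.sum() / max(st.n1.sum() + st.n2.sum(), 1))
        late = np.asarray(late)
        se = late.std(ddof=1) / np.sqrt(late.size)
        assert abs(late.mean() - 0.5) < 3.5 * se
        assert late.std(ddof=1) > np.asarray(early).std(ddof=1)

    def test_front_row_tracks_leading_edge(self, small_config, fig_strains):
        sim = Simulation(small_config, *fig_strains, seed=2)
        sim.init_linear_front(0.5)
        f0 = front_row(sim.state)
        sim.run(150)
        assert front_row(sim.state) > f0
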