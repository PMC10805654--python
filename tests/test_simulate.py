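"""Three-gene circuit and linear-field fixture generators."""

import numpy as np
import pytest

from wfrflow.data import TimeSeriesDataset
from wfrflow.simulate import (
    QUIESCENT,
    TRANSITION,
    CellPopulation,
    ThreeGeneParams,
    divide,
    division_probability,
    drift,
    simulate_linear_field,
    simulate_three_gene,
    step_em,
)


@pytest.fixture(scope="module")
def params():
    return ThreeGeneParams()


class TestDrift:
    def test_at_origin_only_signal_terms_survive(self, params):
        # all quadratic Hill terms vanish at zero expression
        S = params.S
        d = drift(np.zeros(3), params)
        assert d[0] == pytest.approx(S / (1 + S))
        assert d[1] == pytest.approx(S / (1 + S))
        assert d[2] == pytest.approx(0.0)

    def test_large_C_saturates_inhibition(self, params):
        d = drift(np.array([0.0, 0.0, 1e6]), params)
        # production of A and B is crushed by the C^2 inhibition term
        assert abs(d[0]) < 1e-9
        assert abs(d[1]) < 1e-9
        # C itself saturates self-activation at 1 and decays linearly
        assert d[2] == pytest.approx(1.0 - params.d_C * 1e6)

    def test_matches_symbolic_evaluation(self, params):
        sympy = pytest.importorskip("sympy")
        A, B, C = sympy.symbols("A B C", nonnegative=True)
        p = params
        exprs = [
            (p.C_A * A**2 + p.S) / (1 + p.C_A * A**2 + p.H_B * B**2 + p.H_C * C**2 + p.S)
            - p.d_A * A,
            (p.C_B * B**2 + p.S) / (1 + p.H_A * A**2 + p.C_B * B**2 + p.H_C * C**2 + p.S)
            - p.d_B * B,
            p.C_C * C**2 / (1 + p.C_C * C**2) - p.d_C * C,
        ]
        state = np.array([1.0, 1.0, 0.0])
        expected = [
            float(e.subs({A: state[0], B: state[1], C: state[2]})) for e in exprs
        ]
        np.testing.assert_allclose(drift(state, params), expected, rtol=1e-12)

    def test_negative_state_rejected(self, params):
        with pytest.raises(ValueError):
            drift(np.array([-0.1, 0.0, 0.0]), params)

    def test_batch_matches_single(self, params, rng):
        states = rng.uniform(0, 2, size=(6, 3))
        batch = drift(states, params)
        for i in range(6):
            np.testing.assert_allclose(batch[i], drift(states[i], params))


class TestStepEM:
    def test_zero_noise_reduces_to_explicit_euler(self):
        p = ThreeGeneParams(sigma_A=0.0, sigma_B=0.0, sigma_C=0.0)
        pop = CellPopulation(np.array([[1.0, 0.5, 0.2]]), np.array([0]))
        out = step_em(pop, p, np.random.default_rng(3))
        expected = pop.states + p.dt * drift(pop.states, p)
        np.testing.assert_allclose(out.states, expected)
        assert out.time == pytest.approx(p.dt)

    def test_noise_increments_have_correct_moments(self):
        # degradation-free, signal-free circuit at the origin: A's drift is
        # S/(1+S); subtracting it leaves pure noise with sd sigma_A*sqrt(dt)
        p = ThreeGeneParams(S=0.0)
        n = 4000
        pop = CellPopulation(np.zeros((n, 3)), np.arange(n))
        out = step_em(pop, p, np.random.default_rng(11))
        # at the origin the drift of gene C is exactly 0; its increment is
        # pure clipped noise, so use gene A shifted by its known drift
        incr = out.states[:, 0] - p.dt * drift(np.zeros(3), p)[0]
        # clipping at zero truncates the Gaussian: compare against the
        # truncated-normal moments instead of the raw ones
        sd = p.sigma_A * np.sqrt(p.dt)
        drift_a = p.dt * drift(np.zeros(3), p)[0]
        raw = drift_a + sd * np.random.default_rng(99).standard_normal(200000)
        expected_mean = np.clip(raw, 0, None).mean() - drift_a
        assert incr.mean() == pytest.approx(expected_mean, abs=4 * sd / np.sqrt(n))

    def test_negative_expression_clipped_to_zero(self):
        p = ThreeGeneParams(S=0.0, sigma_A=0.0, sigma_B=0.0, sigma_C=0.0,
                            d_A=10.0)
        pop = CellPopulation(np.array([[0.001, 0.0, 0.0]]), np.array([0]))
        out = step_em(pop, p, np.random.default_rng(0))
        assert out.states[0, 0] == 0.0
        assert np.all(out.states >= 0)


class TestDivide:
    def test_no_division_when_B_is_zero(self, params):
        pop = CellPopulation(np.array([[1.0, 0.0, 0.5]] * 50), np.arange(50))
        for seed in range(5):
            out = divide(pop, params, np.random.default_rng(seed))
            assert out.n_cells == 50

    def test_probability_saturates_at_one_percent(self):
        assert division_probability(1e9) == pytest.approx(0.01)
        assert division_probability(1.0) == pytest.approx(0.005)

    def test_growth_rate_matches_hill_probability(self, params):
        # homogeneous B=1 population: expected growth 0.5% per step
        n, steps = 2000, 10
        pop = CellPopulation(
            np.tile([0.0, 1.0, 0.0], (n, 1)), np.arange(n)
        )
        rng = np.random.default_rng(7)
        for _ in range(steps):
            pop = divide(pop, params, rng)
        rate = (pop.n_cells / n) ** (1 / steps) - 1
        assert rate == pytest.approx(0.005, abs=3 * np.sqrt(0.005 / (n * steps)))

    def test_children_inherit_lineage(self, params):
        pop = CellPopulation(np.tile([0.0, 5.0, 0.0], (500, 1)), np.arange(500))
        out = divide(pop, params, np.random.default_rng(1))
        assert out.n_cells > 500  # ~1% per-step division at high B
        assert set(out.lineage_ids) <= set(range(500))


class TestSimulateThreeGene:
    def test_zero_horizon_returns_initial_mixture(self):
        ds, gt = simulate_three_gene(n_per_group=(100, 100),
                                     snapshot_times=(0.0,), seed=3)
        assert len(ds) == 1
        assert ds[0].n_cells == 200
        X = ds[0].X
        lab = gt.group_labels[0]
        np.testing.assert_allclose(
            X[lab == TRANSITION].mean(axis=0), [2, 0.2, 0], atol=0.05
        )
        np.testing.assert_allclose(
            X[lab == QUIESCENT].mean(axis=0), [0, 0, 2], atol=0.05
        )

    def test_off_grid_snapshot_time_rejected(self):
        with pytest.raises(ValueError):
            simulate_three_gene(snapshot_times=(0.0, 0.3), seed=0)

    def test_seeded_runs_are_bit_identical(self):
        ds1, _ = simulate_three_gene(n_per_group=(30, 30),
                                     snapshot_times=(0, 10), seed=5)
        ds2, _ = simulate_three_gene(n_per_group=(30, 30),
                                     snapshot_times=(0, 10), seed=5)
        for s1, s2 in zip(ds1, ds2):
            np.testing.assert_array_equal(s1.X, s2.X)

    def test_snapshots_are_nonnegative_and_mass_grows_only_by_division(self):
        ds, gt = simulate_three_gene(n_per_group=(50, 50), seed=2)
        for s in ds:
            assert np.all(s.X >= 0)
        counts = [s.n_cells for s in ds]
        assert all(c2 >= c1 for c1, c2 in zip(counts, counts[1:]))

    def test_transition_over_quiescent_ratio_increases(self):
        # across seeds, the dividing group outgrows the static one
        ratios = []
        for seed in range(5):
            _, gt = simulate_three_gene(n_per_group=(60, 60), seed=seed)
            ratios.append(gt.ratio())
        mean_ratio = np.mean(ratios, axis=0)
        assert np.all(np.diff(mean_ratio) > 0)

    def test_quiescent_group_stays_near_its_start(self):
        for seed in range(5):
            ds, gt = simulate_three_gene(n_per_group=(40, 40), seed=seed)
            m0 = ds[0].X[gt.group_labels[0] == QUIESCENT].mean(axis=0)
            mT = ds[-1].X[gt.group_labels[-1] == QUIESCENT].mean(axis=0)
            assert np.linalg.norm(mT - m0, np.inf) < 0.2

    def test_transition_group_moves_from_A_to_B(self):
        ds, gt = simulate_three_gene(n_per_group=(60, 60), seed=1)
        a_means = [s.X[lab == TRANSITION][:, 0].mean()
                   for s, lab in zip(ds, gt.group_labels)]
        b_means = [s.X[lab == TRANSITION][:, 1].mean()
                   for s, lab in zip(ds, gt.group_labels)]
        assert all(np.diff(a_means) < 0)
        assert all(np.diff(b_means) > 0)


class TestLinearFieldFixture:
    def test_static_field_keeps_density_constant(self, rng):
        ds, truth = simulate_linear_field(
            np.zeros((2, 2)), 0.0, [1.0, -1.0], np.eye(2), (0, 1, 2), 50, seed=0
        )
        x = rng.normal(size=(5, 2))
        np.testing.assert_allclose(truth.density(x, 0.0), truth.density(x, 2.0))

    def test_contracting_field_shrinks_covariance(self):
        _, truth = simulate_linear_field(
            -np.eye(2), 0.0, [0.0, 0.0], 2 * np.eye(2), (0, 1), 10, seed=0
        )
        np.testing.assert_allclose(truth.cov(1.0), 2 * np.exp(-2) * np.eye(2),
                                   rtol=1e-12)

    def test_uniform_growth_doubles_mass(self):
        T = 3.0
        _, truth = simulate_linear_field(
            np.zeros((1, 1)), np.log(2) / T, [0.0], np.eye(1), (0, T), 10, seed=0
        )
        assert truth.mass(T) == pytest.approx(2.0)

    def test_snapshot_masses_follow_growth(self):
        ds, truth = simulate_linear_field(
            np.zeros((2, 2)), 0.5, [0, 0], np.eye(2), (0, 1, 2), 20, seed=1
        )
        np.testing.assert_allclose(ds.masses, [1, np.exp(0.5), np.exp(1.0)])

    def test_nonsquare_or_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            simulate_linear_field(np.ones((2, 3)), 0, [0, 0], np.eye(2), (0, 1), 5)
        with pytest.raises(ValueError):
            simulate_linear_field(np.eye(2), 0, [0, 0], np.zeros((2, 2)), (0, 1), 5)


def test_dataset_requires_increasing_times():
    from wfrflow.data import Snapshot

    with pytest.raises(ValueError):
        TimeSeriesDataset([Snapshot(1.0, np.ones((2, 2))),
                           Snapshot(0.5, np.ones((2, 2)))])
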