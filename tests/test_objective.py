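"""Transport-growth cost and reconstruction-error oracles."""

import numpy as np
import pytest

from wfrflow.density import GaussianMixtureDensity
from wfrflow.fields import FieldPair
from wfrflow.objective import (
    reconstruction_error_pair,
    total_loss,
    total_reconstruction_error,
    wfr_interval_cost,
    wfr_total_cost,
)

from conftest import AnalyticField


def constant_velocity_field(c):
    c = np.asarray(c, dtype=np.float64)
    return AnalyticField(len(c), v=lambda X, t: np.tile(c, (X.shape[0], 1)))


def uniform_growth_field(d, gamma):
    return AnalyticField(d, g=lambda X, t: np.full(X.shape[0], gamma))


@pytest.fixture
def gauss2(rng):
    return GaussianMixtureDensity(rng.normal(size=(8, 2)), 0.5, mass=1.0)


class TestWFRCost:
    def test_zero_fields_cost_nothing(self, gauss2):
        assert wfr_interval_cost(AnalyticField(2), gauss2, 0.0, 1.0) == 0.0

    @pytest.mark.parametrize("mass,delta", [(1.0, 1.0), (2.5, 1.0), (1.0, 0.5)])
    def test_constant_velocity_closed_form(self, rng, mass, delta):
        # W = Delta * mass * integral |c|^2 dt = Delta^2 |c|^2 mass
        c = np.array([0.6, -0.8])
        mix = GaussianMixtureDensity(rng.normal(size=(5, 2)), 0.4, mass=mass)
        W = wfr_interval_cost(constant_velocity_field(c), mix, 0.0, delta,
                              n_samples=20, seed=1)
        assert W == pytest.approx(delta**2 * 1.0 * mass, rel=1e-9)

    def test_pure_growth_closed_form(self, gauss2):
        gamma, alpha, delta = 0.5, 2.0, 1.5
        W = wfr_interval_cost(uniform_growth_field(2, gamma), gauss2, 0.0,
                              delta, alpha=alpha, n_samples=10, seed=2,
                              base_dt=0.05)
        expected = delta * 1.0 * alpha * gamma * (np.exp(gamma * delta) - 1)
        assert W == pytest.approx(expected, rel=1e-6)

    def test_total_cost_is_sum_over_consecutive_intervals(self, rng):
        c = np.array([1.0, 0.0])
        f = constant_velocity_field(c)
        mixes = [GaussianMixtureDensity(rng.normal(size=(5, 2)) + k, 0.4,
                                        mass=1.0 + k)
                 for k in range(3)]
        total = wfr_total_cost(f, mixes, [0.0, 1.0, 2.0], n_samples=10, seed=3)
        # two unit intervals with masses 1 and 2: (1 + 2) * |c|^2
        assert total == pytest.approx(3.0, rel=1e-9)

    def test_mass_scales_cost_linearly(self, rng):
        means = rng.normal(size=(6, 2))
        f = constant_velocity_field([0.3, 0.4])
        W1 = wfr_interval_cost(f, GaussianMixtureDensity(means, 0.4, 1.0),
                               0.0, 1.0, n_samples=15, seed=4)
        W2 = wfr_interval_cost(f, GaussianMixtureDensity(means, 0.4, 2.0),
                               0.0, 1.0, n_samples=15, seed=4)
        assert W2 == pytest.approx(2 * W1, rel=1e-9)

    def test_requires_two_timepoints(self, gauss2):
        with pytest.raises(ValueError):
            wfr_total_cost(AnalyticField(2), [gauss2], [0.0])


class TestReconstructionError:
    def test_identity_transport_identical_snapshots(self, rng):
        means = rng.normal(size=(10, 2))
        mix = GaussianMixtureDensity(means, 0.5)
        err = reconstruction_error_pair(AnalyticField(2), mix, mix, 0.0, 1.0,
                                        K=50, seed=5)
        assert err == pytest.approx(0.0, abs=1e-12)

    def test_true_linear_field_reconstructs_gaussian_flow(self):
        # transporting the exact Gaussian density with its own generating
        # field: error vanishes as the mixture approximates the Gaussian
        from conftest import linear_field
        from wfrflow.simulate import simulate_linear_field

        A = -0.5 * np.eye(2)
        ds, truth = simulate_linear_field(A, 0.0, [0, 0], 0.5 * np.eye(2),
                                          (0.0, 1.0), 400, seed=6)
        f = linear_field(A, 0.0)
        mix0 = GaussianMixtureDensity(ds[0].X, 0.25, 1.0)
        mix1 = GaussianMixtureDensity(ds[1].X, 0.25, 1.0)
        err = reconstruction_error_pair(f, mix0, mix1, 0.0, 1.0, K=200,
                                        seed=7, base_dt=0.05)
        # densities are O(1); the squared mismatch that remains is the
        # finite-sample mixture approximation error, far below that scale
        assert err < 0.02

    def test_zero_field_translated_copy_matches_direct_mc(self, rng):
        means = rng.normal(size=(12, 2))
        shift = np.array([1.3, -0.4])
        mix_i = GaussianMixtureDensity(means, 0.5)
        mix_j = GaussianMixtureDensity(means + shift, 0.5)
        K, seed = 4000, 8
        err = reconstruction_error_pair(AnalyticField(2), mix_i, mix_j,
                                        0.0, 1.0, K=K, seed=seed)
        # with v = g = 0 the estimate is rho_i evaluated at the x_j samples
        samples = mix_j.sample(K, np.random.default_rng(seed))
        direct = np.mean((mix_i.density(samples) - mix_j.density(samples)) ** 2)
        assert err == pytest.approx(direct, rel=0.15)

    def test_log_density_space_option(self, rng):
        means = rng.normal(size=(6, 2))
        mix_i = GaussianMixtureDensity(means, 0.5)
        mix_j = GaussianMixtureDensity(means + 0.5, 0.5)
        e_lin = reconstruction_error_pair(AnalyticField(2), mix_i, mix_j,
                                          0.0, 1.0, K=100, seed=9)
        e_log = reconstruction_error_pair(AnalyticField(2), mix_i, mix_j,
                                          0.0, 1.0, K=100, seed=9,
                                          recon_space="log_density")
        assert e_lin != pytest.approx(e_log)
        assert e_log > 0

    def test_total_error_counts_short_and_long_terms(self, rng):
        means = rng.normal(size=(6, 2))
        mixes = [GaussianMixtureDensity(means + 0.3 * k, 0.5) for k in range(2)]
        pair = reconstruction_error_pair(AnalyticField(2), mixes[0], mixes[1],
                                         0.0, 1.0, K=200, seed=10)
        total = total_reconstruction_error(AnalyticField(2), mixes, [0.0, 1.0],
                                           K=200, seed=10)
        # T=2: short and long sums coincide, the pair is counted twice
        # (fresh samples per term make the match statistical, not exact)
        assert total == pytest.approx(2 * pair, rel=0.25)

    def test_total_error_zero_for_identical_snapshots(self, rng):
        mix = GaussianMixtureDensity(rng.normal(size=(6, 2)), 0.5)
        mixes = [mix, mix, mix]
        total = total_reconstruction_error(AnalyticField(2), mixes,
                                           [0.0, 1.0, 2.0], K=20, seed=11)
        assert total == pytest.approx(0.0, abs=1e-12)


class TestTotalLoss:
    def test_breakdown_bookkeeping_is_exact(self, rng):
        f = FieldPair(2, (6, 6), (4,), rng=12, init_scale=0.5)
        mixes = [GaussianMixtureDensity(rng.normal(size=(6, 2)) + k, 0.3,
                                        1.0 + 0.5 * k) for k in range(3)]
        bd = total_loss(f, mixes, [0.0, 1.0, 2.0], alpha=1.0, lambda_d=2.5,
                        K=10, seed=13)
        assert bd.loss == pytest.approx(bd.W + 2.5 * bd.R, rel=1e-12)
        assert bd.R == pytest.approx(bd.R_short + bd.R_long, rel=1e-12)
        assert bd.W == pytest.approx(sum(bd.W_intervals), rel=1e-12)
        assert bd.W >= 0 and bd.R >= 0

    def test_lambda_zero_reduces_to_cost(self, rng):
        f = FieldPair(2, (6, 6), (4,), rng=14, init_scale=0.5)
        mixes = [GaussianMixtureDensity(rng.normal(size=(5, 2)), 0.3)
                 for _ in range(2)]
        bd = total_loss(f, mixes, [0.0, 1.0], lambda_d=0.0, K=10, seed=15)
        assert bd.loss == pytest.approx(bd.W, rel=1e-12)

    def test_zero_fields_identical_snapshots_zero_loss(self, rng):
        mix = GaussianMixtureDensity(rng.normal(size=(5, 2)), 0.3)
        bd = total_loss(AnalyticField(2), [mix, mix], [0.0, 1.0], K=10, seed=16)
        assert bd.loss == pytest.approx(0.0, abs=1e-12)

    def test_resampling_changes_monte_carlo_estimate(self, rng):
        f = FieldPair(2, (6, 6), (4,), rng=17, init_scale=1.0)
        mixes = [GaussianMixtureDensity(rng.normal(size=(5, 2)) + k, 0.3)
                 for k in range(2)]
        bd1 = total_loss(f, mixes, [0.0, 1.0], K=10, seed=18)
        bd2 = total_loss(f, mixes, [0.0, 1.0], K=10, seed=19)
        assert bd1.loss != bd2.loss


class TestBatchedEquivalence:
    """The batched epoch path computes the same terms as the pairwise loop."""

    def _setup(self, rng, uniform=True):
        from wfrflow.fields import FieldPair

        f = FieldPair(2, (8, 8), (6,), rng=21, init_scale=0.6, time_scale=2.0)
        times = [0.0, 1.0, 2.0] if uniform else [0.0, 0.7, 2.0]
        mixes = [GaussianMixtureDensity(rng.normal(size=(6, 2)) + 0.4 * k,
                                        0.4, 1.0 + 0.3 * k)
                 for k in range(3)]
        return f, mixes, times

    def test_identical_grids_give_identical_values(self, rng):
        from wfrflow.objective import total_loss_graph

        f, mixes, times = self._setup(rng, uniform=True)
        # uniform spacing: the long pair (t1, t3) spans 2 units; give the
        # loop the same effective grid by matching base_dt
        loss_loop, bd_loop = total_loss_graph(
            f, mixes, times, 1.0, 1.0, 8, np.random.default_rng(5), 0.25
        )
        loss_bat, bd_bat = total_loss_graph(
            f, mixes, times, 1.0, 1.0, 8, np.random.default_rng(5), 0.25,
            batched=True,
        )
        # short terms use identical grids; the long (t1,t3) term is refined
        # in the batched path, so require close, not exact, agreement
        assert bd_bat.W == pytest.approx(bd_loop.W, rel=1e-9)
        assert bd_bat.R_short == pytest.approx(bd_loop.R_short, rel=1e-9)
        assert bd_bat.R_long == pytest.approx(bd_loop.R_long, rel=1e-3)
        assert float(loss_bat.value) == pytest.approx(
            bd_bat.W + bd_bat.R_short + bd_bat.R_long, rel=1e-9
        )

    def test_batched_gradients_match_loop_gradients(self, rng):
        from wfrflow.objective import total_loss_graph

        f, mixes, times = self._setup(rng, uniform=True)
        grads = {}
        for batched in (False, True):
            for p in f.parameters():
                p.grad = None
            loss, _ = total_loss_graph(
                f, mixes, times, 1.0, 1.0, 8, np.random.default_rng(5), 0.25,
                batched=batched,
            )
            loss.backward()
            grads[batched] = [p.grad.copy() for p in f.parameters()]
        for g_loop, g_bat in zip(grads[False], grads[True]):
            np.testing.assert_allclose(g_bat, g_loop, rtol=1e-2, atol=1e-7)

    def test_nonuniform_spacing_supported(self, rng):
        from wfrflow.objective import total_loss_graph

        f, mixes, times = self._setup(rng, uniform=False)
        loss, bd = total_loss_graph(
            f, mixes, times, 1.0, 1.0, 8, np.random.default_rng(6), 0.2,
            batched=True,
        )
        assert np.isfinite(bd.loss)
        assert bd.loss == pytest.approx(bd.W + bd.R, rel=1e-9)
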