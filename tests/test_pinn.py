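import numpy as np
import pytest

from fracalz.glsolver import SolverGrid, Trajectory, integrate_caputo_gl
from fracalz.model import TABLE1_PARAMS, TABLE1_STATE, ModelParameters
from fracalz.pinn import (
    LossBreakdown,
    PINNConfig,
    add_noise,
    build_network,
    fractional_residual,
    noise_benchmark,
    robustness_ratio,
    total_loss,
    train_variant,
)
from fracalz.simulate import simulate
from fracalz.stability import disease_free_equilibrium

from conftest import linear_decay_params


def make_reference(sigma=0.9, horizon=200.0, n_steps=100):
    traj = simulate(TABLE1_PARAMS, TABLE1_STATE, sigma, SolverGrid(horizon, n_steps))
    traj.params = TABLE1_PARAMS
    return traj


class TestNetwork:
    def test_deterministic_given_seed(self):
        cfg = PINNConfig(seed=7)
        probe = np.linspace(0, 1, 37)
        s1, c1 = build_network(cfg).predict(probe)
        s2, c2 = build_network(cfg).predict(probe)
        assert np.array_equal(s1, s2) and np.array_equal(c1, c2)

    def test_output_arity_and_control_bounds(self):
        rng = np.random.default_rng(0)
        probe = rng.uniform(0, 1, 1000)
        states, controls = build_network(PINNConfig(seed=1)).predict(probe)
        assert states.shape == (1000, 5)
        assert controls.shape == (1000, 2)
        assert np.all((controls > 0) & (controls < 1))

    def test_different_seed_different_network(self):
        probe = np.linspace(0, 1, 10)
        s1, _ = build_network(PINNConfig(seed=1)).predict(probe)
        s2, _ = build_network(PINNConfig(seed=2)).predict(probe)
        assert not np.array_equal(s1, s2)


class TestFractionalResidual:
    def test_equilibrium_prediction_gives_zero_residual(self):
        """A constant trajectory pinned at the disease-free equilibrium
        has zero Caputo derivative and zero right-hand side."""
        dfe = disease_free_equilibrium(TABLE1_PARAMS).state
        grid = SolverGrid(10.0, 20)
        traj = Trajectory(grid, np.tile(dfe, (21, 1)))
        R = fractional_residual(traj, TABLE1_PARAMS, 0.8)
        assert np.max(np.abs(R)) < 1e-12

    def test_integer_order_is_backward_difference_defect(self):
        rng = np.random.default_rng(2)
        grid = SolverGrid(5.0, 10)
        states = rng.uniform(0.0, 1.0, (11, 5))
        R = fractional_residual(Trajectory(grid, states), TABLE1_PARAMS, 1.0)
        from fracalz.model import model_rhs

        expected = (states[1:] - states[:-1]) / grid.h - model_rhs(states[1:], TABLE1_PARAMS)
        assert np.allclose(R[1:], expected, rtol=1e-12, atol=1e-12)

    @pytest.mark.parametrize("sigma", [0.6, 0.9])
    def test_solver_trajectory_residual_halves_with_h(self, sigma):
        """The GL solver's own trajectory satisfies the discrete
        equation up to the rhs time lag, so its residual is O(h)."""
        params = linear_decay_params(rate=1.0)
        u0 = np.array([1.0, 0, 0, 0, 0])

        def rhs(t, u):
            from fracalz.model import model_rhs

            return model_rhs(u, params)

        maxima = []
        for n in (50, 100):
            grid = SolverGrid(2.0, n)
            traj = integrate_caputo_gl(rhs, u0, sigma, grid, taylor_start=False)
            R = fractional_residual(traj, params, sigma)
            maxima.append(np.max(np.abs(R[1:])))
        ratio = maxima[0] / maxima[1]
        assert 2.0 * 0.7 <= ratio <= 2.0 * 1.3

    def test_wrong_state_count_rejected(self):
        grid = SolverGrid(1.0, 4)
        with pytest.raises(ValueError):
            fractional_residual(Trajectory(grid, np.zeros((5, 3))), TABLE1_PARAMS, 0.9)


class TestTotalLoss:
    def test_perfect_fit_is_zero(self):
        pred = np.ones((4, 5))
        lb = total_loss(pred, pred.copy(), np.zeros((3, 5)), 1.0)
        assert lb.total == 0.0 and lb.data_loss == 0.0 and lb.physics_loss == 0.0

    def test_zero_lambda_reduces_to_data_loss(self):
        rng = np.random.default_rng(0)
        pred, obs = rng.normal(size=(6, 5)), rng.normal(size=(6, 5))
        lb = total_loss(pred, obs, rng.normal(size=(5, 5)), 0.0)
        assert lb.total == lb.data_loss

    def test_hand_computed_scalar_case(self):
        pred = np.array([[1.5], [2.5]])
        obs = np.array([[1.0], [2.0]])
        lb = total_loss(pred, obs, np.zeros((1, 1)), 1.0)
        assert lb.data_loss == pytest.approx(0.25, rel=1e-14)

    def test_additivity_identity(self):
        rng = np.random.default_rng(1)
        pred, obs = rng.normal(size=(6, 5)), rng.normal(size=(6, 5))
        res = rng.normal(size=(6, 5))
        lb = total_loss(pred, obs, res, 0.7)
        assert lb.total == pytest.approx(lb.data_loss + 0.7 * lb.physics_loss, rel=1e-10)

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError, match="grid"):
            total_loss(np.zeros((4, 5)), np.zeros((3, 5)), np.zeros((2, 5)), 1.0)


class TestNoise:
    def test_zero_level_is_identity(self):
        ref = make_reference(n_steps=20)
        noisy = add_noise(ref, 0.0, seed=3)
        assert np.array_equal(noisy.states, ref.states)

    def test_seeded_reproducibility(self):
        ref = make_reference(n_steps=20)
        a = add_noise(ref, 0.1, seed=3)
        b = add_noise(ref, 0.1, seed=3)
        assert np.array_equal(a.states, b.states)
        assert not np.array_equal(a.states, add_noise(ref, 0.1, seed=4).states)

    def test_clean_trajectory_untouched(self):
        ref = make_reference(n_steps=20)
        before = ref.states.copy()
        add_noise(ref, 0.2, seed=0)
        assert np.array_equal(ref.states, before)

    def test_empirical_sd_matches_level(self):
        grid = SolverGrid(1.0, 9999)
        const = Trajectory(grid, np.ones((10000, 5)))
        noisy = add_noise(const, 0.1, seed=12)
        sd = np.std(noisy.states - const.states, axis=0)
        assert np.all(np.abs(sd - 0.1) < 0.005)

    def test_negative_level_rejected(self):
        with pytest.raises(ValueError):
            add_noise(make_reference(n_steps=4), -0.1, seed=0)


class TestTraining:
    def test_baseline_interpolates_noiseless_data(self):
        ref = make_reference(n_steps=100)
        cfg = PINNConfig(sigma=0.9, iterations=1500, seed=0)
        res = train_variant("baseline", cfg, ref)
        # interpolation regime: data loss negligible against the
        # signal's mean squared magnitude
        signal = np.mean(np.sum(ref.states**2, axis=1))
        assert res.final.data_loss < 1e-4 * signal

    def test_fractional_variant_recovers_neuron_curve(self):
        """Scaled-down run: relative L2 error on F_N below 5%."""
        ref = make_reference(sigma=0.9, horizon=200.0, n_steps=400)
        cfg = PINNConfig(sigma=0.9, iterations=2000, seed=1)
        res = train_variant("fractional", cfg, ref)
        rel = np.linalg.norm(res.predicted.states[:, 0] - ref.states[:, 0]) / np.linalg.norm(
            ref.states[:, 0]
        )
        assert rel < 0.05

    def test_integer_variant_forces_unit_order(self):
        ref = make_reference(n_steps=50)
        cfg = PINNConfig(sigma=0.8, iterations=5, seed=0)
        res = train_variant("integer", cfg, ref)
        assert res.config.sigma == 1.0

    def test_history_and_final_are_consistent(self):
        ref = make_reference(n_steps=50)
        cfg = PINNConfig(iterations=40, seed=2)
        res = train_variant("fractional", cfg, ref)
        assert res.history.shape == (40,)
        assert res.final.total == res.history[-1]
        assert res.final.total == pytest.approx(
            res.final.data_loss + cfg.lambda_phys * res.final.physics_loss, rel=1e-10
        )

    def test_baseline_ignores_model_parameters(self):
        """Without a physics term the model rates never enter training:
        swapping them changes nothing for a fixed seed."""
        ref = make_reference(n_steps=50)
        cfg = PINNConfig(iterations=30, seed=5)
        res_a = train_variant("baseline", cfg, ref)
        ref_b = make_reference(n_steps=50)
        ref_b.params = ModelParameters(alpha=0.7, gamma=0.1)
        res_b = train_variant("baseline", cfg, ref_b)
        assert np.array_equal(res_a.predicted.states, res_b.predicted.states)

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError, match="variant"):
            train_variant("quantum", PINNConfig(), make_reference(n_steps=4))


class TestBenchmark:
    def test_equal_seeds_give_zero_spread(self):
        ref = make_reference(n_steps=40)
        cfg = PINNConfig(iterations=20, seed=0)
        a = train_variant("fractional", cfg, ref, 0.1, seed=123)
        b = train_variant("fractional", cfg, ref, 0.1, seed=123)
        assert a.final.total == b.final.total

    def test_robustness_ratio_identities(self):
        assert robustness_ratio(0.5, 0.5) == 1.0
        with pytest.raises(ZeroDivisionError):
            robustness_ratio(1.0, 0.0)

    def test_aggregation_structure(self):
        ref = make_reference(n_steps=40)
        cfg = PINNConfig(iterations=15, seed=0)
        bench = noise_benchmark(cfg, ref, levels=(0.0, 0.2), replicates=2,
                                variants=("baseline",), base_seed=9)
        st = bench.stats["baseline"]
        assert set(st) == {0.0, 0.2}
        cell = st[0.2]
        assert cell["min"] <= cell["mean"] <= cell["max"]
        assert cell["n"] == 2
        # hand-check the n-1 sd convention on the recorded extremes
        vals = [cell["min"], cell["max"]]
        assert cell["sd"] == pytest.approx(np.std(vals, ddof=1), rel=1e-9)
        assert bench.ratios["baseline"] == pytest.approx(
            st[0.2]["mean"] / st[0.0]["mean"], rel=1e-12
        )
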