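import numpy as np
import pytest

from fracalz.model import CHAOS_PARAMS, TABLE1_PARAMS, ModelParameters, model_rhs
from fracalz.stability import (
    GainVector,
    disease_free_equilibrium,
    eigen_stability,
    endemic_equilibrium,
    gain_example_report,
    jacobian_dfe,
    jacobian_fd_audit,
    ngm_matrices,
    r0_surface,
    solve_endemic_level,
)

from conftest import random_admissible_params


class TestEquilibria:
    def test_dfe_value_and_residual(self):
        eq = disease_free_equilibrium(ModelParameters(Pi_N=1.0, phi1=0.02))
        assert eq.state[0] == pytest.approx(50.0, rel=1e-14)
        assert np.array_equal(eq.state[1:], np.zeros(4))
        assert eq.residual_norm <= 1e-10 * (1 + np.max(np.abs(eq.state)))

    def test_dfe_chaos_preset(self):
        eq = disease_free_equilibrium(CHAOS_PARAMS)
        assert eq.state[0] == pytest.approx(700.0 / 0.00003, rel=1e-12)

    def test_endemic_reduces_to_dfe_at_zero_level(self):
        eq = endemic_equilibrium(TABLE1_PARAMS, 0.0)
        dfe = disease_free_equilibrium(TABLE1_PARAMS)
        assert np.allclose(eq.state, dfe.state, rtol=1e-14)

    def test_endemic_closed_form_components(self):
        eq = endemic_equilibrium(TABLE1_PARAMS, 1.0)
        # A* = gamma/(d_beta+kappa), T* = kappa*gamma/((d_mu+rho)(d_beta+kappa))
        assert eq.state[2] == pytest.approx(0.00017 / 9.535, rel=1e-12)
        assert eq.state[3] == pytest.approx(0.025 * 0.00017 / (0.302 * 9.535), rel=1e-12)
        assert eq.state[2] == pytest.approx(1.78290e-5, rel=1e-4)
        assert eq.state[3] == pytest.approx(1.47591e-6, rel=1e-4)

    def test_endemic_solves_all_but_infected_equation(self):
        eq = endemic_equilibrium(TABLE1_PARAMS, 1.0)
        rhs = model_rhs(eq.state, TABLE1_PARAMS)
        scale = 1 + np.max(np.abs(eq.state))
        assert np.max(np.abs(rhs[[0, 2, 3, 4]])) <= 1e-10 * scale

    def test_negative_level_rejected(self):
        with pytest.raises(ValueError):
            endemic_equilibrium(TABLE1_PARAMS, -1.0)

    def test_self_consistent_level_zeroes_whole_rhs(self):
        # crank alpha up so an endemic state exists (R0 > 1)
        params = TABLE1_PARAMS.with_updates(alpha=0.6)
        assert ngm_matrices(params).R0 > 1
        level = solve_endemic_level(params)
        eq = endemic_equilibrium(params, level)
        scale = 1 + np.max(np.abs(eq.state))
        assert np.max(np.abs(model_rhs(eq.state, params))) <= 1e-9 * scale


class TestReproductionNumber:
    def test_no_infection_no_reproduction(self):
        # alpha = 0 kills the only new-infection pathway
        params = TABLE1_PARAMS.with_updates(alpha=0.0)
        assert ngm_matrices(params).R0 == 0.0

    def test_closed_form_matches_spectral_radius_on_random_draws(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            params = random_admissible_params(rng)
            res = ngm_matrices(params)
            rho = np.max(np.abs(np.linalg.eigvals(res.K)))
            assert res.R0 == pytest.approx(rho, abs=1e-12 * max(1.0, rho))

    def test_v_is_positive_diagonal(self):
        res = ngm_matrices(TABLE1_PARAMS)
        assert np.array_equal(res.V, np.diag(np.diag(res.V)))
        assert np.all(np.diag(res.V) > 0)

    def test_threshold_consistency_with_linearization(self):
        """Scaling alpha through the R0 = 1 point flips the sign of the
        dominant eigenvalue of F - V."""
        for alpha, expect_unstable in ((0.08, False), (0.6, True)):
            params = TABLE1_PARAMS.with_updates(alpha=alpha)
            res = ngm_matrices(params)
            lead = np.max(np.linalg.eigvals(res.F - res.V).real)
            assert (res.R0 > 1) == expect_unstable
            assert (lead > 0) == expect_unstable


class TestR0Surface:
    def test_base_point_consistency(self):
        xs = np.linspace(0.04, 0.12, 5)
        ys = np.linspace(0.0001, 0.0003, 5)
        xs_out, ys_out, R, mask = r0_surface(TABLE1_PARAMS, ("alpha", "gamma"), (xs, ys))
        i = np.argmin(np.abs(xs_out - 0.08))
        j = np.argmin(np.abs(ys_out - TABLE1_PARAMS.gamma))
        base = ngm_matrices(
            TABLE1_PARAMS.with_updates(alpha=float(xs_out[i]), gamma=float(ys_out[j]))
        ).R0
        assert R[i, j] == base

    def test_monotone_in_alpha(self):
        xs = np.linspace(0.01, 0.5, 8)
        ys = np.array([0.0001, 0.0002])
        _, _, R, _ = r0_surface(TABLE1_PARAMS, ("alpha", "gamma"), (xs, ys))
        assert np.all(np.diff(R, axis=0) > 0)

    def test_subthreshold_surface_has_empty_mask(self):
        xs = np.linspace(0.04, 0.12, 4)
        ys = np.linspace(0.0001, 0.0003, 4)
        _, _, R, mask = r0_surface(TABLE1_PARAMS, ("alpha", "gamma"), (xs, ys))
        assert R.max() < 1 and not mask.any()

    def test_crossing_surface_is_masked(self):
        xs = np.linspace(0.05, 3.0, 12)
        ys = np.linspace(0.0001, 0.0004, 6)
        _, _, R, mask = r0_surface(TABLE1_PARAMS, ("alpha", "gamma"), (xs, ys))
        assert R.max() > 1 and mask.any()

    def test_non_r0_parameter_rejected(self):
        with pytest.raises(ValueError, match="does not enter R0"):
            r0_surface(TABLE1_PARAMS, ("beta1", "alpha"), (np.ones(2), np.ones(2)))


class TestJacobian:
    def test_zero_gain_diagonal_entry(self):
        J = jacobian_dfe(TABLE1_PARAMS)
        assert J[0, 0] == pytest.approx(-0.02, rel=1e-14)

    def test_antisymmetric_infection_entries(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            params = random_admissible_params(rng)
            J = jacobian_dfe(params)
            assert J[0, 2] + J[1, 2] == pytest.approx(0.0, abs=1e-12 * abs(J[1, 2]))

    def test_gain_augmented_diagonal(self):
        J = jacobian_dfe(CHAOS_PARAMS, GainVector(1, 2, 3, 4))
        assert J[0, 0] == pytest.approx(-1.00003, rel=1e-14)
        assert J[3, 3] == pytest.approx(-4.302, rel=1e-14)

    def test_finite_difference_audit_is_clean(self):
        audit = jacobian_fd_audit(TABLE1_PARAMS)
        assert audit["discrepancies"] == []
        assert audit["max_abs_difference"] < 1e-6


class TestEigenStability:
    def test_diagonal_matrix(self):
        rep = eigen_stability(np.diag([-1.0, -2.0]))
        assert np.allclose(rep.eigenvalues, [-1.0, -2.0])
        assert rep.stable

    def test_sorted_by_magnitude_then_real_part(self):
        rep = eigen_stability(np.diag([3.0, -1.0, -3.0, 2.0]))
        assert np.allclose(rep.eigenvalues, [-1.0, 2.0, -3.0, 3.0])
        assert not rep.stable

    def test_trace_identity_on_random_matrices(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            M = rng.normal(size=(5, 5))
            rep = eigen_stability(M)
            assert np.sum(rep.eigenvalues).real == pytest.approx(
                np.trace(M), rel=1e-8, abs=1e-8
            )

    def test_non_square_rejected(self):
        with pytest.raises(ValueError, match="square"):
            eigen_stability(np.zeros((2, 3)))


class TestGainWorkedExample:
    def test_forced_roots_reproduced_to_machine_precision(self):
        rep = gain_example_report(CHAOS_PARAMS)
        ev = rep["eigenvalues_by_magnitude"]
        assert ev[0].real == pytest.approx(-1.00003, rel=1e-12)
        assert ev[0].imag == 0.0
        assert ev[1].real == pytest.approx(-4.302, rel=1e-12)
        assert ev[1].imag == 0.0

    def test_published_tail_roots_flagged_as_inconsistent(self):
        """The two remaining published roots do not sum to the matrix
        trace; the report must expose the inconsistency rather than
        echo them."""
        rep = gain_example_report(CHAOS_PARAMS)
        assert rep["trace_consistent"] is False
        # and the actual spectrum contains a positive root the published
        # list misses entirely
        reals = sorted(ev.real for ev in rep["eigenvalues_by_magnitude"])
        assert reals[-1] > 0
        assert rep["stable"] is False

    def test_omega5_accepted_and_ignored(self):
        with_5 = jacobian_dfe(CHAOS_PARAMS, GainVector(1, 2, 3, 4, 5))
        without = jacobian_dfe(CHAOS_PARAMS, GainVector(1, 2, 3, 4, 0))
        assert np.array_equal(with_5, without)
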