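import numpy as np
import pytest

from nmblock import (
    nondimensionalize,
    rhs_dimensionless_full,
    rhs_full,
    rhs_reduced,
    scale_state,
    simulate_event,
    simulate_dimensionless_full,
    simulate_reduced,
    unscale_state,
)
from nmblock.dimensionless import FULL_X_NAMES, REDUCED_X_NAMES, peak_x_ara_star
from nmblock.kinetics import occupancy_fractions, peak_activation


def _scaled_derivative(p, dy):
    """Change-of-variables oracle: map a dimensional derivative to tau units."""
    dx = dy / (p.R_total * p.k_decay)
    dx[0] = dy[0] / (p.K_A1 * p.k_decay)
    return dx


class TestNondimensionalize:
    def test_base_case_groups(self, base_params):
        dp = nondimensionalize(base_params, 1.0e-7)
        assert dp.kappa_A1 == pytest.approx(1.5)
        assert dp.kappa_close == pytest.approx(0.1)
        assert dp.kappa_open == pytest.approx(50.0 / 12.0)
        assert dp.lambda_A1 == pytest.approx(7.75e-5 / (1.8e4 / 1.1e8))
        assert dp.lambda_A1 == pytest.approx(0.4736, rel=1e-3)
        assert dp.delta == pytest.approx(1.0)
        assert dp.mu_D == pytest.approx(1.0)
        assert dp.kappa_D1 == pytest.approx(10.0 / 1.2e4)

    def test_round_trip_recovers_rates(self, base_params):
        p = base_params
        dp = nondimensionalize(p, 3e-8)
        assert dp.kappa_A1 * p.k_decay == pytest.approx(p.k_dissA1)
        assert dp.lambda_A1 * p.K_A1 == pytest.approx(p.R_total)
        assert dp.delta * p.K_D1 == pytest.approx(3e-8)
        assert dp.mu_A * p.K_A2 == pytest.approx(p.K_A1)


class TestStateScaling:
    def test_unit_points(self, base_params):
        p = base_params
        x = scale_state(_state_with(p, A=p.K_A1), p)
        assert x[0] == pytest.approx(1.0)
        assert np.all(x[1:] == 0.0)
        x = scale_state(_state_with(p, ARA_star=p.R_total), p)
        assert x[FULL_X_NAMES.index("x_ARA_star")] == pytest.approx(1.0)

    def test_round_trip_is_identity(self, base_params):
        rng = np.random.default_rng(7)
        for _ in range(20):
            x = rng.uniform(0.0, 1.0, 10)
            x2 = scale_state(unscale_state(x, base_params), base_params)
            np.testing.assert_allclose(x2, x, rtol=1e-14)


def _state_with(p, **kw):
    from nmblock.kinetics import ReceptorState

    vals = {name: 0.0 for name in
            ("A", "ARA_star", "ARA", "DRD", "ARD", "DRA",
             "ARO", "ORA", "DRO", "ORD")}
    vals.update(kw)
    return ReceptorState(**vals, R_total=p.R_total)


class TestFullDimensionlessSystem:
    def test_zero_state_is_quiescent(self, base_params):
        dp = nondimensionalize(base_params, 0.0)
        dx = rhs_dimensionless_full(np.zeros(10), dp)
        assert np.all(dx == 0.0)

    @pytest.mark.parametrize("drug", [0.0, 3e-8, 1e-7])
    def test_change_of_variables_oracle(self, base_params, drug):
        """Scaled dimensional derivative == dimensionless derivative."""
        p = base_params.with_mu_D(10.0)
        dp = nondimensionalize(p, drug)
        rng = np.random.default_rng(3)
        for _ in range(50):
            x = rng.uniform(0.0, 0.1, 10)
            x[0] = rng.uniform(0.0, 2.0)
            dy = rhs_full(unscale_state(x, p), p, drug)
            np.testing.assert_allclose(
                rhs_dimensionless_full(x, dp),
                _scaled_derivative(p, dy),
                rtol=1e-10,
                atol=1e-16,
            )

    def test_trace_equivalence_with_dimensional_model(self, base_params):
        """Simulate-then-scale equals simulating the scaled system."""
        p = base_params
        drug = 3.0e-8
        horizon = 2.5e-3
        traj = simulate_event(p, drug, horizon)
        dp = nondimensionalize(p, drug)
        dtraj = simulate_dimensionless_full(
            dp, p.A_init / p.K_A1, tau_max=p.k_decay * horizon
        )
        scaled = traj.column("ARA_star") / p.R_total
        # relative agreement on the scale of the peak; the deep tails sit
        # at the two solvers' absolute-tolerance floors
        np.testing.assert_allclose(
            dtraj.column("x_ARA_star"),
            scaled,
            rtol=1e-6,
            atol=1e-6 * scaled.max(),
        )


class TestReducedModel:
    def test_substitution_oracle_against_full_system(self, base_params):
        """Reduced RHS equals the full system at kappa_D = 0 under the
        frozen-pool identification x_ORD = O_ORD - x_ARD etc."""
        p = base_params.with_mu_D(10.0)
        dp = nondimensionalize(p, 1e-7)
        dp0 = dp.evolve(kappa_D1=0.0, kappa_D2=0.0)
        occ = occupancy_fractions(dp.delta, dp.mu_D)
        rng = np.random.default_rng(11)
        for _ in range(50):
            xr = rng.uniform(0.0, 0.05, 7)
            xr[0] = rng.uniform(0.0, 2.0)
            xA, xs, xARA, xARO, xORA, xARD, xDRA = xr
            xfull = np.array(
                [
                    xA,
                    xs,
                    xARA,
                    occ.O_DRD,
                    xARD,
                    xDRA,
                    xARO,
                    xORA,
                    occ.O_DRO - xDRA,
                    occ.O_ORD - xARD,
                ]
            )
            dfull = dict(zip(FULL_X_NAMES, rhs_dimensionless_full(xfull, dp0)))
            expected = np.array([dfull[n] for n in REDUCED_X_NAMES])
            np.testing.assert_allclose(
                rhs_reduced(xr, dp, occ), expected, rtol=1e-12, atol=1e-18
            )

    def test_inconsistent_occupancies_rejected(self, base_params):
        dp = nondimensionalize(base_params, 1e-7)
        wrong = occupancy_fractions(2.0, dp.mu_D)
        with pytest.raises(ValueError):
            rhs_reduced(np.zeros(7), dp, wrong)

    def test_coincides_with_full_model_without_drug(self, base_params):
        p = base_params
        dp = nondimensionalize(p, 0.0)
        x0 = p.A_init / p.K_A1
        full = simulate_dimensionless_full(dp, x0)
        red = simulate_reduced(dp, x0)
        np.testing.assert_allclose(
            red.column("x_ARA_star"),
            full.column("x_ARA_star"),
            atol=1e-8,
        )

    def test_frozen_pool_conserved_along_trajectory(self, base_params):
        """With blocker exchange switched off in the full system, the
        drug-bound pool quantities are constants of motion."""
        p = base_params
        dp = nondimensionalize(p, 1e-7).evolve(kappa_D1=0.0, kappa_D2=0.0)
        traj = simulate_dimensionless_full(
            dp, p.A_init / p.K_A1, atol=1e-14
        )
        drd = traj.column("x_DRD")
        ord_plus_ard = traj.column("x_ORD") + traj.column("x_ARD")
        dro_plus_dra = traj.column("x_DRO") + traj.column("x_DRA")
        for q in (drd, ord_plus_ard, dro_plus_dra):
            assert np.max(np.abs(q - q[0])) < 1e-10
        # in the reduced model the dynamical mixed states stay inside the
        # frozen occupancies (x_ORD, x_DRO reconstructions stay >= 0)
        occ = occupancy_fractions(dp.delta, dp.mu_D)
        red = simulate_reduced(nondimensionalize(p, 1e-7),
                               p.A_init / p.K_A1, atol=1e-14)
        assert np.all(red.column("x_ARD") <= occ.O_ORD + 1e-10)
        assert np.all(red.column("x_DRA") <= occ.O_DRO + 1e-10)

    def test_peak_matches_full_model_at_small_kappa_D(self, base_params):
        """At the base-case blocker off-rate (kappa_D ~ 8e-4) the reduced
        model reproduces the full peak to better than 1e-3 relative."""
        p = base_params
        dp = nondimensionalize(p, 1e-7)
        x0 = p.A_init / p.K_A1
        pf, _ = peak_x_ara_star(simulate_dimensionless_full(dp, x0))
        pr, _ = peak_x_ara_star(simulate_reduced(dp, x0))
        assert abs(pf - pr) / pf < 1e-3

    def test_fast_dissociation_breaks_reduction_at_high_ach(self, base_params):
        """With k_dissD raised to the ACh scale at in vitro ACh the reduced
        and full peaks disagree materially."""
        p = base_params.with_K_A(1e-5).evolve(
            A_init=10.0 * base_params.R_total
        ).with_k_dissD(1.8e4)
        dp = nondimensionalize(p, 3e-7)
        x0 = p.A_init / p.K_A1
        pf, _ = peak_x_ara_star(simulate_dimensionless_full(dp, x0))
        pr, _ = peak_x_ara_star(simulate_reduced(dp, x0))
        assert abs(pf - pr) / pf > 0.05

    def test_full_model_converges_to_reduction_as_k_dissD_shrinks(
        self, base_params
    ):
        """Relative-current gap between full and reduced models decreases
        monotonically as the blocker off-rate drops with K_D fixed."""
        p = base_params
        drug = 1e-7
        x0 = p.A_init / p.K_A1
        dp_ref = nondimensionalize(p, drug)
        pr, _ = peak_x_ara_star(simulate_reduced(dp_ref, x0))
        gaps = []
        for k_dissD in (1e3, 1e2, 1e1):
            dp = nondimensionalize(p.with_k_dissD(k_dissD), drug)
            pf, _ = peak_x_ara_star(simulate_dimensionless_full(dp, x0))
            gaps.append(abs(pf - pr) / pr)
        assert gaps[0] > gaps[1] > gaps[2]
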