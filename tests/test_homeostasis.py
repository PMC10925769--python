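"""ODE core: rates, quasi-steady states, age-course simulation."""

from dataclasses import replace

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from thymosim import (CarryingCapacities, HomeostasisParams,
                      InvolutionParams, SimulationSettings, ThymocyteState,
                      lhs_sample, rhs, simulate, steady_state,
                      steady_state_batch, thymic_output)
from thymosim.screening import GENERALIZED_BOUNDS


def independent_rhs(y, caps, p):
    """Term-by-term transcription of the model equations, kept separate
    from the library implementation as an arithmetic oracle."""
    t1, t2, t3, t4 = y
    u = 1 - (t1 + t2) / caps.t_cort_max
    v = 1 - (t3 + t4) / caps.t_med_max
    return np.array([
        p.phi * u - p.phi1 * t1 + p.lam1 * u * t1 - p.mu1 * t1,
        p.phi1 * t1 + p.lam2 * u * t2 - (p.phi4 + p.phi8) * v * t2 - p.mu2 * t2,
        p.phi4 * v * t2 - p.eps4 * t3 + p.lam4 * v * t3 - p.mu4 * t3,
        p.phi8 * v * t2 - p.eps8 * t4 + p.lam8 * v * t4 - p.mu8 * t4,
    ])


class TestRhs:
    def test_origin_only_inflow_survives(self, base_params, infant_caps):
        rates = rhs(ThymocyteState(0, 0, 0, 0), infant_caps, base_params)
        assert rates == pytest.approx([4.8e5, 0.0, 0.0, 0.0])

    def test_full_niches_leave_pure_loss(self, base_params, infant_caps):
        tc, tm = infant_caps.t_cort_max, infant_caps.t_med_max
        s = ThymocyteState(tc / 2, tc / 2, tm / 2, tm / 2)
        p = base_params
        expected = [
            -p.phi1 * s.t_dn - p.mu1 * s.t_dn,
            p.phi1 * s.t_dn - p.mu2 * s.t_dp,
            -(p.eps4 + p.mu4) * s.t_sp4,
            -(p.eps8 + p.mu8) * s.t_sp8,
        ]
        assert rhs(s, infant_caps, p) == pytest.approx(expected, rel=1e-12)

    def test_matches_arithmetic_oracle(self, base_params):
        caps = CarryingCapacities(2.84e10, 1.05e10)
        y = np.array([1e9, 1e10, 5e9, 2e9])
        got = rhs(y, caps, base_params)
        assert got == pytest.approx(independent_rhs(y, caps, base_params), rel=1e-10)

    def test_non_finite_rejected(self, base_params, infant_caps):
        with pytest.raises(ValueError):
            rhs(np.array([np.nan, 0, 0, 0]), infant_caps, base_params)


class TestSteadyState:
    def test_baseline_reproduces_calibration(self, base_params, infant_caps):
        """At the fixed infant capacities the baseline rates reproduce the
        calibrated quasi-steady-state populations."""
        res = steady_state(base_params, infant_caps)
        assert res.converged
        s = res.state
        assert s.t_dp == pytest.approx(2.12e10, rel=0.05)
        assert s.t_sp4 == pytest.approx(7.45e9, rel=0.02)
        assert s.t_sp8 == pytest.approx(2.79e9, rel=0.02)
        assert 1.3e9 <= s.t_dn <= 3.4e9

    def test_fixed_point_residual(self, base_params, infant_caps):
        res = steady_state(base_params, infant_caps)
        assert res.residual <= 1e-8

    def test_linear_chain_closed_form(self):
        """With no proliferation and effectively infinite niches the chain
        is linear with the textbook cascade solution."""
        p = HomeostasisParams(lam1=0, lam2=0, lam4=0, lam8=0)
        caps = CarryingCapacities(1e30, 1e30)
        res = steady_state(p, caps)
        assert res.converged
        t_dn = p.phi / (p.phi1 + p.mu1)
        t_dp = p.phi1 * t_dn / (p.phi4 + p.phi8 + p.mu2)
        t_sp4 = p.phi4 * t_dp / (p.eps4 + p.mu4)
        t_sp8 = p.phi8 * t_dp / (p.eps8 + p.mu8)
        assert t_dn == pytest.approx(1.805e6, rel=1e-3)
        assert res.state.t_dn == pytest.approx(t_dn, rel=1e-9)
        assert res.state.t_dp == pytest.approx(t_dp, rel=1e-9)
        assert res.state.t_sp4 == pytest.approx(t_sp4, rel=1e-9)
        assert res.state.t_sp8 == pytest.approx(t_sp8, rel=1e-9)

    def test_zero_inflow_zero_start_stays_zero(self, infant_caps):
        p = HomeostasisParams(phi=0.0)
        res = steady_state(p, infant_caps, initial_state=ThymocyteState(0, 0, 0, 0))
        assert res.converged
        assert res.state.total == 0.0

    def test_capacity_attraction(self, base_params, infant_caps):
        res = steady_state(base_params, infant_caps)
        s = res.state
        assert s.t_dn + s.t_dp < infant_caps.t_cort_max
        assert s.t_sp4 + s.t_sp8 < infant_caps.t_med_max

    def test_agrees_with_long_integration(self, infant_caps, settings):
        """Semi-analytic steady state matches forward integration to 2e4 d
        within 0.1% on random draws from the generalized bounds."""
        sets = lhs_sample(GENERALIZED_BOUNDS, 12, seed=2024)
        states, conv, _ = steady_state_batch(sets.to_numpy(), infant_caps)
        assert conv.all()
        for i in range(len(sets)):
            p = HomeostasisParams(**sets.iloc[i].to_dict())
            sol = solve_ivp(
                lambda t, y: independent_rhs(y, infant_caps, p),
                (0, 2e4), np.full(4, 1e6), method="LSODA",
                rtol=1e-10, atol=1.0)
            assert sol.success
            assert states[i] == pytest.approx(sol.y[:, -1], rel=1e-3)

    def test_batch_matches_scalar(self, base_params, infant_caps):
        states, conv, _ = steady_state_batch(
            base_params.as_array()[None, :], infant_caps)
        scalar = steady_state(base_params, infant_caps)
        assert conv[0]
        assert states[0] == pytest.approx(scalar.state.as_array(), rel=1e-10)


class TestSimulate:
    def test_frozen_involution_is_stationary(self, base_params):
        inv = InvolutionParams(k_tes=1e-15, k_cm=1e-15, gamma=60.0)
        series = simulate(base_params, inv, age_start=0.0, age_end=10.0)
        for nm in ("t_dn", "t_dp", "t_sp4", "t_sp8"):
            vals = getattr(series, nm)
            assert np.all(np.abs(vals / vals[0] - 1) < 1e-4), nm

    def test_proportion_trends_with_age(self, base_params, inv_params):
        series = simulate(base_params, inv_params, age_start=0.0, age_end=90.0)
        total = series.t_dn + series.t_dp + series.t_sp4 + series.t_sp8
        frac_dn = series.t_dn / total
        frac_dp = series.t_dp / total
        frac_sp = (series.t_sp4 + series.t_sp8) / total
        assert frac_dn[-1] < frac_dn[0]
        assert frac_dp[-1] < frac_dp[0]
        assert frac_sp[-1] > frac_sp[0]

    def test_tolerance_refinement(self, base_params, inv_params):
        coarse = SimulationSettings(rel_tol=1e-8, abs_tol=1.0)
        fine = SimulationSettings(rel_tol=5e-9, abs_tol=0.5)
        a = simulate(base_params, inv_params, coarse, 0.0, 40.0)
        b = simulate(base_params, inv_params, fine, 0.0, 40.0)
        for nm in ("t_dn", "t_dp", "t_sp4", "t_sp8"):
            assert np.allclose(getattr(a, nm), getattr(b, nm), rtol=1e-3)

    def test_non_negative_trajectories(self, base_params, inv_params):
        series = simulate(base_params, inv_params, age_start=0.0, age_end=60.0,
                          initial_state=ThymocyteState(1e6, 1e6, 1e6, 1e6))
        for nm in ("t_dn", "t_dp", "t_sp4", "t_sp8"):
            assert np.all(getattr(series, nm) >= 0)

    def test_invalid_span_rejected(self, base_params):
        with pytest.raises(ValueError):
            simulate(base_params, age_start=50.0, age_end=10.0)


class TestThymicOutput:
    def test_values_and_linearity(self, base_params):
        assert thymic_output(ThymocyteState(1e9, 1e9, 0, 0), base_params) == 0.0
        s = ThymocyteState(0, 0, 7.43e9, 2.79e9)
        p = replace(base_params, eps4=0.06, eps8=0.06)
        assert thymic_output(s, p) == pytest.approx(0.06 * (7.43e9 + 2.79e9), rel=1e-12)
        assert thymic_output(s, p) == pytest.approx(6.13e8, rel=1e-2)
        doubled = replace(p, eps4=0.12, eps8=0.12)
        assert thymic_output(s, doubled) == pytest.approx(2 * thymic_output(s, p), rel=1e-12)
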