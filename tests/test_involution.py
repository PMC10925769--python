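"""Involution curves, carrying capacities, and curve fitting."""

import numpy as np
import pytest
from hypothesis import given, settings as hyp_settings, strategies as st

from thymosim import (CalibrationSeries, InvolutionParams, MorphometryParams,
                      NoiseSpec, capacities, cm_ratio, fit_involution,
                      gen_involution_series, infant_capacities,
                      relative_cortex_volume, tes_fraction, wet_weight)
from thymosim.involution import _INFANT_QUAD_POINTS


class TestCurves:
    def test_wet_weight_closed_form(self, inv_params):
        # age 0: the Hill term vanishes, leaving the infant weight
        assert wet_weight(0.0, inv_params) == pytest.approx(20.652)
        # half-maximum at the EC50 age, by construction
        assert wet_weight(inv_params.ec50, inv_params) == pytest.approx(20.652 / 2)
        # direct high-precision evaluation of the closed form at age 20
        a, g, e = 20.0, inv_params.gamma, inv_params.ec50
        expected = 20.652 * (1 - a**g / (a**g + e**g))
        assert expected == pytest.approx(20.59, abs=0.01)
        assert wet_weight(20.0, inv_params) == pytest.approx(expected, rel=1e-12)

    def test_tes_fraction_closed_form(self, inv_params):
        assert tes_fraction(0.0, inv_params) == pytest.approx(93.344)
        # 93.344 * exp(-0.035*40) = 93.344 * e^-1.4
        assert tes_fraction(40.0, inv_params) == pytest.approx(
            93.344 * np.exp(-1.4), rel=1e-12)
        assert tes_fraction(40.0, inv_params) == pytest.approx(23.02, abs=0.01)

    def test_cm_ratio_closed_form(self, inv_params):
        assert cm_ratio(0.0, inv_params) == pytest.approx(2.77)
        half_life = np.log(2) / inv_params.k_cm
        assert half_life == pytest.approx(19.80, abs=0.01)
        assert cm_ratio(half_life, inv_params) == pytest.approx(2.77 / 2, rel=1e-12)

    @pytest.mark.parametrize("fn", [wet_weight, tes_fraction, cm_ratio])
    def test_strictly_decreasing_and_positive(self, fn, inv_params):
        ages = np.linspace(0.0, 100.0, 400)
        vals = fn(ages, inv_params)
        assert np.all(vals > 0)
        assert np.all(np.diff(vals) < 0)

    @pytest.mark.parametrize("fn", [wet_weight, tes_fraction, cm_ratio, capacities])
    def test_negative_age_rejected(self, fn, inv_params):
        with pytest.raises(ValueError):
            fn(-0.5, inv_params)


class TestCapacities:
    def test_infant_cortex_value(self, inv_params):
        # t0 * CM/(CM+1) at age 0
        c = capacities(0.0, inv_params)
        assert c.t_cort_max == pytest.approx(4.0e10 * 2.77 / 3.77, rel=1e-12)

    @hyp_settings(max_examples=50, deadline=None, derandomize=True)
    @given(age=st.floats(0.0, 100.0),
           k_tes=st.floats(0.001, 0.1), k_cm=st.floats(0.001, 0.1))
    def test_algebraic_identities(self, age, k_tes, k_cm):
        p = InvolutionParams(k_tes=k_tes, k_cm=k_cm)
        c = capacities(age, p)
        # cortex/medulla ratio is exactly the cortico-medullary ratio
        assert c.t_cort_max / c.t_med_max == pytest.approx(cm_ratio(age, p), rel=1e-12)
        # the sum conserves t0 scaled by the weight*TES decline
        rel = wet_weight(age, p) * tes_fraction(age, p) / (p.ww_bl * p.b_tes)
        assert c.t_cort_max + c.t_med_max == pytest.approx(p.t0 * rel, rel=1e-12)

    def test_capacities_decrease_with_age(self, inv_params):
        ages = np.linspace(0.0, 100.0, 200)
        c = capacities(ages, inv_params)
        assert np.all(np.diff(c.t_cort_max) < 0)
        assert np.all(np.diff(c.t_med_max) < 0)

    def test_flat_involution_keeps_infant_capacities(self):
        # no TES/CM decay and a very steep late Hill: capacities stay at age-0
        p = InvolutionParams(k_tes=1e-12, k_cm=1e-12, gamma=80.0)
        c0, c40 = capacities(0.0, p), capacities(40.0, p)
        assert c40.t_cort_max == pytest.approx(c0.t_cort_max, rel=1e-6)
        assert c40.t_med_max == pytest.approx(c0.t_med_max, rel=1e-6)


class TestInfantCapacities:
    def test_matches_calibration_values(self, inv_params, infant_caps):
        ic = infant_capacities(inv_params)
        assert ic.t_cort_max == pytest.approx(infant_caps.t_cort_max, rel=0.05)
        assert ic.t_med_max == pytest.approx(infant_caps.t_med_max, rel=0.05)

    def test_flat_involution_reduces_to_age_zero(self):
        p = InvolutionParams(k_tes=1e-15, k_cm=1e-15, gamma=60.0)
        ic, c0 = infant_capacities(p), capacities(0.0, p)
        assert ic.t_cort_max == pytest.approx(c0.t_cort_max, rel=1e-9)
        assert ic.t_med_max == pytest.approx(c0.t_med_max, rel=1e-9)

    def test_quadrature_scheme_insensitive(self, inv_params):
        # midpoint rule vs the Simpson default agrees to < 0.1%
        ages = np.linspace(0.0, 1.0, 2001)
        mid = 0.5 * (ages[:-1] + ages[1:])
        c = capacities(mid, inv_params)
        ref_c = float(np.mean(c.t_cort_max))
        ref_m = float(np.mean(c.t_med_max))
        ic = infant_capacities(inv_params)
        assert ic.t_cort_max == pytest.approx(ref_c, rel=1e-3)
        assert ic.t_med_max == pytest.approx(ref_m, rel=1e-3)


class TestRelativeCortexVolume:
    def test_infant_reference_is_one(self, inv_params):
        m = MorphometryParams()
        ages = np.linspace(0.0, 1.0, _INFANT_QUAD_POINTS)
        from scipy.integrate import simpson
        vals = relative_cortex_volume(ages, inv_params, m)
        assert simpson(vals, x=ages) == pytest.approx(1.0, rel=1e-12)

    def test_constant_morphometry_reduces_to_capacity_shape(self, inv_params):
        m = MorphometryParams(k_d=0.0, b_d=1.0, k_v=0.0, b_v=25.0)
        ages = np.array([0.0, 10.0, 30.0, 60.0])
        vals = relative_cortex_volume(ages, inv_params, m)
        cm = cm_ratio(ages, inv_params)
        shape = cm / (cm + 1) * wet_weight(ages, inv_params) * tes_fraction(ages, inv_params)
        ratio = vals / shape
        assert np.allclose(ratio, ratio[0], rtol=1e-12)

    def test_decreasing_in_age(self, inv_params):
        ages = np.linspace(0.0, 90.0, 100)
        vals = relative_cortex_volume(ages, inv_params, MorphometryParams())
        assert np.all(np.diff(vals) < 0)

    def test_domain_errors(self, inv_params):
        with pytest.raises(ValueError):
            relative_cortex_volume(101.0, inv_params, MorphometryParams())
        # a morphometry whose density goes negative inside the age domain
        # is rejected at construction
        with pytest.raises(ValueError):
            MorphometryParams(k_d=-0.02, b_d=1.0)


class TestFitting:
    @pytest.mark.parametrize("kind,truth_attr", [
        ("wet_weight", ("ww_bl", "ec50", "gamma")),
        ("tes_fraction", ("b_tes", "k_tes")),
        ("cm_ratio", ("b_cm", "k_cm")),
    ])
    def test_noiseless_recovery(self, inv_params, kind, truth_attr):
        series = gen_involution_series(inv_params, kind, noise=NoiseSpec(kind="none"))
        fit = fit_involution(series)
        assert fit.converged
        for nm in truth_attr:
            assert fit.estimates[nm] == pytest.approx(getattr(inv_params, nm), rel=1e-4)
        assert fit.residual_sum_squares < 1e-12 * np.sum(series.values ** 2)

    def test_noiseless_linear_recovery(self):
        m = MorphometryParams()
        for kind, names in (("density", ("k_d", "b_d")), ("volume", ("k_v", "b_v"))):
            fit = fit_involution(gen_involution_series(m, kind, noise=NoiseSpec(kind="none")))
            for nm in names:
                assert fit.estimates[nm] == pytest.approx(getattr(m, nm), rel=1e-6)

    def test_rse_definition(self, inv_params):
        # RSE = 100*SE/estimate: an estimate of 2.77 with SE 0.206 gives 7.4%
        assert 100 * 0.206 / 2.77 == pytest.approx(7.4, abs=0.05)
        series = gen_involution_series(
            inv_params, "cm_ratio",
            noise=NoiseSpec("multiplicative_lognormal", 0.1, seed=3))
        fit = fit_involution(series)
        for nm in fit.estimates:
            assert fit.rse_percent[nm] == pytest.approx(
                100 * fit.se[nm] / abs(fit.estimates[nm]), rel=1e-12)

    def test_insufficient_data_rejected(self, inv_params):
        series = CalibrationSeries([0.0, 50.0, 90.0], [20.0, 15.0, 10.0], "wet_weight")
        with pytest.raises(ValueError, match="distinct ages"):
            fit_involution(series)

    def test_noisy_fit_coverage(self, inv_params):
        """True parameters fall inside +-2 SE in >=90% of noisy replicates."""
        ages = np.linspace(0.5, 90.0, 30)
        n_rep, hits = 200, {"b_cm": 0, "k_cm": 0}
        for rep in range(n_rep):
            series = gen_involution_series(
                inv_params, "cm_ratio", ages,
                NoiseSpec("multiplicative_lognormal", 0.1, seed=10_000 + rep))
            fit = fit_involution(series)
            for nm in hits:
                true = getattr(inv_params, nm)
                if abs(fit.estimates[nm] - true) <= 2 * fit.se[nm]:
                    hits[nm] += 1
        for nm, k in hits.items():
            assert k / n_rep >= 0.90, f"{nm}: coverage {k / n_rep}"
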