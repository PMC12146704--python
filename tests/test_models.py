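"""Constitutive model family, Laplace/stress relations, parameter maps."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nucleorheo.models import (
    Interface,
    InvalidGeometryError,
    MaterialParams,
    ModelClass,
    StressContext,
    UnphysicalFitError,
    coefficients_to_params,
    effective_stress,
    inverse_capillary_velocity,
    laplace_pressure,
    maxwell_jump,
    params_to_coefficients,
    strain_response,
)
from nucleorheo.tension import tension_from_laplace


class TestLaplacePressure:
    @pytest.mark.parametrize(
        "gamma,Rp,Rc,expected",
        [
            (1.7, 1.0, math.inf, 3.4),
            (1.7, 1.0, 5.0, 2.72),
            (0.5, 1.0, math.inf, 1.0),
            (2.3, 2.3, 2.3, 0.0),  # equal curvatures cancel
        ],
    )
    def test_values(self, gamma, Rp, Rc, expected):
        assert laplace_pressure(gamma, Rp, Rc) == pytest.approx(expected)

    def test_droplet_smaller_than_pipette_rejected(self):
        with pytest.raises(InvalidGeometryError):
            laplace_pressure(1.0, 2.0, 1.0)

    def test_negative_tension_rejected(self):
        with pytest.raises(ValueError):
            laplace_pressure(-0.1, 1.0)

    @given(
        gamma=st.floats(1e-3, 100.0),
        Rp=st.floats(0.1, 10.0),
        rc_factor=st.floats(1.001, 1e6),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_inverse_with_tension_from_laplace(self, gamma, Rp, rc_factor):
        """Laplace pressure and tension inference are mutual inverses."""
        Rc = Rp * rc_factor
        p = laplace_pressure(gamma, Rp, Rc)
        assert tension_from_laplace(p, Rp, Rc) == pytest.approx(gamma, rel=1e-12)
        p_flat = laplace_pressure(gamma, Rp)
        assert tension_from_laplace(p_flat, Rp) == pytest.approx(gamma, rel=1e-12)


class TestEffectiveStress:
    def test_single_interface(self):
        ctx = StressContext(20.0, (Interface(1.7, 1.0, 5.0),))
        assert effective_stress(ctx) == pytest.approx(20.0 - 2.72)

    def test_no_interfaces_identity(self):
        assert effective_stress(StressContext(5.0)) == 5.0

    def test_summed_interfaces(self):
        # outer GC surface (2.72 Pa) plus internal GC-DFC interface (0.8 Pa)
        ctx = StressContext(20.0, (Interface(1.7, 1.0, 5.0), Interface(0.4, 1.0)))
        assert effective_stress(ctx) == pytest.approx(16.48)

    def test_negative_stress_flagged_not_error(self):
        ctx = StressContext(1.0, (Interface(1.7, 1.0),))
        assert effective_stress(ctx) < 0
        assert ctx.capillarity_dominates


class TestStrainResponse:
    def test_all_models_zero_at_t0(self):
        p = MaterialParams(eta_eff=250.0, E_eff=3.1)
        for m in ModelClass:
            assert strain_response(m, p, 20.0, 0.0) == 0.0

    def test_kelvin_voigt_plateau(self, dfc_params):
        # plateau sigma/E = 20/3.1
        val = strain_response(ModelClass.KELVIN_VOIGT, dfc_params, 20.0, 1e7)
        assert val == pytest.approx(6.4516, rel=1e-4)

    def test_newtonian_closed_form(self):
        p = MaterialParams(eta_eff=50.0)
        assert strain_response(ModelClass.NEWTONIAN, p, 5.0, 10.0) == pytest.approx(1.0)

    def test_maxwell_dominates_newtonian_by_jump(self, dfc_params):
        t = np.linspace(0.1, 100, 40)
        mx = strain_response(ModelClass.MAXWELL, dfc_params, 20.0, t)
        nw = strain_response(ModelClass.NEWTONIAN, dfc_params, 20.0, t)
        np.testing.assert_allclose(mx - nw, maxwell_jump(dfc_params, 20.0))

    def test_kelvin_voigt_monotone_and_bounded(self, dfc_params):
        t = np.linspace(0, 2000, 500)
        eps = strain_response(ModelClass.KELVIN_VOIGT, dfc_params, 20.0, t)
        assert np.all(np.diff(eps) >= 0)
        assert np.all(eps <= 20.0 / 3.1 + 1e-12)

    def test_invalid_params_rejected(self):
        with pytest.raises(UnphysicalFitError):
            MaterialParams(eta_eff=-1.0)


class TestCoefficientMaps:
    def test_kelvin_voigt_worked_example(self):
        p = coefficients_to_params(
            ModelClass.KELVIN_VOIGT, A=5.574, D=0.0124, sigma=17.28
        )
        assert p.E_eff == pytest.approx(3.10, rel=1e-3)
        assert p.eta_eff == pytest.approx(250.0, rel=1e-3)

    def test_newtonian_identity_scale(self):
        assert coefficients_to_params(ModelClass.NEWTONIAN, B=1.0, sigma=1.0).eta_eff == 1.0

    def test_newtonian_gc_magnitude(self):
        p = coefficients_to_params(ModelClass.NEWTONIAN, B=0.0227, sigma=5.0)
        assert p.eta_eff == pytest.approx(220.0, rel=0.01)

    def test_unphysical_coefficients_rejected(self):
        with pytest.raises(UnphysicalFitError):
            coefficients_to_params(ModelClass.NEWTONIAN, B=-0.1, sigma=5.0)
        with pytest.raises(UnphysicalFitError):
            coefficients_to_params(ModelClass.KELVIN_VOIGT, A=1.0, D=-1.0, sigma=5.0)

    @given(
        eta=st.floats(1.0, 1e4),
        E=st.floats(0.1, 100.0),
        sigma=st.floats(0.1, 100.0),
        model=st.sampled_from(list(ModelClass)),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_roundtrip_identity(self, eta, E, sigma, model):
        """coefficients_to_params inverts the forward parameter->coefficient map."""
        p = MaterialParams(eta_eff=eta, E_eff=E)
        coef = params_to_coefficients(model, p, sigma)
        back = coefficients_to_params(model, **coef, sigma=sigma)
        assert back.eta_eff == pytest.approx(eta, rel=1e-9)
        if model is not ModelClass.NEWTONIAN:
            assert back.E_eff == pytest.approx(E, rel=1e-9)

    def test_linear_scaling_in_stress(self):
        """Doubling effective stress doubles eta and E for fixed coefficients."""
        p1 = coefficients_to_params(ModelClass.KELVIN_VOIGT, A=5.0, D=0.01, sigma=10.0)
        p2 = coefficients_to_params(ModelClass.KELVIN_VOIGT, A=5.0, D=0.01, sigma=20.0)
        assert p2.eta_eff == pytest.approx(2 * p1.eta_eff)
        assert p2.E_eff == pytest.approx(2 * p1.E_eff)

    def test_uncertainty_propagation_first_order(self):
        p = coefficients_to_params(
            ModelClass.KELVIN_VOIGT, A=5.0, D=0.01, sigma=10.0, se_A=0.5, se_D=0.001
        )
        rel = math.hypot(0.5 / 5.0, 0.001 / 0.01)
        assert p.eta_err == pytest.approx(p.eta_eff * rel)
        assert p.E_err == pytest.approx(p.E_eff * 0.1)


class TestInverseCapillaryVelocity:
    @pytest.mark.parametrize(
        "eta,gamma,expected,rel",
        [
            (220.0, 1.7, 129.41, 1e-3),  # published GC value, printed as ~130
            (38.0, 1.7, 22.35, 1e-3),  # <1h-old GC subset, printed as ~22
            (1.0, 1.0, 1.0, 1e-12),
        ],
    )
    def test_values(self, eta, gamma, expected, rel):
        assert inverse_capillary_velocity(eta, gamma) == pytest.approx(expected, rel=rel)

    def test_zero_tension_undefined(self):
        with pytest.raises(ValueError):
            inverse_capillary_velocity(100.0, 0.0)

    def test_si_unit_self_consistency(self):
        """eta/gamma in s/um equals eta/gamma in SI times 1e-6 m/um."""
        eta_si, gamma_si = 220.0, 1.7e-6  # Pa*s, N/m
        assert inverse_capillary_velocity(220.0, 1.7) == pytest.approx(
            (eta_si / gamma_si) * 1e-6
        )
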