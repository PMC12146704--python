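"""Creep-trace fitting, model selection, and per-nucleolus aggregation."""

import math

import numpy as np
import pytest

from nucleorheo.creep import (
    AspirationTrace,
    aggregate_params,
    compute_strain,
    fit_model,
    select_model,
)
from nucleorheo.models import (
    Interface,
    MaterialParams,
    ModelClass,
    StressContext,
)
from nucleorheo import synthetic as syn


def make_trace(times, Lp, Rp=1.0, **kw):
    kw.setdefault("P", 20.0)
    return AspirationTrace(times=np.asarray(times), Lp=np.asarray(Lp), Rp=Rp, **kw)


class TestComputeStrain:
    def test_direct_substitution(self):
        tr = make_trace([0, 1, 2, 3, 4], [2, 3, 4, 5, 6], Rp=1.0)
        np.testing.assert_allclose(compute_strain(tr), [0, 1, 2, 3, 4])

    def test_constant_trace_zero_strain(self):
        tr = make_trace(range(5), [3.0] * 5)
        np.testing.assert_allclose(compute_strain(tr), 0.0)

    def test_half_micron_pipette(self):
        tr = make_trace([0, 1, 2, 3, 4], [5.0, 5.5, 6.0, 6.5, 7.0], Rp=0.5)
        np.testing.assert_allclose(compute_strain(tr), [0, 1, 2, 3, 4])

    def test_first_frame_exactly_zero(self, noiseless_kv_trace):
        assert compute_strain(noiseless_kv_trace)[0] == 0.0

    def test_invalid_geometry(self):
        with pytest.raises(ValueError):
            make_trace(range(5), range(5), Rp=-1.0)


class TestFitModel:
    def test_noiseless_newtonian_recovery(self):
        t = np.arange(0, 200, 2.0)
        f = fit_model(0.05 * t, t, ModelClass.NEWTONIAN)
        assert f.converged
        assert f.B == pytest.approx(0.05, rel=1e-6)
        assert f.mse < 1e-16

    def test_noiseless_kelvin_voigt_recovery(self):
        t = np.arange(0, 300, 2.0)
        eps = 6.45 * (1 - np.exp(-0.0124 * t))
        f = fit_model(eps, t, ModelClass.KELVIN_VOIGT)
        assert f.A == pytest.approx(6.45, rel=1e-6)
        assert f.D == pytest.approx(0.0124, rel=1e-6)
        assert f.C == pytest.approx(-f.A)  # eps(0)=0 constraint
        assert f.mse < 1e-16

    def test_noiseless_residuals_below_oracle_tolerance(self, noiseless_kv_trace):
        eps = compute_strain(noiseless_kv_trace)
        f = fit_model(eps, noiseless_kv_trace.times, ModelClass.KELVIN_VOIGT)
        assert math.sqrt(f.mse) < 1e-8

    def test_newtonian_equals_through_origin_slope(self):
        """Constrained-through-zero LSQ slope is the closed-form oracle for B."""
        rng = np.random.default_rng(7)
        t = np.arange(0, 100, 2.0)
        eps = 0.03 * t + rng.normal(0, 0.05, t.size)
        eps[0] = 0.0
        f = fit_model(eps, t, ModelClass.NEWTONIAN)
        slope = np.sum(t * eps) / np.sum(t * t)
        assert f.B == pytest.approx(slope, rel=1e-9)

    def test_noisy_kv_recovery_within_ten_percent(self):
        """Median A and D over 20 seeded replicates at 2% plateau noise."""
        A_true, D_true = 6.45, 0.0124
        t = np.arange(0, 300, 2.0)
        ratios_A, ratios_D = [], []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            eps = A_true * (1 - np.exp(-D_true * t)) + rng.normal(0, 0.02 * A_true, t.size)
            f = fit_model(eps, t, ModelClass.KELVIN_VOIGT)
            ratios_A.append(f.A / A_true)
            ratios_D.append(f.D / D_true)
        assert abs(np.median(ratios_A) - 1) < 0.10
        assert abs(np.median(ratios_D) - 1) < 0.10

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_model([0, 1, 2], [0, 1, 2], ModelClass.NEWTONIAN)


class TestSelectModel:
    def test_pure_linear_selects_newtonian(self):
        t = np.arange(0, 100, 2.0)
        winner, fits = select_model(0.02 * t, t)
        assert winner is ModelClass.NEWTONIAN
        assert set(fits) == set(ModelClass)

    def test_saturating_exponential_selects_kelvin_voigt(self):
        t = np.arange(0, 300, 2.0)
        eps = 5.0 * (1 - np.exp(-0.01 * t))
        winner, fits = select_model(eps, t)
        assert winner is ModelClass.KELVIN_VOIGT
        ratio = fits[ModelClass.NEWTONIAN].mse / max(fits[ModelClass.KELVIN_VOIGT].mse, 1e-300)
        assert ratio > 2.0

    def test_never_richer_on_simpler_noiseless_data(self):
        """Zero-noise Newtonian traces across a parameter sweep never elect a
        two-parameter model."""
        t = np.arange(0, 200, 2.0)
        for B in [1e-3, 0.01, 0.1, 1.0]:
            winner, _ = select_model(B * t, t)
            assert winner is ModelClass.NEWTONIAN, f"B={B}"

    def test_noisy_kv_cohort_selection_rate(self):
        """>= 95% of noisy Kelvin-Voigt traces are identified as such."""
        t = np.arange(0, 300, 2.0)
        A_true, D_true = 6.45, 0.0124
        picked = 0
        n = 40
        for seed in range(n):
            rng = np.random.default_rng(seed)
            eps = A_true * (1 - np.exp(-D_true * t)) + rng.normal(0, 0.02 * A_true, t.size)
            winner, _ = select_model(eps, t)
            picked += winner is ModelClass.KELVIN_VOIGT
        assert picked / n >= 0.95


class TestAggregateParams:
    def _fit(self, B, nucleolus_id):
        t = np.arange(0, 100, 2.0)
        return fit_model(B * t, t, ModelClass.NEWTONIAN, nucleolus_id=nucleolus_id)

    def test_two_nucleoli_mean_and_sem(self):
        # eta = sigma/B: sigma=10 with B=0.1 -> 100, B=1/30 -> 300
        fits = [self._fit(0.1, "n1"), self._fit(1 / 30, "n2")]
        ctx = StressContext(10.0)
        out = aggregate_params(fits, {"n1": ctx, "n2": ctx})
        est = out["eta_eff"]
        assert est.mean == pytest.approx(200.0)
        assert est.sem == pytest.approx(100.0)
        assert est.n_nucleoli == 2 and est.n_measurements == 2

    def test_within_nucleolus_averaging_prevents_overweighting(self):
        """A nucleolus measured twice counts once in the cohort mean."""
        fits = [self._fit(0.1, "n1"), self._fit(0.3, "n1"), self._fit(0.2, "n2")]
        ctx = StressContext(10.0)
        out = aggregate_params(fits, {"n1": ctx, "n2": ctx})
        # within-first: n1 mean B = 0.2, n2 B = 0.2 -> eta 50 both -> cohort 50
        assert out["eta_eff"].mean == pytest.approx(50.0)

    def test_duplicating_a_trace_leaves_cohort_mean_unchanged(self):
        ctx = StressContext(10.0)
        base = [self._fit(0.1, "n1"), self._fit(0.3, "n1"), self._fit(0.2, "n2")]
        dup = base + [self._fit(0.1, "n1")]
        m1 = aggregate_params(base, {"n1": ctx, "n2": ctx})["eta_eff"].per_nucleolus["n2"]
        m2 = aggregate_params(dup, {"n1": ctx, "n2": ctx})["eta_eff"].per_nucleolus["n2"]
        assert m1 == m2
        # n2 untouched, and the cohort is a mean over nucleolus values only
        assert aggregate_params(dup, {"n1": ctx, "n2": ctx})["eta_eff"].n_nucleoli == 2

    def test_order_invariance(self):
        ctx = StressContext(10.0)
        fits = [self._fit(0.1, "n1"), self._fit(0.3, "n1"), self._fit(0.2, "n2")]
        a = aggregate_params(fits, {"n1": ctx, "n2": ctx})["eta_eff"].mean
        b = aggregate_params(fits[::-1], {"n1": ctx, "n2": ctx})["eta_eff"].mean
        assert a == pytest.approx(b)

    def test_single_nucleolus_sem_undefined(self):
        out = aggregate_params([self._fit(0.1, "n1")], {"n1": StressContext(10.0)})
        assert math.isnan(out["eta_eff"].sem)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            aggregate_params([], {})

    def test_kelvin_voigt_cohort_reports_both_parameters(self, noiseless_kv_trace):
        eps = compute_strain(noiseless_kv_trace)
        f = fit_model(eps, noiseless_kv_trace.times, ModelClass.KELVIN_VOIGT,
                      nucleolus_id="n1")
        ctx = StressContext(20.0, (Interface(1.7, 1.0),))
        out = aggregate_params([f], {"n1": ctx})
        assert out["eta_eff"].mean == pytest.approx(250.0, rel=1e-4)
        assert out["E_eff"].mean == pytest.approx(3.1, rel=1e-4)
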