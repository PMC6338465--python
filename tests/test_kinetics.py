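"""Steady-state velocities, force coupling, and Michaelis-Menten behavior."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ratchetfit.kinetics import (GeometryContext, LogisticParams, RateSet,
                                 bell_factors, equilibrium_shift, fit_logistic,
                                 fit_mm_curve, logistic_velocity,
                                 mm_parameters, steady_state_velocity,
                                 thermal_force_scale, velocity_grid)
from ratchetfit.polymer import KBT_PN_NM, NM_PER_BP, ForkParams
from ratchetfit.schemes import enumerate_schemes, get_scheme

KBT = KBT_PN_NM


class TestBellFactors:
    def test_zero_force_identity(self):
        assert bell_factors(0.0, 3.3, 3.3) == (1.0, 1.0)

    def test_forward_loaded_barrier_has_unit_backward_factor(self):
        fwd, bwd = bell_factors(25.0, 3.3, 3.3)
        assert bwd == 1.0
        assert fwd < 1.0

    def test_unit_exponent(self):
        # F * x_dagger * 0.34 / kBT = 1  ->  forward factor e^-1
        delta = 2.0
        F = KBT / (delta * NM_PER_BP)
        fwd, _ = bell_factors(F, delta, delta)
        assert fwd == pytest.approx(math.exp(-1.0), rel=1e-12)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            bell_factors(-1.0, 3.3, 3.3)
        with pytest.raises(ValueError):
            bell_factors(1.0, 3.3, 4.0)
        with pytest.raises(ValueError):
            bell_factors(1.0, 3.3, 0.0)

    @settings(derandomize=True, max_examples=50)
    @given(k_eq=st.floats(1e-3, 1e3), F=st.floats(0.0, 60.0),
           delta=st.floats(0.5, 10.0), frac=st.floats(0.05, 1.0))
    def test_consistent_with_equilibrium_shift(self, k_eq, F, delta, frac):
        """K -> K * backward/forward holds for every transition-state split."""
        xd = frac * delta
        fwd, bwd = bell_factors(F, delta, xd)
        shifted = equilibrium_shift(k_eq, F, delta)
        assert k_eq * bwd / fwd == pytest.approx(shifted, rel=1e-9)

    def test_equilibrium_doubling_force(self):
        delta = 3.3
        F = KBT * math.log(2.0) / (delta * NM_PER_BP)
        assert equilibrium_shift(5.0, F, delta) == pytest.approx(10.0, rel=1e-12)


class TestSteadyStateVelocity:
    @pytest.mark.parametrize("scheme", enumerate_schemes(),
                             ids=lambda s: s.scheme_id)
    def test_no_atp_no_velocity(self, scheme, rates_complex, geom_opposing):
        assert steady_state_velocity(scheme, rates_complex, 10.0, 0.0,
                                     geom_opposing) == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("coupling", ["binding", "hydrolysis", "release"])
    def test_ps_at_zero_force_matches_three_step_closed_form(self, coupling,
                                                             rates_complex):
        """With no force the PS cycle is the textbook 3-step chain."""
        r = rates_complex
        scheme = get_scheme(f"ps-{coupling}")
        mm = mm_parameters(scheme, r, 0.0)
        vmax = r.delta * r.k_h * r.k_r / (r.k_h + r.k_r)
        km = (r.k_minus_b + r.k_h) / r.k_plus_b * (r.k_r / (r.k_h + r.k_r))
        assert mm.v_max == pytest.approx(vmax, rel=1e-5)
        assert mm.K_M == pytest.approx(km, rel=1e-5)

    def test_br_binding_rapid_equilibrium_km_shift(self, rates_complex,
                                                   geom_opposing):
        """Fast fluctuations: v_max force-free, K_M scaled by 1+K e^(F/F0)."""
        r = rates_complex.with_(k_plus_tr=1e9, k_minus_tr=1e8)
        scheme = get_scheme("br-binding")
        F0 = thermal_force_scale(r.delta)
        mm0 = mm_parameters(scheme, r, 0.0, geom_opposing)
        for F in (8.0, 16.0):
            mm = mm_parameters(scheme, r, F, geom_opposing)
            pred = (1 + r.k_eq * math.exp(F / F0)) / (1 + r.k_eq)
            assert mm.v_max == pytest.approx(mm0.v_max, rel=1e-3)
            assert mm.K_M / mm0.K_M == pytest.approx(pred, rel=1e-3)

    def test_hairpin_with_open_fork_matches_force_free_opposing(self,
                                                                rates_isolated):
        """P_open = 1 and F = 0 modify nothing, so the couplings coincide."""
        # an unstable fork (huge destabilization) keeps P_open = 1
        fork = ForkParams(dg_bp=0.1, n_step=1, m_window=10)
        hairpin = GeometryContext(mode="hairpin_assisting", fork=fork)
        r = rates_isolated.with_(dG_dest=4.0)
        scheme = get_scheme("br-binding")
        mm_h = mm_parameters(scheme, r, 12.0, hairpin)
        mm_o = mm_parameters(scheme, r, 0.0, GeometryContext())
        assert mm_h.v_max == pytest.approx(mm_o.v_max, rel=1e-6)
        assert mm_h.K_M == pytest.approx(mm_o.K_M, rel=1e-6)

    @pytest.mark.parametrize("scheme", enumerate_schemes(),
                             ids=lambda s: s.scheme_id)
    def test_monotonicity(self, scheme, rates_complex, rates_isolated,
                          geom_opposing, geom_hairpin):
        F = np.linspace(0.0, 40.0, 15)
        v_op = velocity_grid(scheme, rates_complex, F, 1e-3, geom_opposing)
        assert np.all(np.diff(v_op) <= 1e-9)
        Fh = np.linspace(0.0, 15.0, 12)
        v_hp = velocity_grid(scheme, rates_isolated, Fh, 1e-3, geom_hairpin)
        assert np.all(np.diff(v_hp) >= -1e-9)
        atp = np.logspace(-6, -2, 12)
        v_T = velocity_grid(scheme, rates_complex, 5.0, atp, geom_opposing)
        assert np.all(np.diff(v_T) > 0)

    @pytest.mark.parametrize("scheme", enumerate_schemes(),
                             ids=lambda s: s.scheme_id)
    @pytest.mark.parametrize("geom_name", ["opposing", "hairpin"])
    def test_michaelis_menten_functional_form(self, scheme, geom_name,
                                              rates_complex, rates_isolated,
                                              geom_opposing, geom_hairpin):
        """v([ATP]) at fixed force is Michaelis-Menten to R^2 > 0.9999."""
        if geom_name == "opposing":
            geom, rates, force = geom_opposing, rates_complex, 12.0
        else:
            geom, rates, force = geom_hairpin, rates_isolated, 10.0
        mm = mm_parameters(scheme, rates, force, geom)
        T = np.logspace(math.log10(mm.K_M / 100), math.log10(mm.K_M * 100), 25)
        v = velocity_grid(scheme, rates, force, T, geom)
        resid = v - mm.velocity(T)
        r2 = 1 - np.sum(resid**2) / np.sum((v - v.mean()) ** 2)
        assert r2 > 0.9999
        # spec'd invariant of the MMParams type itself
        assert np.max(np.abs(resid) / np.maximum(v, 1e-12)) < 1e-3

    def test_singular_input_raises_with_diagnostic(self, rates_complex):
        scheme = get_scheme("br-binding")
        with pytest.raises(ValueError):
            velocity_grid(scheme, rates_complex, 5.0, -1e-3)


class TestLogistic:
    def test_half_force_gives_half_velocity(self):
        p = LogisticParams(v0=1000.0, F_half=43.0, F0=4.0)
        assert logistic_velocity(43.0, p) == pytest.approx(500.0)
        F = np.linspace(0, 60, 30)
        assert np.all(np.diff(logistic_velocity(F, p)) < 0)

    def test_noiseless_fit_recovers_parameters(self):
        truth = LogisticParams(v0=1000.0, F_half=43.0, F0=4.0)
        F = np.linspace(2, 60, 20)
        fit = fit_logistic(F, logistic_velocity(F, truth))
        assert fit.v0 == pytest.approx(truth.v0, rel=1e-6)
        assert fit.F_half == pytest.approx(truth.F_half, rel=1e-6)
        assert fit.F0 == pytest.approx(truth.F0, rel=1e-6)

    def test_degenerate_curve_flagged(self):
        F = np.linspace(0, 30, 8)
        with pytest.raises(ValueError, match="constant"):
            fit_logistic(F, np.full_like(F, 123.0))
        with pytest.raises(ValueError, match="4 force bins"):
            fit_logistic([1, 2, 3], [3, 2, 1])

    def test_ps_hydrolysis_curve_is_exactly_logistic(self, rates_complex):
        """Coupling at an irreversible step gives v = v0/(1+exp[(F-F1/2)/F0]).

        Net-rate algebra at any fixed [ATP]: 1/v = A + B exp(F/F0) with
        A = (1/a + 1/kr)/delta and B = (k-b/a + 1)/(kh delta), a = k+b*T —
        which is the logistic law with v0 = 1/A and F1/2 = F0 ln(A/B).
        """
        r = rates_complex
        scheme = get_scheme("ps-hydrolysis")
        F = np.linspace(0.0, 60.0, 40)
        T = 2e-3
        v = velocity_grid(scheme, r, F, T)
        F0 = thermal_force_scale(r.delta)
        a = r.k_plus_b * T
        A = (1 / a + 1 / r.k_r) / r.delta
        B = (r.k_minus_b / a + 1) / (r.k_h * r.delta)
        pred = logistic_velocity(
            F, LogisticParams(v0=1 / A, F_half=F0 * math.log(A / B), F0=F0))
        assert np.allclose(v, pred, rtol=1e-8)


class TestMMFit:
    def test_exact_recovery_and_half_saturation(self):
        T = np.array([20, 100, 350, 1000, 2000]) * 1e-6
        truth_v, truth_k = 1000.0, 1e-4
        v = truth_v * T / (truth_k + T)
        mm = fit_mm_curve(T, v)
        assert mm.v_max == pytest.approx(truth_v, rel=1e-6)
        assert mm.K_M == pytest.approx(truth_k, rel=1e-6)
        assert mm.velocity(truth_k) == pytest.approx(truth_v / 2)

    def test_needs_three_concentrations(self):
        with pytest.raises(ValueError):
            fit_mm_curve([1e-4, 2e-4], [10, 20])


def test_rate_set_invariants():
    r = RateSet(k_plus_b=1e6, k_minus_b=100, k_h=50, k_r=200,
                k_plus_tr=1e4, k_minus_tr=1e3)
    assert r.k_eq == pytest.approx(0.1)
    assert r.k_c_eff == pytest.approx(40.0)
    assert r.k_c_eff <= min(r.k_h, r.k_r)
    assert r.xd == r.delta
    with pytest.raises(ValueError):
        RateSet(k_plus_b=0, k_minus_b=1, k_h=1, k_r=1)
    with pytest.raises(ValueError):
        RateSet(k_plus_b=1, k_minus_b=1, k_h=1, k_r=1, delta=3.3, x_dagger=4.0)
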