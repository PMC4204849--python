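"""Unperturbed lifespan growth model: efficiency functions, closed forms,
asymptotic bounds, linear-phase slope, and the method-of-steps solver
against an independent brute-force oracle."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lstgi import (GrowthParameters, asymptotic_bounds, closed_form_constant_p,
                   efficiency, linear_phase_slope, simulate_unperturbed)
from lstgi.growth import production_rate_product

from conftest import brute_force_unperturbed

CONST = GrowthParameters(T=1.0, k_in0=0.05, w0=1.0, p0=2.0, mode="constant_p")


class TestEfficiency:
    def test_plateau_below_threshold(self):
        gp = GrowthParameters(T=1.0, k_in0=0.05, w0=1.0, p0=2.0, w_th=10.0)
        assert efficiency(1e-3, gp, "threshold_power") == pytest.approx(
            2.0, abs=1e-9)

    def test_limit_one_at_large_size(self):
        gp = GrowthParameters(T=1.0, k_in0=0.05, w0=1.0, p0=1.8, w_th=10.0)
        for form in ("threshold_power", "switch_limit", "linear_phase"):
            assert efficiency(1e12, gp, form) == pytest.approx(1.0, abs=1e-6)

    def test_linear_phase_equals_switch_limit_above_threshold(self):
        """For w > w_th the identifiable-product form 1 + (p0-1) w_th / w
        coincides with the sharp-switch limit."""
        gp = GrowthParameters(T=1.0, k_in0=0.05, w0=1.0, p0=1.7, w_th=3.0)
        gp_lin = gp.with_(mode="linear_phase", p_wth=(1.7 - 1.0) * 3.0)
        w = np.logspace(np.log10(3.0001), 4, 50)
        assert np.allclose(efficiency(w, gp_lin, "linear_phase"),
                           efficiency(w, gp, "switch_limit"), rtol=1e-12)

    def test_sharp_psi_approaches_switch_limit(self):
        """psi = 200 is within 1% of the piecewise limit away from the
        threshold."""
        gp = GrowthParameters(T=1.0, k_in0=0.05, w0=1.0, p0=2.0, w_th=10.0,
                              psi=200.0)
        w = np.concatenate([np.logspace(-2, np.log10(9.4), 40),
                            np.logspace(np.log10(10.6), 3, 40)])
        assert np.allclose(efficiency(w, gp, "threshold_power"),
                           efficiency(w, gp, "switch_limit"), rtol=1e-2)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(w=st.floats(0.0, 1e6), p0=st.floats(1.0, 2.0),
           w_th=st.floats(1e-3, 1e3), psi=st.floats(0.5, 50.0))
    def test_bounded_and_decreasing(self, w, p0, w_th, psi):
        gp = GrowthParameters(T=1.0, k_in0=0.05, w0=1.0, p0=p0, w_th=w_th,
                              psi=psi)
        p = efficiency(w, gp, "threshold_power")
        assert 1.0 - 1e-12 <= p <= p0 + 1e-12
        assert efficiency(w + 1.0, gp, "threshold_power") <= p + 1e-12

    def test_errors(self):
        gp = GrowthParameters(T=1.0, k_in0=0.05, w0=1.0, p0=2.0, w_th=10.0)
        with pytest.raises(ValueError):
            efficiency(-1.0, gp)
        with pytest.raises(ValueError):
            efficiency(0.0, gp.with_(mode="linear_phase", p_wth=5.0),
                       "linear_phase")


class TestConstantEfficiency:
    def test_discrete_sum_oracle(self):
        """w(nT) = w0 + k_in0*T*(p0^n - 1), exact piecewise-linear
        structure."""
        for n in range(1, 11):
            expect = 1.0 + 0.05 * 1.0 * (2.0 ** n - 1.0)
            assert closed_form_constant_p(CONST, n * 1.0) == pytest.approx(
                expect, rel=1e-12)
        assert closed_form_constant_p(CONST, 0.0) == 1.0
        assert closed_form_constant_p(CONST, 3.0) == pytest.approx(1.35)

    def test_simulation_matches_closed_form(self):
        traj = simulate_unperturbed(CONST, 20.0, pps=200)
        t = np.linspace(0.0, 20.0, 501)
        cf = closed_form_constant_p(CONST, t)
        assert np.max(np.abs(traj.w_at(t) - cf) / cf) < 1e-6
        assert traj.w_at(3.0) == pytest.approx(1.35, rel=1e-9)

    def test_asymptotic_bounds_bracket_solution(self):
        t = np.linspace(0.0, 20.0, 500)
        lo, hi = asymptotic_bounds(CONST, t)
        cf = closed_form_constant_p(CONST, t)
        assert np.all(lo <= cf * (1 + 1e-12))
        assert np.all(cf <= hi * (1 + 1e-12))
        lo0, hi0 = asymptotic_bounds(CONST, 0.0)
        assert lo0 <= CONST.w0 <= hi0
        assert np.all(hi / lo <= CONST.p0 + 1e-12)

    def test_stasis_at_unit_efficiency(self):
        gp = CONST.with_(p0=1.0)
        traj = simulate_unperturbed(gp, 10.0, pps=100)
        assert np.allclose(traj.w, gp.w0, rtol=1e-12)

    def test_doubling_property(self):
        """With p0 = 2 the size ratio over one lifespan tends to 2."""
        traj = simulate_unperturbed(CONST, 21.0, pps=100)
        for t in np.linspace(10.0, 20.0, 11):
            ratio = traj.w_at(t + 1.0) / traj.w_at(t)
            assert ratio == pytest.approx(2.0, rel=1e-2)


class TestFullModel:
    def test_biphasic_and_slope(self, fig_growth):
        traj = simulate_unperturbed(fig_growth, 40.0, pps=200)
        assert np.all(np.diff(traj.w) > 0)
        # early phase: exponential at rate ln(p0)/T
        t1 = np.linspace(1.0, 6.0, 30)
        rate = np.polyfit(t1, np.log(traj.w_at(t1)), 1)[0]
        assert rate == pytest.approx(math.log(2.0), rel=0.01)
        # late phase: linear with slope (p0-1) w_th / T
        t2 = np.linspace(30.0, 40.0, 60)
        slope = np.polyfit(t2, traj.w_at(t2), 1)[0]
        assert slope == pytest.approx(linear_phase_slope(fig_growth), rel=0.05)

    def test_slope_formula_proportionalities(self, fig_growth):
        s = linear_phase_slope(fig_growth)
        assert linear_phase_slope(fig_growth.with_(w_th=20.0)) == pytest.approx(
            2.0 * s)
        assert linear_phase_slope(fig_growth.with_(T=2.0)) == pytest.approx(
            s / 2.0)
        with pytest.raises(ValueError):
            linear_phase_slope(CONST)

    def test_slope_invariant_to_kin0_and_w0(self, fig_growth):
        def late_slope(gp):
            traj = simulate_unperturbed(gp, 40.0, pps=100)
            t = np.linspace(30.0, 40.0, 60)
            return np.polyfit(t, traj.w_at(t), 1)[0]

        s = late_slope(fig_growth)
        assert abs(late_slope(fig_growth.with_(k_in0=0.5)) - s) / s < 0.02
        assert abs(late_slope(fig_growth.with_(w0=1.0)) - s) / s < 0.02

    def test_method_of_steps_vs_brute_force(self):
        """Cross-validation against the independent Heun oracle with step
        T/2000 for random parameter draws."""
        rng = np.random.default_rng(42)
        for _ in range(10):
            gp = GrowthParameters(
                T=float(rng.uniform(0.5, 2.0)),
                k_in0=float(rng.uniform(0.01, 0.2)),
                w0=float(rng.uniform(0.05, 2.0)),
                p0=float(rng.uniform(1.2, 2.0)),
                w_th=float(rng.uniform(2.0, 20.0)),
                mode="full")
            t_last = 20.0 * gp.T
            traj = simulate_unperturbed(gp, t_last, pps=200)
            bt, bw = brute_force_unperturbed(gp, t_last, n_per_T=2000)
            sel = slice(0, len(bt), 100)
            ours = traj.w_at(bt[sel])
            assert np.max(np.abs(ours - bw[sel]) / bw[sel]) < 1e-5

    def test_production_rate_recursion_vs_product_form(self, fig_growth):
        """Memoized recursion k_in(t) = p(w) k_in(t-T) equals the expanded
        product over INT(t/T)+1 efficiency factors."""
        traj = simulate_unperturbed(fig_growth, 12.0, pps=200)
        for t in (0.4, 1.7, 5.3, 9.9, 11.5):
            rec = traj.k_in.left(t)
            prod = production_rate_product(traj, fig_growth, t)
            assert rec == pytest.approx(prod, rel=1e-4)

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            GrowthParameters(T=0.0, k_in0=0.05, w0=1.0, p0=2.0, w_th=10.0)
        with pytest.raises(ValueError):
            GrowthParameters(T=1.0, k_in0=0.05, w0=1.0, p0=2.5, w_th=10.0)
        with pytest.raises(ValueError):
            GrowthParameters(T=1.0, k_in0=0.05, w0=1.0, mode="linear_phase")
        with pytest.raises(ValueError):
            simulate_unperturbed(CONST, -1.0)
        with pytest.raises(ValueError):
            closed_form_constant_p(CONST, -0.5)
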