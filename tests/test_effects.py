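"""Perturbed tumor models: drug-effect functions, survival fraction,
apoptotic-pool bookkeeping, drug-free reduction, treatment ordering and
delay signatures."""

import math

import numpy as np
import pytest

from lstgi import (DoseRegimen, DrugEffectSpec, GrowthParameters, PKModelSpec,
                   apoptotic_pool, drug_effect, simulate_concentration,
                   simulate_cycle_specific, simulate_non_cycle_specific,
                   simulate_unperturbed, survival_fraction)


class TestDrugEffect:
    def test_zero_concentration(self, fig_drug_linear, fig_drug_emax):
        assert drug_effect(0.0, fig_drug_linear) == 0.0
        assert drug_effect(0.0, fig_drug_emax) == 0.0

    def test_emax_half_maximum_at_ec50(self):
        spec = DrugEffectSpec(mechanism="cycle_specific", effect_form="emax",
                              T_A=1.0, Emax=0.8, EC50=100.0)
        assert drug_effect(100.0, spec) == pytest.approx(0.4)

    def test_linear_potency_product(self):
        spec = DrugEffectSpec(mechanism="non_cycle_specific",
                              effect_form="linear", T_A=5.56, k2=2.30e-3)
        assert drug_effect(1000.0, spec) == pytest.approx(2.30)

    def test_monotone_in_concentration(self, fig_drug_emax):
        c = np.linspace(0.0, 10.0, 100)
        e = drug_effect(c, fig_drug_emax)
        assert np.all(np.diff(e) >= 0)
        with pytest.raises(ValueError):
            drug_effect(-1.0, fig_drug_emax)

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            DrugEffectSpec(mechanism="cycle_specific", effect_form="linear",
                           T_A=1.0, k2=0.1)
        with pytest.raises(ValueError):
            DrugEffectSpec(mechanism="non_cycle_specific", effect_form="emax",
                           T_A=1.0, Emax=1.5, EC50=1.0)
        with pytest.raises(ValueError):
            DrugEffectSpec(mechanism="non_cycle_specific",
                           effect_form="linear", T_A=-1.0, k2=0.1)


class TestSurvivalFraction:
    def test_no_drug_gives_unity(self, fig_pk, fig_drug_linear):
        profile = simulate_concentration(fig_pk, DoseRegimen(()), 20.0)
        for t in (0.0, 5.0, 19.0):
            assert survival_fraction(profile, t, 1.0, fig_drug_linear) == 1.0

    def test_constant_concentration_analytic(self):
        """Constant C = 1 with k2 = 1.5 over one 1-day lifespan:
        exp(-1.5) ~ 0.2231."""
        spec = PKModelSpec(n_compartments=1, kel=1e-9, V=1000.0)
        # near-zero elimination keeps C essentially constant at 1 ng/mL
        profile = simulate_concentration(
            spec, DoseRegimen(((0.0, 1.0, "iv"),)), 10.0)
        drug = DrugEffectSpec(mechanism="non_cycle_specific",
                              effect_form="linear", T_A=4.0, k2=1.5)
        s = survival_fraction(profile, 5.0, 1.0, drug)
        assert s == pytest.approx(math.exp(-1.5), rel=1e-6)

    def test_zero_potency(self, fig_profile):
        drug = DrugEffectSpec(mechanism="non_cycle_specific",
                              effect_form="linear", T_A=4.0, k2=0.0)
        assert survival_fraction(fig_profile, 12.0, 1.0, drug) == 1.0

    def test_rejects_cycle_specific(self, fig_profile, fig_drug_emax):
        with pytest.raises(ValueError):
            survival_fraction(fig_profile, 12.0, 1.0, fig_drug_emax)


class TestDrugFreeReduction:
    def test_both_simulators_reduce_to_unperturbed(self, fig_growth, fig_pk,
                                                   fig_drug_linear,
                                                   fig_drug_emax):
        empty = simulate_concentration(fig_pk, DoseRegimen(()), 30.0)
        ctrl = simulate_unperturbed(fig_growth, 30.0, pps=100)
        t = np.linspace(0.0, 30.0, 200)
        wc = ctrl.w_at(t)
        ncs = simulate_non_cycle_specific(fig_growth, fig_drug_linear, empty,
                                          30.0, pps=100)
        cs = simulate_cycle_specific(fig_growth, fig_drug_emax.with_(Emax=0.0),
                                     fig_profile_dummy(fig_pk), 30.0, pps=100)
        assert np.max(np.abs(ncs.w_at(t) - wc) / wc) < 1e-6
        assert np.max(np.abs(cs.w_at(t) - wc) / wc) < 1e-6
        assert np.all(ncs.A == 0.0)

    def test_vanishing_potency_limits(self, fig_growth, fig_pk, fig_regimen):
        """EC50 -> infinity and k2 = 0 reproduce the control trajectory even
        with dosing present."""
        profile = simulate_concentration(fig_pk, fig_regimen, 35.0)
        ctrl = simulate_unperturbed(fig_growth, 35.0, pps=100)
        t = np.linspace(0.0, 35.0, 150)
        wc = ctrl.w_at(t)
        cs = simulate_cycle_specific(
            fig_growth, DrugEffectSpec(mechanism="cycle_specific",
                                       effect_form="emax", T_A=4.0, Emax=1.0,
                                       EC50=1e12),
            profile, 35.0, pps=100)
        ncs = simulate_non_cycle_specific(
            fig_growth, DrugEffectSpec(mechanism="non_cycle_specific",
                                       effect_form="linear", T_A=4.0, k2=0.0),
            profile, 35.0, pps=100)
        assert np.max(np.abs(cs.w_at(t) - wc) / wc) < 1e-6
        assert np.max(np.abs(ncs.w_at(t) - wc) / wc) < 1e-6


def fig_profile_dummy(fig_pk):
    return simulate_concentration(fig_pk, DoseRegimen(()), 30.0)


class TestPerturbedDynamics:
    def test_apoptotic_pool_empty_before_first_dose(self, fig_growth,
                                                    fig_profile,
                                                    fig_drug_linear):
        traj = simulate_non_cycle_specific(fig_growth, fig_drug_linear,
                                           fig_profile, 45.0, pps=50)
        assert np.all(traj.A[traj.times < 10.0] == 0.0)
        assert np.all(traj.M >= 0.0)
        assert np.allclose(traj.w, traj.M + traj.A)

    def test_treated_below_control_pointwise(self, fig_growth, fig_profile,
                                             fig_drug_linear):
        ctrl = simulate_unperturbed(fig_growth, 45.0, pps=50)
        traj = simulate_non_cycle_specific(fig_growth, fig_drug_linear,
                                           fig_profile, 45.0, pps=50)
        t = np.linspace(0.0, 45.0, 400)
        assert np.all(traj.w_at(t) <= ctrl.w_at(t) + 1e-9)

    def test_monotone_potency(self, fig_growth, fig_profile):
        """Larger k2 gives pointwise smaller tumors after the first dose."""
        t = np.linspace(10.0, 45.0, 200)
        prev = None
        for k2 in (0.5, 1.5, 3.0):
            drug = DrugEffectSpec(mechanism="non_cycle_specific",
                                  effect_form="linear", T_A=4.0, k2=k2)
            w = simulate_non_cycle_specific(fig_growth, drug, fig_profile,
                                            45.0, pps=50).w_at(t)
            if prev is not None:
                assert np.all(w <= prev + 1e-9)
            prev = w

    def test_delay_shift_equals_ta_change(self, fig_growth, fig_profile,
                                          fig_drug_linear):
        """Increasing T_A leaves pre-dose growth unchanged and shifts the
        onset of decline by exactly the same amount (within 0.1 day)."""
        onsets = {}
        pre = {}
        for ta in (2.0, 4.0, 6.0):
            traj = simulate_non_cycle_specific(
                fig_growth, fig_drug_linear.with_(T_A=ta), fig_profile, 45.0,
                pps=50)
            ts = np.arange(10.0, 25.0, 0.02)
            w = traj.w_at(ts)
            onsets[ta] = ts[np.where(np.diff(w) < 0)[0][0]]
            pre[ta] = traj.w_at(9.5)
        assert onsets[4.0] - onsets[2.0] == pytest.approx(2.0, abs=0.1)
        assert onsets[6.0] - onsets[4.0] == pytest.approx(2.0, abs=0.1)
        vals = list(pre.values())
        assert max(vals) - min(vals) < 1e-9 * vals[0]

    def test_mass_bookkeeping_against_quadrature(self, fig_growth):
        """A(t) equals the recorded removal inflow integrated over
        (t - T_A, t), to 1e-4 relative (gentle PK so the trapezoid oracle
        resolves the inflow)."""
        pk = PKModelSpec(n_compartments=2, kel=2.0, k12=0.2, k21=2.0, V=1000.0)
        regimen = DoseRegimen(((10.0, 10.0, "iv"), (20.0, 10.0, "iv")))
        profile = simulate_concentration(pk, regimen, 35.0)
        drug = DrugEffectSpec(mechanism="non_cycle_specific",
                              effect_form="linear", T_A=4.0, k2=0.3)
        traj = simulate_non_cycle_specific(fig_growth, drug, profile, 35.0,
                                           pps=100)
        A_oracle = apoptotic_pool(traj.removal, 4.0, traj.times)
        assert np.max(np.abs(A_oracle - traj.A)) < 1e-4 * traj.A.max()

    def test_conservation_of_removed_mass(self, fig_growth):
        """Cumulative removal from M equals the apoptotic inflow, and at the
        horizon splits exactly into the standing pool plus its outflow."""
        # extravascular dosing keeps C(t) continuous, so plain trapezoid
        # quadrature of E(C) * M is an adequate independent oracle
        pk = PKModelSpec(n_compartments=2, kel=2.0, ka=8.0, k12=0.2, k21=2.0,
                         V=1000.0)
        profile = simulate_concentration(
            pk, DoseRegimen(((10.0, 10.0, "ip"),)), 30.0)
        drug = DrugEffectSpec(mechanism="non_cycle_specific",
                              effect_form="linear", T_A=4.0, k2=0.3)
        traj = simulate_non_cycle_specific(fig_growth, drug, profile, 30.0,
                                           pps=100)
        # independent quadrature of E(C) * M over the horizon
        ts = np.linspace(0.0, 30.0, 30001)
        em = drug_effect(profile.conc(ts), drug) * traj.M_at(ts)
        total_removed = np.trapezoid(em, ts)
        # pool content + what already left the pool
        outflow = apoptotic_pool(traj.removal, 4.0, traj.times)
        pool_final = traj.A[-1]
        inflow_total = np.trapezoid(
            [traj.removal.left(t) for t in ts], ts)
        assert inflow_total == pytest.approx(total_removed, rel=1e-4)
        left_pool = inflow_total - pool_final
        assert left_pool >= -1e-9
        # A(horizon) consistent with the windowed integral
        assert outflow[-1] == pytest.approx(pool_final, rel=1e-4)

    def test_negative_state_raises_not_clips(self, fig_growth, fig_profile):
        """An absurd potency drives M toward 0 fast; the solver must report
        failure rather than silently clipping states."""
        drug = DrugEffectSpec(mechanism="non_cycle_specific",
                              effect_form="linear", T_A=4.0, k2=1e4)
        with pytest.raises(RuntimeError):
            simulate_non_cycle_specific(fig_growth, drug, fig_profile, 45.0,
                                        pps=20)


class TestApoptoticPool:
    def test_zero_inflow(self):
        t = np.linspace(0.0, 10.0, 101)
        assert np.all(apoptotic_pool(lambda s: 0.0, 3.0, t) == 0.0)

    def test_constant_inflow_ramp_and_plateau(self):
        """Constant rate r from t = 0: A(t) = r * min(t, T_A)."""
        t = np.linspace(0.0, 12.0, 241)
        A = apoptotic_pool(lambda s: 2.0, 3.0, t)
        assert np.allclose(A, 2.0 * np.minimum(t, 3.0), atol=1e-10)

    def test_piecewise_linear_pulse_held_for_exactly_ta(self):
        """A triangular pulse of known mass is held in the pool for exactly
        T_A and then released completely."""
        edges = np.array([0.0, 0.05, 0.1])
        grid = np.unique(np.concatenate([np.linspace(0.0, 8.0, 1601), edges,
                                         edges + 5.0]))
        vals = np.interp(grid, edges, [0.0, 2.0, 0.0], left=0.0, right=0.0)
        A = apoptotic_pool(vals, 5.0, grid)
        mass = 0.5 * 0.1 * 2.0
        plateau = (grid > 0.2) & (grid < 4.9)
        assert np.allclose(A[plateau], mass, rtol=1e-10)
        assert np.all(A[grid > 5.2] == 0.0)

    def test_validation(self):
        with pytest.raises(ValueError):
            apoptotic_pool(lambda s: 1.0, -1.0, np.linspace(0, 1, 10))
        with pytest.raises(ValueError):
            apoptotic_pool(lambda s: -1.0, 1.0, np.linspace(0, 1, 10))
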