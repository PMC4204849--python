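"""Shared fixtures: the sensitivity-analysis simulation constants and small
helpers used across the suite.  Everything is generated in-process."""

import numpy as np
import pytest

from lstgi import (DoseRegimen, DrugEffectSpec, GrowthParameters, PKModelSpec,
                   simulate_concentration)


@pytest.fixture(scope="session")
def fig_growth():
    """Growth constants of the sensitivity analyses: T = 1 d, p0 = 2,
    k_in0 = 0.05 g/day, w_th = 10 g."""
    return GrowthParameters(T=1.0, k_in0=0.05, w0=0.05, p0=2.0, w_th=10.0,
                            mode="full")


@pytest.fixture(scope="session")
def fig_pk():
    """Two-compartment PK driver of the sensitivity analyses (rates 1/day).

    The published fixture uses dimensionless 10-unit doses with V = 1 mL so
    that peak concentration is 10 units/mL; V = 1000 absorbs this package's
    (mg/kg)/(L/kg) -> ng/mL scaling so the peaks match exactly.
    """
    return PKModelSpec(n_compartments=2, kel=20.0, k12=0.2, k21=2.0, V=1000.0)


@pytest.fixture(scope="session")
def fig_regimen():
    return DoseRegimen(((10.0, 10.0, "iv"), (20.0, 10.0, "iv"),
                        (30.0, 10.0, "iv")))


@pytest.fixture(scope="session")
def fig_profile(fig_pk, fig_regimen):
    return simulate_concentration(fig_pk, fig_regimen, 45.0)


@pytest.fixture(scope="session")
def fig_drug_linear():
    """Non-cycle-specific linear-kill spec of the sensitivity analysis:
    T_A = 4 d, k2 = 1.5 mL/ng/day."""
    return DrugEffectSpec(mechanism="non_cycle_specific", effect_form="linear",
                          T_A=4.0, k2=1.5)


@pytest.fixture(scope="session")
def fig_drug_emax():
    """Cycle-specific Emax-kill spec: T_A = 4 d, Emax = 1, EC50 = 0.01."""
    return DrugEffectSpec(mechanism="cycle_specific", effect_form="emax",
                          T_A=4.0, Emax=1.0, EC50=0.01)


def brute_force_unperturbed(params, t_last, n_per_T=2000, form=None):
    """Independent fixed-step oracle for the growth DDE.

    Heun (trapezoid) steps on a uniform grid with h = T / n_per_T; the
    production rate is memoized on the same grid so all lag lookups are
    exact index shifts.  Completely independent of the method-of-steps
    machinery under test.
    """
    from lstgi.growth import efficiency

    h = params.T / n_per_T
    n_steps = int(np.ceil(t_last / h))
    # left/right limits of the production rate at each node: they differ
    # only at multiples of T, where the lag count jumps
    kin_l = np.empty(n_steps + 1)
    kin_r = np.empty(n_steps + 1)
    w = np.empty(n_steps + 1)
    w[0] = params.w0
    k0 = params.k_in0

    def lag_left(i):
        j = i - n_per_T
        return k0 if j <= 0 else kin_l[j]

    def lag_right(i):
        j = i - n_per_T
        return k0 if j < 0 else kin_r[j]

    def p_of(wv):
        return float(efficiency(wv, params, form))

    kin_l[0] = k0
    kin_r[0] = p_of(w[0]) * lag_right(0)
    for i in range(n_steps):
        f_i = kin_r[i] - lag_right(i)
        w_pred = w[i] + h * f_i
        lag_n = lag_left(i + 1)
        f_pred = p_of(w_pred) * lag_n - lag_n
        w[i + 1] = w[i] + 0.5 * h * (f_i + f_pred)
        kin_l[i + 1] = p_of(w[i + 1]) * lag_n
        kin_r[i + 1] = p_of(w[i + 1]) * lag_right(i + 1)
    times = h * np.arange(n_steps + 1)
    return times, w
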