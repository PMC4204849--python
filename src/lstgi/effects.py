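"""Perturbed lifespan tumor-growth models: drug effects on dividing cells.

The tumor is split into a proliferating mass M(t) and an apoptotic mass
A(t); total size w = M + A.  Drug-damaged cells are not removed instantly:
they enter the apoptotic pool and leave it after the apoptosis lifespan
T_A, which produces the characteristic delay between dosing and observable
tumor shrinkage.

Non-cycle-specific action (kill at any cell-cycle stage):

    dM/dt = (p(w) - 1) * k_in(t-T) * S(t) - E(C(t)) * M(t)
    k_in(t) = p(w(t)) * k_in(t-T) * S(t)
    S(t)   = exp(-integral_{max(t-T,0)}^{t} E(C(s)) ds)   (surviving fraction)
    dA/dt  = E(C(t)) * M(t) - E(C(t-T_A)) * M(t-T_A)

with E(C) = k2 * C (linear) or Emax * C / (EC50 + C) (saturable).  Only
cells that survive drug exposure over their whole lifespan divide.

Cycle-specific action (kill only at the moment of division): a fraction
E(C(t)) of the cells completing their lifespan at t is shunted to the
apoptotic pool instead of dividing,

    k_in(t) = p(w(t)) * (1 - E(C(t))) * k_in(t-T)
    dM/dt   = k_in(t) - k_in(t-T)
    dA/dt   = E(C(t)) * k_in(t-T) - [same term lagged by T_A].

Here E must be a bounded fraction, so only the Emax form is admitted.
Because the drug can only act on the subpopulation at the division instant,
fitted EC50 values are compensatorily low relative to plasma levels, and
dose escalation saturates quickly.

Division efficiency p is evaluated at the total burden w = M + A in both
models (the apoptotic mass still competes for resources); evaluating p at
M only is available as a switch for sensitivity checks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from ._dde import HermiteDense, JumpSignal, build_mesh
from .growth import GrowthParameters, _make_p
from .pk import ConcentrationProfile

__all__ = [
    "DrugEffectSpec",
    "PerturbedTrajectory",
    "drug_effect",
    "survival_fraction",
    "simulate_non_cycle_specific",
    "simulate_cycle_specific",
    "apoptotic_pool",
]

_MECHANISMS = ("non_cycle_specific", "cycle_specific")
_EFFECT_FORMS = ("linear", "emax")


@dataclass(frozen=True)
class DrugEffectSpec:
    """Drug mechanism and potency.

    k2    second-order potency (mL/ng/day), linear form
    Emax  maximum effect (dimensionless fraction in [0, 1]), emax form
    EC50  concentration of half-maximal effect (ng/mL), emax form
    T_A   apoptosis lifespan (day): time drug-damaged cells remain part of
          the measured tumor mass before disappearing
    """

    mechanism: str
    effect_form: str
    T_A: float
    k2: float | None = None
    Emax: float | None = None
    EC50: float | None = None

    def __post_init__(self):
        if self.mechanism not in _MECHANISMS:
            raise ValueError(f"mechanism must be one of {_MECHANISMS}")
        if self.effect_form not in _EFFECT_FORMS:
            raise ValueError(f"effect_form must be one of {_EFFECT_FORMS}")
        if self.T_A <= 0:
            raise ValueError("apoptosis lifespan T_A must be positive")
        if self.effect_form == "linear":
            if self.mechanism == "cycle_specific":
                raise ValueError(
                    "cycle-specific effect must be a bounded fraction: "
                    "use the emax form")
            if self.k2 is None or self.k2 < 0:
                raise ValueError("linear form requires k2 >= 0")
        else:
            if self.Emax is None or not 0.0 <= self.Emax <= 1.0:
                raise ValueError("Emax must lie in [0, 1]")
            if self.EC50 is None or self.EC50 <= 0:
                raise ValueError("EC50 must be positive")

    def with_(self, **kwargs) -> "DrugEffectSpec":
        return replace(self, **kwargs)


def drug_effect(C, spec: DrugEffectSpec):
    """Effect E(C): k2*C (1/day) for linear, Emax*C/(EC50+C) for emax."""
    C_arr = np.asarray(C, dtype=float)
    if np.any(C_arr < 0):
        raise ValueError("concentration must be non-negative")
    if spec.effect_form == "linear":
        out = spec.k2 * C_arr
    else:
        out = spec.Emax * C_arr / (spec.EC50 + C_arr)
    return float(out) if C_arr.ndim == 0 else out


class _EffectExposure:
    """Running integral of E(C(s)) ds, exact for the linear effect form.

    For the emax form the integral has no closed form; it is precomputed
    once per trajectory on a dense grid (trapezoid with dose-time nodes)
    and interpolated.
    """

    def __init__(self, profile: ConcentrationProfile, spec: DrugEffectSpec,
                 t_last: float, n_grid: int = 20001):
        self._profile = profile
        self._spec = spec
        if spec.effect_form == "linear":
            self._k2 = spec.k2
            self._grid = None
        else:
            ts = np.unique(np.concatenate([
                np.linspace(0.0, t_last, n_grid),
                np.asarray(profile.dose_times, dtype=float),
            ]))
            E = drug_effect(profile.conc(ts), spec)
            cum = np.concatenate([[0.0], np.cumsum(
                0.5 * (E[1:] + E[:-1]) * np.diff(ts))])
            self._grid = (ts, cum)

    def cum(self, t: float) -> float:
        if t <= 0.0:
            return 0.0
        if self._grid is None:
            return self._k2 * self._profile.cumulative(t)
        ts, cum = self._grid
        return float(np.interp(t, ts, cum))

    def window(self, t0: float, t1: float) -> float:
        return self.cum(t1) - self.cum(max(t0, 0.0))


def survival_fraction(profile: ConcentrationProfile, t: float, T: float,
                      spec: DrugEffectSpec) -> float:
    """Fraction of cells produced at t - T that survive drug exposure to t.

    exp(-integral of E(C) over (t-T, t)), with no contribution from times
    before the experiment start (no drug before t = 0).  Defined for the
    non-cycle-specific mechanism only; cycle-specific kill happens at the
    division instant, not over the lifespan.
    """
    if spec.mechanism != "non_cycle_specific":
        raise ValueError("survival fraction applies to the non-cycle-specific "
                         "mechanism only")
    if t < 0:
        raise ValueError("t must be non-negative")
    exposure = _EffectExposure(profile, spec, max(t, profile.t_last))
    return math.exp(-exposure.window(t - T, t))


@dataclass(frozen=True)
class PerturbedTrajectory:
    """Proliferating mass M, apoptotic mass A, and total w = M + A.

    Internally the dense state is (M, I) where I(t) is the cumulative
    inflow into the apoptotic pool; A(t) = I(t) - I(t - T_A) follows the
    lifespan bookkeeping exactly and is non-negative by construction
    because I is non-decreasing.
    """

    times: np.ndarray
    M: np.ndarray
    A: np.ndarray
    T_A: float
    dense: HermiteDense  # components (M, I)
    k_in: JumpSignal
    removal: JumpSignal  # inflow rate into the apoptotic pool

    @property
    def w(self) -> np.ndarray:
        return self.M + self.A

    def M_at(self, t):
        if np.ndim(t) > 0:
            return np.array([self.dense(float(ti))[0]
                             for ti in np.asarray(t).ravel()])
        return self.dense(float(t))[0]

    def A_at(self, t):
        if np.ndim(t) > 0:
            return np.array([self.A_at(float(ti))
                             for ti in np.asarray(t).ravel()])
        t = float(t)
        cum_now = self.dense(t)[1]
        cum_lag = self.dense(t - self.T_A)[1] if t - self.T_A > 0 else 0.0
        return max(cum_now - cum_lag, 0.0)

    def w_at(self, t):
        if np.ndim(t) > 0:
            return np.array([self.w_at(float(ti))
                             for ti in np.asarray(t).ravel()])
        return self.M_at(t) + self.A_at(t)


def _simulate_perturbed(growth: GrowthParameters, spec: DrugEffectSpec,
                        profile: ConcentrationProfile, t_last: float,
                        form: str | None, pps: int,
                        efficiency_of_total: bool) -> PerturbedTrajectory:
    if t_last <= 0:
        raise ValueError("t_last must be positive")
    if profile.t_last < t_last - 1e-9:
        raise ValueError("concentration profile does not cover the horizon")
    form = form or growth.default_form
    cycle = spec.mechanism == "cycle_specific"
    T, T_A = growth.T, spec.T_A
    mesh = build_mesh(t_last, (T, T_A), event_times=profile.dose_times, pps=pps)
    p_of = _make_p(growth, form)
    exposure = None if cycle else _EffectExposure(profile, spec, t_last)
    kin = JumpSignal(growth.k_in0)
    inflow = JumpSignal(0.0)
    dense = HermiteDense()
    exp_ = math.exp

    if spec.effect_form == "linear":
        k2 = spec.k2

        def eff(c: float) -> float:
            return k2 * c
    else:
        emax, ec50 = spec.Emax, spec.EC50

        def eff(c: float) -> float:
            return emax * c / (ec50 + c)

    # State is (M, I) with I the cumulative apoptotic inflow; the pool mass
    # A(t) = I(t) - I(t - T_A) is recovered from the stored I history, so A
    # cannot drift negative (I is non-decreasing under non-negative inflow).
    cum_in = JumpSignal(0.0)

    def pool(t: float, I: float, side: str) -> float:
        lag_t = t - T_A
        if lag_t <= 0.0:
            return I
        cum_lag = cum_in.left(lag_t) if side == "left" else cum_in.right(lag_t)
        return max(I - cum_lag, 0.0)

    def rhs(t: float, M: float, I: float, side: str):
        if side == "left":
            lag = kin.left(t - T)
            c = profile.conc_left(t)
        else:
            lag = kin.right(t - T)
            c = profile.conc(t)
        E = eff(c)
        A = pool(t, I, side)
        p = p_of(M + A) if efficiency_of_total else p_of(M)
        if cycle:
            kin_t = p * (1.0 - E) * lag
            in_A = E * lag
            dM = kin_t - lag
        else:
            surv = exp_(-exposure.window(t - T, t))
            kin_t = p * lag * surv
            in_A = E * M
            dM = kin_t - lag * surv - in_A
        return dM, in_A, kin_t

    M, I = growth.w0, 0.0
    Ms, As = [M], [0.0]
    dM_r, in_r, kin_r = rhs(0.0, M, I, "right")
    kin.append(0.0, kin_r)
    inflow.append(0.0, in_r)
    cum_in.append(0.0, 0.0)
    for t0, t1 in zip(mesh[:-1], mesh[1:]):
        h = t1 - t0
        tm = t0 + 0.5 * h
        k1M, k1I = dM_r, in_r
        k2M, k2I, _ = rhs(tm, M + 0.5 * h * k1M, I + 0.5 * h * k1I, "right")
        k3M, k3I, kin_m = rhs(tm, M + 0.5 * h * k2M, I + 0.5 * h * k2I,
                              "right")
        kin.append(tm, kin_m)
        inflow.append(tm, k3I)
        cum_in.append(tm, I + 0.5 * h * k2I)
        k4M, k4I, _ = rhs(t1, M + h * k3M, I + h * k3I, "left")
        M1 = M + h / 6.0 * (k1M + 2.0 * k2M + 2.0 * k3M + k4M)
        I1 = I + h / 6.0 * (k1I + 2.0 * k2I + 2.0 * k3I + k4I)
        if not (math.isfinite(M1) and math.isfinite(I1)):
            raise RuntimeError(f"perturbed integration failed on [{t0}, {t1}]")
        if M1 < 0 or I1 < I - 1e-12 * max(I, 1.0):
            raise RuntimeError(
                f"negative state on [{t0}, {t1}]: M={M1}, dI={I1 - I}")
        dM_l, in_l, kin_l = rhs(t1, M1, I1, "left")
        kin.append(t1, kin_l)
        inflow.append(t1, in_l)
        cum_in.append(t1, I1)
        dM_r, in_r, kin_r = rhs(t1, M1, I1, "right")
        kin.append(t1, kin_r)
        inflow.append(t1, in_r)
        dense.add_step(t0, t1, (M, I), (M1, I1), (k1M, k1I), (dM_l, in_l))
        M, I = M1, I1
        Ms.append(M)
        As.append(pool(t1, I, "left"))
    return PerturbedTrajectory(np.asarray(mesh), np.asarray(Ms), np.asarray(As),
                               T_A, dense, kin, inflow)


def simulate_non_cycle_specific(growth: GrowthParameters, spec: DrugEffectSpec,
                                profile: ConcentrationProfile, t_last: float,
                                form: str | None = None, pps: int = 200,
                                efficiency_of_total: bool = True,
                                ) -> PerturbedTrajectory:
    """Tumor growth under a drug that kills at any cell-cycle stage."""
    if spec.mechanism != "non_cycle_specific":
        raise ValueError("spec.mechanism must be 'non_cycle_specific'")
    return _simulate_perturbed(growth, spec, profile, t_last, form, pps,
                               efficiency_of_total)


def simulate_cycle_specific(growth: GrowthParameters, spec: DrugEffectSpec,
                            profile: ConcentrationProfile, t_last: float,
                            form: str | None = None, pps: int = 200,
                            efficiency_of_total: bool = True,
                            ) -> PerturbedTrajectory:
    """Tumor growth under a drug that kills only at the division instant."""
    if spec.mechanism != "cycle_specific":
        raise ValueError("spec.mechanism must be 'cycle_specific'")
    return _simulate_perturbed(growth, spec, profile, t_last, form, pps,
                               efficiency_of_total)


def apoptotic_pool(removal_rate_signal, T_A: float, t_grid,
                   refine: int = 8) -> np.ndarray:
    """Apoptotic mass from its inflow: A(t) = integral of inflow over (t-T_A, t).

    ``removal_rate_signal`` is either a callable of time or an array aligned
    with ``t_grid``; inflow is assumed zero before t_grid[0] (no drug before
    the experiment).  Equivalent to dA/dt = inflow(t) - inflow(t - T_A) with
    A(0) = 0.
    """
    if T_A <= 0:
        raise ValueError("T_A must be positive")
    t_grid = np.asarray(t_grid, dtype=float)
    if isinstance(removal_rate_signal, JumpSignal):
        # integrate the recorded polyline itself: duplicated abscissae make
        # the trapezoid rule exact across inflow jumps at dose times
        fine = np.asarray(removal_rate_signal.ts)
        vals = np.asarray(removal_rate_signal.vs)
    elif callable(removal_rate_signal):
        fine = np.unique(np.concatenate(
            [np.linspace(t_grid[0], t_grid[-1],
                         refine * max(len(t_grid) - 1, 1) + 1), t_grid]))
        vals = np.array([removal_rate_signal(float(t)) for t in fine])
    else:
        fine = t_grid
        vals = np.asarray(removal_rate_signal, dtype=float)
        if vals.shape != t_grid.shape:
            raise ValueError("signal array must align with t_grid")
    if np.any(vals < 0):
        raise ValueError("removal rate must be non-negative")
    cum = np.concatenate([[0.0], np.cumsum(
        0.5 * (vals[1:] + vals[:-1]) * np.diff(fine))])
    cum_at = lambda t: np.interp(t, fine, cum)
    return np.asarray(cum_at(t_grid) - cum_at(np.maximum(t_grid - T_A, fine[0])))
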