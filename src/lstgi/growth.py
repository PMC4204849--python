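"""Unperturbed lifespan model of tumor growth.

Tumor size w(t) changes as the balance of a production rate k_in(t) and an
elimination rate k_out(t) = k_in(t - T): every cell produced at t - T reaches
the end of its lifespan T at time t and divides, contributing p daughter
cells per dividing cell, so k_in(t) = p(w(t)) * k_in(t - T).  The division
efficiency p lies between 1 (stasis) and 2 (full division) and decreases
with tumor burden,

    p(w) = 1 + (p0 - 1) * (1 + (w / w_th)**psi)**(-1/psi),

which switches (sharply for large psi) from p0 below the threshold size w_th
to 1 + (p0 - 1) * w_th / w above it.  The resulting delay differential
equation

    dw/dt = (p(w(t)) - 1) * k_in(t - T),    w(0) = w0,
    k_in(t) = k_in0 for -T < t <= 0,

produces exponential growth at rate log(p0)/T while w << w_th and linear
growth of slope (p0 - 1) * w_th / T once w >> w_th, matching the biphasic
shape of xenograft volume data.  It is solved by the method of steps:
k_in is discontinuous at every multiple of T (the jumps propagate from the
constant-history junction at t = 0), so integration restarts there.

Mass/volume units are opaque: the model runs in whatever unit the
observations use (g or mm^3); no density conversion is applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from ._dde import HermiteDense, JumpSignal, build_mesh

__all__ = [
    "GrowthParameters",
    "Trajectory",
    "efficiency",
    "simulate_unperturbed",
    "closed_form_constant_p",
    "asymptotic_bounds",
    "linear_phase_slope",
    "production_rate_product",
]

_FORMS = ("threshold_power", "switch_limit", "linear_phase", "constant")
_MODES = ("full", "linear_phase", "constant_p")

#: w_th sentinel factor for exponential-only growth: the threshold is placed
#: far beyond any observable size so the efficiency never leaves its plateau.
EXPONENTIAL_ONLY_WTH = 1e9


@dataclass(frozen=True)
class GrowthParameters:
    """Constants of the unperturbed model.

    T        cell lifespan / doubling time (day)
    k_in0    pre-experiment production rate (mass/day), the constant history
    p0       division efficiency below threshold, constrained to [1, 2]
    w_th     threshold size at which growth turns from exponential to linear
    psi      sharpness of the efficiency switch (dimensionless, default 20)
    p_wth    identifiable product (p0 - 1) * w_th, used in linear_phase mode
             where p0 and w_th are not separately identifiable
    w0       tumor size at t = 0
    """

    T: float
    k_in0: float
    w0: float
    p0: float | None = None
    w_th: float | None = None
    psi: float = 20.0
    p_wth: float | None = None
    mode: str = "full"

    def __post_init__(self):
        if self.mode not in _MODES:
            raise ValueError(f"mode must be one of {_MODES}, got {self.mode!r}")
        for name in ("T", "k_in0", "w0"):
            v = getattr(self, name)
            if v is None or not math.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v}")
        if self.T <= 0:
            raise ValueError("lifespan T must be positive")
        if self.k_in0 < 0:
            raise ValueError("k_in0 must be non-negative")
        if self.w0 <= 0:
            raise ValueError("w0 must be positive")
        if self.mode == "linear_phase":
            if self.p_wth is None or self.p_wth <= 0:
                raise ValueError("linear_phase mode requires p_wth > 0")
        else:
            if self.p0 is None or not 1.0 <= self.p0 <= 2.0:
                raise ValueError("division efficiency p0 must lie in [1, 2]")
            if self.mode == "full":
                if self.w_th is None or self.w_th <= 0:
                    raise ValueError("full mode requires w_th > 0")
                if self.psi <= 0:
                    raise ValueError("psi must be positive")

    def with_(self, **kwargs) -> "GrowthParameters":
        return replace(self, **kwargs)

    @property
    def default_form(self) -> str:
        return {"full": "threshold_power", "linear_phase": "linear_phase",
                "constant_p": "constant"}[self.mode]


def efficiency(w, params: GrowthParameters, form: str | None = None):
    """Division efficiency p(w); accepts scalars or arrays, w >= 0."""
    form = form or params.default_form
    if form not in _FORMS:
        raise ValueError(f"unknown efficiency form {form!r}")
    w_arr = np.asarray(w, dtype=float)
    if np.any(w_arr < 0):
        raise ValueError("tumor size w must be non-negative")
    scalar = w_arr.ndim == 0

    if form == "constant":
        out = np.full_like(w_arr, params.p0, dtype=float)
    elif form == "linear_phase":
        p_wth = params.p_wth if params.p_wth is not None else \
            (params.p0 - 1.0) * params.w_th
        if np.any(w_arr == 0):
            raise ValueError("linear_phase efficiency is undefined at w = 0")
        out = 1.0 + p_wth / w_arr
    elif form == "switch_limit":
        out = np.where(
            w_arr <= params.w_th,
            params.p0,
            1.0 + (params.p0 - 1.0) * params.w_th / np.maximum(w_arr, 1e-300),
        )
    else:  # threshold_power
        with np.errstate(divide="ignore"):
            logr = np.log(w_arr / params.w_th)
        # (1 + r**psi)**(-1/psi) computed in the log domain (overflow-safe)
        factor = np.exp(-np.logaddexp(0.0, params.psi * logr) / params.psi)
        out = 1.0 + (params.p0 - 1.0) * factor
    return float(out) if scalar else out


def _make_p(params: GrowthParameters, form: str):
    """Fast scalar p(w) closure for the integrator hot loop."""
    if form == "constant":
        p0 = params.p0
        return lambda w: p0
    if form == "linear_phase":
        p_wth = params.p_wth if params.p_wth is not None else \
            (params.p0 - 1.0) * params.w_th
        return lambda w: 1.0 + p_wth / w
    if form == "switch_limit":
        p0, w_th = params.p0, params.w_th
        return lambda w: p0 if w <= w_th else 1.0 + (p0 - 1.0) * w_th / w
    p0, w_th, psi = params.p0, params.w_th, params.psi
    pm1 = p0 - 1.0
    log, exp = math.log, math.exp

    def p(w: float) -> float:
        if w <= 0.0:
            return p0
        big = psi * log(w / w_th)
        if big > 60.0:
            return 1.0 + pm1 * exp(-big / psi)
        return 1.0 + pm1 * (1.0 + exp(big)) ** (-1.0 / psi)

    return p


@dataclass(frozen=True)
class Trajectory:
    """Solution grid of the growth model with dense off-grid evaluation."""

    times: np.ndarray
    w: np.ndarray
    dense: HermiteDense
    k_in: JumpSignal  # production-rate signal, constant k_in0 on (-T, 0]

    def w_at(self, t):
        if np.ndim(t) > 0:
            return np.array([self.dense(float(ti))[0] for ti in np.asarray(t).ravel()])
        return self.dense(float(t))[0]


def simulate_unperturbed(params: GrowthParameters, t_last: float,
                         form: str | None = None, pps: int = 200) -> Trajectory:
    """Solve the growth DDE by the method of steps.

    The mesh restarts at every multiple of T; the production rate is
    advanced with the state (k_in(t) = p(w(t)) * k_in(t - T), memoized on
    the mesh) so each right-hand-side evaluation costs O(1).  ``pps`` sets
    the number of integration steps per lifespan interval.
    """
    if t_last <= 0:
        raise ValueError("t_last must be positive")
    form = form or params.default_form
    mesh = build_mesh(t_last, (params.T,), pps=pps)
    kin = JumpSignal(params.k_in0)
    dense = HermiteDense()
    T = params.T
    p_of = _make_p(params, form)

    def rhs(t: float, w: float, side: str) -> tuple[float, float]:
        if side == "left":
            lag = kin.left(t - T)
        else:
            lag = kin.right(t - T)
        kin_t = p_of(w) * lag
        return kin_t - lag, kin_t

    w = params.w0
    ws = [w]
    d_right, kin_right = rhs(0.0, w, "right")
    kin.append(0.0, kin_right)  # right limit of k_in at the history junction
    for t0, t1 in zip(mesh[:-1], mesh[1:]):
        h = t1 - t0
        k1 = d_right
        k2, _ = rhs(t0 + 0.5 * h, w + 0.5 * h * k1, "right")
        k3, kin_mid = rhs(t0 + 0.5 * h, w + 0.5 * h * k2, "right")
        kin.append(t0 + 0.5 * h, kin_mid)
        k4, _ = rhs(t1, w + h * k3, "left")
        w1 = w + h / 6.0 * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        if not math.isfinite(w1) or w1 <= 0:
            raise RuntimeError(
                f"growth integration failed on step [{t0}, {t1}]: w = {w1}")
        d_left, kin_left = rhs(t1, w1, "left")
        kin.append(t1, kin_left)
        d_right, kin_right = rhs(t1, w1, "right")
        kin.append(t1, kin_right)
        dense.add_step(t0, t1, (w,), (w1,), (k1,), (d_left,))
        w = w1
        ws.append(w)
    return Trajectory(np.asarray(mesh), np.asarray(ws), dense, kin)


def production_rate_product(traj: Trajectory, params: GrowthParameters, t: float,
                            form: str | None = None) -> float:
    """k_in(t) via the expanded product form (cross-check for the recursion).

    k_in(t) = k_in0 * prod_{j=0}^{n-1} p(w(t - j*T)) with n = ceil(t / T)
    recursion levels, i.e. INT(t/T) stored delays plus the current interval.
    """
    if t <= 0:
        return params.k_in0
    n = math.ceil(t / params.T - 1e-12)
    val = params.k_in0
    for j in range(n):
        val *= efficiency(traj.w_at(t - j * params.T), params, form)
    return val


def closed_form_constant_p(params: GrowthParameters, t):
    """Explicit solution for constant division efficiency p(w) = p0.

    On (nT, (n+1)T] the production rate is k_in0 * p0**(n+1) and the
    elimination rate k_in0 * p0**n, so w is piecewise linear with

        w(t) = w0 + k_in0*T*(p0**n - 1) + k_in0 * p0**n * (p0 - 1) * (t - nT),
        n = INT(t / T).
    """
    if params.mode != "constant_p":
        raise ValueError("closed form applies to constant_p mode only")
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("t must be non-negative")
    n = np.floor(t_arr / params.T + 1e-12)
    s = t_arr - n * params.T
    pn = params.p0 ** n
    w = params.w0 + params.k_in0 * params.T * (pn - 1.0) \
        + params.k_in0 * pn * (params.p0 - 1.0) * s
    return float(w) if t_arr.ndim == 0 else w


def asymptotic_bounds(params: GrowthParameters, t):
    """Envelope of the constant-efficiency solution.

    Because 0 <= t/T - INT(t/T) < 1, the exact solution is bracketed by the
    smooth exponentials obtained by replacing INT(t/T) with t/T and
    t/T + 1:

        w0 + k_in0*T*(p0**(t/T) - 1) <= w(t) <= w0 + k_in0*T*(p0**(t/T + 1) - 1),

    showing w grows exponentially as p0**(t/T).
    """
    if params.mode != "constant_p":
        raise ValueError("asymptotic bounds apply to constant_p mode only")
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("t must be non-negative")
    x = t_arr / params.T
    lower = params.w0 + params.k_in0 * params.T * (params.p0 ** x - 1.0)
    upper = params.w0 + params.k_in0 * params.T * (params.p0 ** (x + 1.0) - 1.0)
    if t_arr.ndim == 0:
        return float(lower), float(upper)
    return lower, upper


def linear_phase_slope(params: GrowthParameters) -> float:
    """Slope of the late linear growth phase, (p0 - 1) * w_th / T.

    Valid when T is small relative to the observation horizon.  The slope is
    independent of k_in0 and w0, which only set when measurable growth
    begins.
    """
    if params.mode == "constant_p":
        raise ValueError("constant-efficiency growth has no linear phase")
    if params.mode == "linear_phase":
        return params.p_wth / params.T
    return (params.p0 - 1.0) * params.w_th / params.T
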