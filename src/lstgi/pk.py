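"""Compartmental pharmacokinetic drivers for the tumor models.

Plasma concentration C(t) is built by linear superposition of closed-form
single-dose solutions (bolus mono/bi-exponentials, first-order-absorption
Bateman and its two-compartment extension).  Each profile also exposes the
exact running integral of C, which the pharmacodynamic models consume when
evaluating per-lifespan drug exposure.

Unit conventions: doses are mg per kg body weight, volumes are apparent
L per kg (V/F for extravascular routes), all rate constants are 1/day, and
concentrations are reported in ng/mL, i.e. (mg/kg)/(L/kg) = ug/mL = 1000
ng/mL.  Dose-level-specific {kel, V} overrides implement the empirically
nonlinear kinetics seen with some compounds: each dose event evolves with
its own constants and the profiles superpose.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "PKModelSpec",
    "DoseEvent",
    "DoseRegimen",
    "ConcentrationProfile",
    "simulate_concentration",
    "cumulative_exposure",
]

_HOURS_PER_DAY = 24.0
_UG_TO_NG = 1000.0
_ROUTES = ("iv", "ip", "po")


@dataclass(frozen=True)
class PKModelSpec:
    """Structural PK model: 1 or 2 compartments, optional first-order depot.

    Rates are 1/day; ``V`` is the apparent central volume in L/kg (read as
    V/F for oral dosing).  ``per_dose_overrides`` maps a dose level (mg/kg)
    to replacement field values, e.g. ``{10.0: {"kel": 33.9, "V": 2.70}}``.
    """

    n_compartments: int
    kel: float
    V: float
    ka: float | None = None
    k12: float = 0.0
    k21: float = 0.0
    per_dose_overrides: dict[float, dict[str, float]] | None = field(default=None)

    def __post_init__(self):
        if self.n_compartments not in (1, 2):
            raise ValueError("n_compartments must be 1 or 2")
        if self.kel <= 0:
            raise ValueError("kel must be positive")
        if self.V <= 0:
            raise ValueError("V must be positive")
        if self.ka is not None and self.ka <= 0:
            raise ValueError("ka must be positive when given")
        if min(self.k12, self.k21) < 0:
            raise ValueError("inter-compartment rates must be non-negative")
        if self.n_compartments == 1 and (self.k12 != 0 or self.k21 != 0):
            raise ValueError("one-compartment model requires k12 = k21 = 0")
        if self.n_compartments == 2 and self.k21 <= 0:
            raise ValueError("two-compartment model requires k21 > 0")

    @classmethod
    def per_hour(cls, **kwargs) -> "PKModelSpec":
        """Build a spec whose rate constants are given in 1/h.

        Rates are converted to 1/day at construction; all model time is days.
        """
        converted = dict(kwargs)
        for key in ("kel", "ka", "k12", "k21"):
            if converted.get(key) is not None:
                converted[key] = converted[key] * _HOURS_PER_DAY
        return cls(**converted)

    def for_dose(self, amount: float) -> "PKModelSpec":
        if not self.per_dose_overrides:
            return self
        for level, override in self.per_dose_overrides.items():
            if math.isclose(level, amount, rel_tol=1e-9, abs_tol=1e-12):
                return replace(self, per_dose_overrides=None, **override)
        raise KeyError(
            f"dose level {amount} mg/kg not covered by per-dose PK overrides "
            f"{sorted(self.per_dose_overrides)}"
        )


@dataclass(frozen=True)
class DoseEvent:
    time: float  # day
    amount: float  # mg/kg
    route: str  # iv | ip | po

    def __post_init__(self):
        if self.amount < 0:
            raise ValueError("dose amount must be non-negative")
        if self.route not in _ROUTES:
            raise ValueError(f"route must be one of {_ROUTES}, got {self.route!r}")


@dataclass(frozen=True)
class DoseRegimen:
    """Dosing schedule; an empty event list is an untreated (control) arm."""

    events: tuple[DoseEvent, ...]

    def __post_init__(self):
        events = tuple(
            e if isinstance(e, DoseEvent) else DoseEvent(*e) for e in self.events
        )
        object.__setattr__(self, "events", events)
        times = [e.time for e in events]
        if any(t1 <= t0 for t0, t1 in zip(times, times[1:])):
            raise ValueError("dose times must be strictly increasing")

    @classmethod
    def repeated(cls, amount: float, route: str, start: float, interval: float,
                 n: int) -> "DoseRegimen":
        return cls(tuple(DoseEvent(start + i * interval, amount, route)
                         for i in range(n)))

    @property
    def times(self) -> tuple[float, ...]:
        return tuple(e.time for e in self.events)


def _two_compartment_rates(kel: float, k12: float, k21: float) -> tuple[float, float]:
    s = kel + k12 + k21
    disc = s * s - 4.0 * kel * k21
    root = math.sqrt(max(disc, 0.0))
    alpha = 0.5 * (s + root)
    beta = 0.5 * (s - root)
    return alpha, beta


def _dose_terms(spec: PKModelSpec, event: DoseEvent) -> list[tuple[float, float, int]]:
    """Exponential-sum representation of one dose: C(tau) = sum c * tau^p * exp(-r tau)."""
    spec = spec.for_dose(event.amount)
    c0 = event.amount / spec.V * _UG_TO_NG  # ng/mL
    if event.route == "iv":
        if spec.n_compartments == 1:
            return [(c0, spec.kel, 0)]
        alpha, beta = _two_compartment_rates(spec.kel, spec.k12, spec.k21)
        den = alpha - beta
        return [
            (c0 * (alpha - spec.k21) / den, alpha, 0),
            (c0 * (spec.k21 - beta) / den, beta, 0),
        ]
    # extravascular: first-order absorption from a depot
    if spec.ka is None:
        raise ValueError(f"route {event.route!r} requires an absorption rate ka")
    ka = spec.ka
    if spec.n_compartments == 1:
        if abs(ka - spec.kel) <= 1e-9 * ka:
            # flip-flop degenerate Bateman limit: C = c0 * ka * tau * exp(-ka tau)
            return [(c0 * ka, ka, 1)]
        f = c0 * ka / (ka - spec.kel)
        return [(f, spec.kel, 0), (-f, ka, 0)]
    alpha, beta = _two_compartment_rates(spec.kel, spec.k12, spec.k21)
    for r in (alpha, beta):
        if abs(ka - r) <= 1e-9 * ka:
            raise ValueError(
                "absorption rate coincides with a disposition rate; "
                "the closed-form two-compartment oral solution is degenerate"
            )
    return [
        (c0 * ka * (spec.k21 - alpha) / ((ka - alpha) * (beta - alpha)), alpha, 0),
        (c0 * ka * (spec.k21 - beta) / ((ka - beta) * (alpha - beta)), beta, 0),
        (c0 * ka * (spec.k21 - ka) / ((alpha - ka) * (beta - ka)), ka, 0),
    ]


def _term_value(c: float, r: float, p: int, tau: float) -> float:
    if p == 0:
        return c * math.exp(-r * tau)
    return c * tau * math.exp(-r * tau)


def _term_integral(c: float, r: float, p: int, tau: float) -> float:
    """Integral of the term from 0 to tau."""
    if p == 0:
        return c / r * (1.0 - math.exp(-r * tau))
    return c / (r * r) * (1.0 - (1.0 + r * tau) * math.exp(-r * tau))


class ConcentrationProfile:
    """Evaluable plasma concentration C(t) with its exact running integral.

    ``conc`` is right-continuous at bolus times (a dose at t contributes at
    t); ``conc_left`` gives the pre-dose limit, which the DDE integrator uses
    for stages that terminate a step exactly at a dose time.
    """

    def __init__(self, doses: list[tuple[float, list[tuple[float, float, int]]]],
                 t_last: float):
        if t_last < 0:
            raise ValueError("t_last must be non-negative")
        self._doses = sorted(doses, key=lambda d: d[0])
        self.t_last = float(t_last)
        self.dose_times = tuple(t0 for t0, _ in self._doses)

    def conc(self, t):
        if np.ndim(t) > 0:
            return np.array([self.conc(float(ti)) for ti in np.asarray(t).ravel()])
        total = 0.0
        for t0, terms in self._doses:
            tau = t - t0
            if tau < 0:
                break
            for c, r, p in terms:
                total += _term_value(c, r, p, tau)
        return max(total, 0.0)

    __call__ = conc

    def conc_left(self, t: float) -> float:
        total = 0.0
        for t0, terms in self._doses:
            tau = t - t0
            if tau <= 1e-12 * max(1.0, abs(t)):
                break
            for c, r, p in terms:
                total += _term_value(c, r, p, tau)
        return max(total, 0.0)

    def cumulative(self, t):
        """Integral of C from 0 to t (ng*day/mL); zero contribution for t < 0."""
        if np.ndim(t) > 0:
            return np.array([self.cumulative(float(ti)) for ti in np.asarray(t).ravel()])
        if t <= 0:
            return 0.0
        total = 0.0
        for t0, terms in self._doses:
            tau = t - t0
            if tau <= 0:
                break
            for c, r, p in terms:
                total += _term_integral(c, r, p, tau)
        return total

    def cmax(self, n_grid: int = 4001) -> float:
        """Maximum of C(t) over [0, t_last] (checks dose-time right limits too)."""
        grid = np.linspace(0.0, self.t_last, n_grid)
        best = max((self.conc(float(t)) for t in grid), default=0.0)
        for t0 in self.dose_times:
            best = max(best, self.conc(t0))
        return best


def simulate_concentration(spec: PKModelSpec, regimen: DoseRegimen,
                           t_last: float) -> ConcentrationProfile:
    """Closed-form superposition concentration profile for a dosing regimen."""
    if t_last < 0:
        raise ValueError("t_last must be non-negative")
    if regimen.events and t_last < regimen.events[-1].time:
        raise ValueError("t_last must cover the last dose time")
    doses = [(e.time, _dose_terms(spec, e)) for e in regimen.events if e.amount > 0]
    return ConcentrationProfile(doses, t_last)


def cumulative_exposure(profile: ConcentrationProfile, t0: float, t1: float) -> float:
    """Drug exposure integral of C over (t0, t1); times before 0 contribute zero."""
    if t1 < t0:
        raise ValueError(f"t1 ({t1}) must be >= t0 ({t0})")
    return profile.cumulative(t1) - profile.cumulative(max(t0, 0.0))
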