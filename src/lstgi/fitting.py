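"""Two-stage estimation workflow for the lifespan TGI model.

The model output is discontinuous in the lifespans T and T_A (the integer
lag count jumps), so those two parameters cannot be found by gradient
minimization: they are grid-searched, and at every grid node the remaining
continuous parameters are estimated by nonlinear least squares (bounds
enforced through smooth log / scaled-logit transforms).  The standard
xenograft workflow is sequential: growth parameters are estimated on the
control arm first, then fixed while the drug parameters are estimated on
the treated arms; an optional final pass refits all continuous parameters
simultaneously with the lifespans held at their grid optima.

Precision is reported as CV% = 100 * SE / estimate, with standard errors
from the asymptotic covariance s^2 (J'J)^-1 of the final Jacobian.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .effects import (DrugEffectSpec, simulate_cycle_specific,
                      simulate_non_cycle_specific)
from .growth import GrowthParameters, simulate_unperturbed
from .pk import DoseRegimen, PKModelSpec, simulate_concentration
from .simeoni import SimeoniLinearParams, simulate_simeoni_linear

__all__ = [
    "FitConfig",
    "FitResult",
    "StudyModel",
    "SimeoniStudyModel",
    "fit_continuous",
    "grid_search_lifespans",
    "sequential_fit_workflow",
]

_GROWTH_KEYS = ("T", "k_in0", "p0", "w_th", "psi", "p_wth", "w0")
_DRUG_KEYS = ("T_A", "k2", "Emax", "EC50")


def grid_values(spec) -> np.ndarray:
    """Resolve a grid spec: an explicit sequence, or (min, max, step)."""
    if spec is None:
        raise ValueError("grid spec is required")
    if isinstance(spec, dict):
        spec = (spec["min"], spec["max"], spec["step"])
    spec = tuple(np.atleast_1d(np.asarray(spec, dtype=float)))
    if len(spec) == 3 and spec[2] < spec[1]:  # (min, max, step) convention
        lo, hi, step = spec
        if step <= 0:
            raise ValueError("grid step must be positive")
        n = int(round((hi - lo) / step))
        return lo + step * np.arange(n + 1)
    vals = np.asarray(spec, dtype=float)
    if vals.size == 0:
        raise ValueError("grid must be non-empty")
    return np.sort(vals)


@dataclass
class FitConfig:
    """Free parameters are given as name -> (initial, lower, upper)."""

    free: dict[str, tuple[float, float, float]] = field(default_factory=dict)
    free_drug: dict[str, tuple[float, float, float]] = field(default_factory=dict)
    fixed: dict[str, float] = field(default_factory=dict)
    t_grid: object = None
    ta_grid: object = None
    weighting: str = "unweighted"  # or "proportional"
    n_starts: int = 5
    jitter: float = 0.2
    seed: int | None = 0
    max_nfev: int = 200
    simultaneous_refit: bool = False
    regrid_T: bool = False  # also re-grid T alongside T_A in the treated stage

    def __post_init__(self):
        if self.weighting not in ("unweighted", "proportional"):
            raise ValueError("weighting must be 'unweighted' or 'proportional'")
        for name, (init, lo, hi) in {**self.free, **self.free_drug}.items():
            if not lo <= init <= hi:
                raise ValueError(f"initial value of {name} outside its bounds")
            if name == "p0" and not (lo >= 1.0 and hi <= 2.0):
                raise ValueError("p0 bounds must respect 1 <= p0 <= 2")
            if name == "Emax" and not (lo >= 0.0 and hi <= 1.0):
                raise ValueError("Emax bounds must respect 0 <= Emax <= 1")

    def replace(self, **kwargs) -> "FitConfig":
        return replace(self, **kwargs)


@dataclass
class FitResult:
    estimates: dict[str, float]          # free estimates plus fixed values
    cv_percent: dict[str, float | None]  # free parameters only
    ssr: float
    residuals: np.ndarray
    fitted: pd.DataFrame                 # arm, time_day, observed, predicted
    fixed: dict[str, float]
    converged: bool
    n_obs: int
    grid_trace: list[dict] = field(default_factory=list)


class StudyModel:
    """Prediction engine mapping a parameter dict to tumor-size curves.

    Holds the structural choices (growth mode/efficiency form, drug
    mechanism, PK model, per-arm regimens); parameter values passed to
    ``predict`` override the template values.
    """

    def __init__(self, growth: GrowthParameters,
                 drug: DrugEffectSpec | None = None,
                 pk_spec: PKModelSpec | None = None,
                 regimens: dict[str, DoseRegimen] | None = None,
                 form: str | None = None, pps: int = 32,
                 efficiency_of_total: bool = True):
        self.growth = growth
        self.drug = drug
        self.pk_spec = pk_spec
        self.regimens = regimens or {}
        self.form = form
        self.pps = pps
        self.efficiency_of_total = efficiency_of_total

    def _growth_params(self, params) -> GrowthParameters:
        over = {k: params[k] for k in _GROWTH_KEYS if k in params}
        return self.growth.with_(**over) if over else self.growth

    def _drug_spec(self, params) -> DrugEffectSpec:
        over = {k: params[k] for k in _DRUG_KEYS if k in params}
        return self.drug.with_(**over) if over else self.drug

    def predict(self, params, arm: str, times) -> np.ndarray:
        times = np.asarray(times, dtype=float)
        t_last = float(times.max()) + 1e-9
        growth = self._growth_params(params)
        regimen = self.regimens.get(arm)
        if regimen is None or not regimen.events or self.drug is None:
            traj = simulate_unperturbed(growth, t_last, form=self.form,
                                        pps=self.pps)
            return traj.w_at(times)
        drug = self._drug_spec(params)
        profile = simulate_concentration(self.pk_spec, regimen, t_last)
        sim = (simulate_cycle_specific
               if drug.mechanism == "cycle_specific"
               else simulate_non_cycle_specific)
        traj = sim(growth, drug, profile, t_last, form=self.form, pps=self.pps,
                   efficiency_of_total=self.efficiency_of_total)
        return traj.w_at(times)


class SimeoniStudyModel:
    """Same prediction interface for the linearized reference model."""

    _KEYS = ("lambda1", "k1", "k2", "w0")

    def __init__(self, params: SimeoniLinearParams, pk_spec: PKModelSpec,
                 regimens: dict[str, DoseRegimen], steps_per_day: int = 50):
        self.params = params
        self.pk_spec = pk_spec
        self.regimens = regimens or {}
        self.steps_per_day = steps_per_day

    def predict(self, params, arm: str, times) -> np.ndarray:
        times = np.asarray(times, dtype=float)
        t_last = float(times.max()) + 1e-9
        over = {k: params[k] for k in self._KEYS if k in params}
        p = self.params.with_(**over) if over else self.params
        regimen = self.regimens.get(arm) or DoseRegimen(())
        profile = simulate_concentration(self.pk_spec, regimen, t_last)
        traj = simulate_simeoni_linear(p, profile, t_last,
                                       steps_per_day=self.steps_per_day)
        return traj.w_at(times)


# ---------------------------------------------------------------------------
# bound transforms: optimize in an unconstrained space


def _to_internal(x, lo, hi):
    if math.isfinite(lo) and math.isfinite(hi):
        u = (x - lo) / (hi - lo)
        u = min(max(u, 1e-9), 1.0 - 1e-9)
        return math.log(u / (1.0 - u))
    if math.isfinite(lo):
        return math.log(max(x - lo, 1e-300))
    return x


def _from_internal(z, lo, hi):
    if math.isfinite(lo) and math.isfinite(hi):
        return lo + (hi - lo) / (1.0 + math.exp(-z))
    if math.isfinite(lo):
        return lo + math.exp(min(z, 700.0))
    return z


def _check_dataset(dataset: pd.DataFrame) -> pd.DataFrame:
    required = {"arm", "time_day", "volume"}
    missing = required - set(dataset.columns)
    if missing:
        raise ValueError(f"dataset is missing columns {sorted(missing)}")
    return dataset.reset_index(drop=True)


def _predict_all(model, params, dataset: pd.DataFrame) -> np.ndarray:
    pred = np.empty(len(dataset))
    for arm, idx in dataset.groupby("arm", sort=False).groups.items():
        idx = np.asarray(idx)
        pred[idx] = model.predict(params, str(arm),
                                  dataset.loc[idx, "time_day"].to_numpy())
    return pred


def fit_continuous(model, dataset: pd.DataFrame, config: FitConfig,
                   free: dict | None = None) -> FitResult:
    """Least-squares estimation of the continuous parameters.

    ``model`` is any object with ``predict(params, arm, times)``.  The
    lifespans (and anything else held constant) go in ``config.fixed`` and
    are echoed unchanged in the result.  Multi-start with seeded jitter
    guards against local minima of the rugged DDE objective surface.
    """
    dataset = _check_dataset(dataset)
    free = dict(free if free is not None else config.free)
    if not free:
        raise ValueError("at least one free parameter is required")
    if len(dataset) < len(free) + 1:
        raise ValueError("need at least n_free + 1 observations")
    names = list(free)
    bounds = {k: (free[k][1], free[k][2]) for k in names}
    obs = dataset["volume"].to_numpy(dtype=float)
    proportional = config.weighting == "proportional"

    def params_of(z):
        return {**config.fixed,
                **{k: _from_internal(zi, *bounds[k]) for k, zi in zip(names, z)}}

    def residual(z):
        try:
            pred = _predict_all(model, params_of(z), dataset)
        except Exception:
            # a pathological trial point (e.g. potency collapsing the tumor
            # to zero mass) counts as a very poor fit, not a fatal error
            return np.full(len(obs), 1e6)
        r = obs - pred
        if proportional:
            r = r / np.maximum(np.abs(pred), 1e-12)
        return r

    z0 = np.array([_to_internal(free[k][0], *bounds[k]) for k in names])
    rng = np.random.default_rng(config.seed)
    starts = [z0] + [z0 + config.jitter * rng.standard_normal(len(z0))
                     for _ in range(max(config.n_starts - 1, 0))]
    best = None
    converged = False
    for z_start in starts:
        try:
            sol = least_squares(residual, z_start, method="trf",
                                max_nfev=config.max_nfev)
        except Exception:
            continue
        ssr = float(2.0 * sol.cost)
        if best is None or ssr < best[0]:
            best = (ssr, sol)
            converged = converged or sol.status > 0
    if best is None:
        raise RuntimeError("all optimization starts failed")
    ssr, sol = best
    estimates = {k: _from_internal(zi, *bounds[k]) for k, zi in zip(names, sol.x)}
    resid = residual(sol.x)
    pred = _predict_all(model, {**config.fixed, **estimates}, dataset)
    cv = _cv_percent(model, dataset, config, estimates, bounds, resid,
                     proportional)
    fitted = dataset[["arm", "time_day"]].copy()
    fitted["observed"] = obs
    fitted["predicted"] = pred
    return FitResult(estimates={**estimates, **config.fixed},
                     cv_percent=cv, ssr=ssr, residuals=resid, fitted=fitted,
                     fixed=dict(config.fixed), converged=converged,
                     n_obs=len(dataset))


def _cv_percent(model, dataset, config, estimates, bounds, resid,
                proportional) -> dict:
    """CV% from the Jacobian-based asymptotic covariance s^2 (J'J)^-1,
    differentiated in the natural parameter space."""
    names = list(estimates)
    n, p = len(resid), len(names)
    cv: dict[str, float | None] = {k: None for k in names}
    if n <= p:
        return cv
    obs = dataset["volume"].to_numpy(dtype=float)

    def r_of(theta):
        pred = _predict_all(model, {**config.fixed,
                                    **dict(zip(names, theta))}, dataset)
        r = obs - pred
        return r / np.maximum(np.abs(pred), 1e-12) if proportional else r

    theta = np.array([estimates[k] for k in names])
    J = np.empty((n, p))
    for j, name in enumerate(names):
        lo, hi = bounds[name]
        h = 1e-4 * max(abs(theta[j]), 1e-8)
        tp, tm = theta.copy(), theta.copy()
        tp[j] = min(theta[j] + h, hi) if math.isfinite(hi) else theta[j] + h
        tm[j] = max(theta[j] - h, lo)
        if tp[j] == tm[j]:
            return cv
        J[:, j] = (r_of(tp) - r_of(tm)) / (tp[j] - tm[j])
    s2 = float(resid @ resid) / (n - p)
    jtj = J.T @ J
    try:
        cov = s2 * np.linalg.inv(jtj)
    except np.linalg.LinAlgError:
        return cv  # singular Jacobian: CV% unavailable, not fabricated
    if not np.all(np.isfinite(cov)) or np.any(np.diag(cov) < 0):
        return cv
    for j, name in enumerate(names):
        if abs(theta[j]) > 0:
            cv[name] = 100.0 * math.sqrt(cov[j, j]) / abs(theta[j])
    return cv


def grid_search_lifespans(model, dataset: pd.DataFrame, config: FitConfig,
                          free: dict | None = None,
                          ) -> tuple[float, float | None, list[dict]]:
    """Exhaustive search over the discontinuous lifespan parameters.

    For every node of the T grid (and the T_A grid, when present) the
    continuous parameters are re-fitted and the node SSR recorded; the node
    with minimal SSR wins, ties broken toward smaller T then smaller T_A.
    """
    t_values = grid_values(config.t_grid) if config.t_grid is not None else None
    ta_values = (grid_values(config.ta_grid)
                 if config.ta_grid is not None else None)
    if t_values is None and ta_values is None:
        raise ValueError("a grid for T and/or T_A is required")
    nodes = [(t, ta)
             for t in (t_values if t_values is not None else [None])
             for ta in (ta_values if ta_values is not None else [None])]
    trace, best = [], None
    for T, TA in nodes:
        fixed = dict(config.fixed)
        if T is not None:
            fixed["T"] = float(T)
        if TA is not None:
            fixed["T_A"] = float(TA)
        node = {"T": T if T is None else float(T),
                "T_A": TA if TA is None else float(TA)}
        try:
            res = fit_continuous(model, dataset, config.replace(fixed=fixed),
                                 free=free)
        except Exception as exc:
            trace.append({**node, "ssr": math.inf, "converged": False,
                          "error": str(exc)})
            continue
        trace.append({**node, "ssr": res.ssr, "converged": res.converged,
                      "result": res})
        if best is None or res.ssr < best[0] - 0.0:
            best = (res.ssr, node["T"], node["T_A"], res)
    if best is None:
        raise RuntimeError("grid search failed at every node")
    return best[1], best[2], trace


def _best_from_trace(trace):
    ok = [t for t in trace if "result" in t]
    return min(ok, key=lambda t: t["ssr"])


def sequential_fit_workflow(control_data: pd.DataFrame,
                            treated_data_by_dose: dict[str, pd.DataFrame],
                            model: StudyModel, config: FitConfig) -> dict:
    """Control-then-treated estimation mirroring the xenograft workflow.

    Stage 1: grid-search T on the control arm while fitting the continuous
    growth parameters.  Stage 2: fix the stage-1 values, grid-search T_A
    (optionally T as well) while fitting the drug parameters jointly across
    treated arms.  Stage 3 (optional): refit all continuous parameters on
    all arms with the lifespans fixed.
    """
    report: dict = {}
    best_T, _, trace1 = grid_search_lifespans(
        model, control_data, config.replace(ta_grid=None), free=config.free)
    node1 = _best_from_trace(trace1)
    stage1: FitResult = node1["result"]
    stage1.grid_trace = [{k: v for k, v in t.items() if k != "result"}
                         for t in trace1]
    report["stage1"] = {"best_T": best_T, "result": stage1}
    if not treated_data_by_dose:
        return report

    growth_fixed = {k: v for k, v in stage1.estimates.items()
                    if k in _GROWTH_KEYS}
    growth_fixed["T"] = best_T
    treated = pd.concat(treated_data_by_dose.values(), ignore_index=True)
    cfg2 = config.replace(fixed={**config.fixed, **growth_fixed},
                          t_grid=config.t_grid if config.regrid_T else None)
    _, best_TA, trace2 = grid_search_lifespans(
        model, treated, cfg2, free=config.free_drug)
    node2 = _best_from_trace(trace2)
    best_T2 = node2["T"] if node2["T"] is not None else best_T
    stage2: FitResult = node2["result"]
    stage2.grid_trace = [{k: v for k, v in t.items() if k != "result"}
                         for t in trace2]
    report["stage2"] = {"best_T": best_T2, "best_TA": best_TA,
                        "result": stage2}
    if not config.simultaneous_refit:
        return report

    all_data = pd.concat([control_data, treated], ignore_index=True)
    fixed3 = {**config.fixed, "T": best_T2, "T_A": best_TA}
    init3 = dict(config.free)
    for k in init3:  # warm-start from stage 1
        if k in stage1.estimates:
            lo, hi = init3[k][1], init3[k][2]
            init3[k] = (min(max(stage1.estimates[k], lo), hi), lo, hi)
    init_drug = dict(config.free_drug)
    for k in init_drug:
        if k in stage2.estimates:
            lo, hi = init_drug[k][1], init_drug[k][2]
            init_drug[k] = (min(max(stage2.estimates[k], lo), hi), lo, hi)
    stage3 = fit_continuous(model, all_data, config.replace(fixed=fixed3),
                            free={**init3, **init_drug})
    report["stage3"] = {"T": best_T2, "T_A": best_TA, "result": stage3}
    return report
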