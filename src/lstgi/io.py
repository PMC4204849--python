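"""Tabular I/O and configuration handling.

Observations are long-format CSV (arm, time_day, volume); dosing is CSV
(arm, time_day, dose_mg_per_kg, route).  Run configuration is YAML/JSON
with sections growth/drug/pk/reference/fit/synth/sim; unknown keys are
rejected with their location so typos fail loudly.  Time is days with t = 0
at the start of observation/treatment of the dataset at hand.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .effects import DrugEffectSpec
from .fitting import FitConfig
from .growth import GrowthParameters
from .pk import DoseEvent, DoseRegimen, PKModelSpec
from .simeoni import SimeoniLinearParams

__all__ = [
    "read_observations", "read_dosing", "regimens_from_dosing",
    "load_config", "validate_config", "write_resolved_config",
    "growth_from_config", "drug_from_config", "pk_from_config",
    "simeoni_from_config", "fitconfig_from_config",
]

_SCHEMA = {
    "growth": {"mode", "T", "k_in0", "p0", "w_th", "psi", "p_wth", "w0"},
    "drug": {"mechanism", "effect_form", "k2", "Emax", "EC50", "T_A"},
    "pk": {"n_compartments", "ka", "kel", "k12", "k21", "V",
           "rates_per_hour", "per_dose"},
    "reference": {"lambda1", "k1", "k2", "w0", "n_transit"},
    "fit": {"free", "free_drug", "fixed", "t_grid", "ta_grid", "weighting",
            "n_starts", "jitter", "seed", "max_nfev", "simultaneous_refit",
            "regrid_T", "pps"},
    "synth": {"template", "noise_cv", "noise_sd", "seed"},
    "sim": {"t_last", "pps", "form", "efficiency_of_total"},
}
_TOP_KEYS = set(_SCHEMA) | {"output_dir", "seed"}


class ConfigError(ValueError):
    pass


def validate_config(cfg: dict) -> dict:
    if not isinstance(cfg, dict):
        raise ConfigError("configuration root must be a mapping")
    for key in cfg:
        if key not in _TOP_KEYS:
            raise ConfigError(f"unknown configuration key {key!r} (top level)")
    for section, allowed in _SCHEMA.items():
        sub = cfg.get(section)
        if sub is None:
            continue
        if not isinstance(sub, dict):
            raise ConfigError(f"section {section!r} must be a mapping")
        for key in sub:
            if key not in allowed:
                raise ConfigError(
                    f"unknown configuration key {key!r} at {section}.{key}")
    return cfg


def load_config(path) -> dict:
    text = Path(path).read_text()
    cfg = yaml.safe_load(text) or {}
    return validate_config(cfg)


def write_resolved_config(cfg: dict, outdir) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    path = outdir / "resolved_config.yaml"
    path.write_text(yaml.safe_dump(cfg, sort_keys=False))
    return path


def _check_columns(df: pd.DataFrame, required, path):
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing} "
                         f"(found {list(df.columns)})")


def read_observations(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _check_columns(df, ["arm", "time_day", "volume"], path)
    bad = df[~np.isfinite(df["volume"]) | (df["volume"] <= 0)]
    if len(bad):
        raise ValueError(
            f"{path}: non-positive or non-finite volumes at rows "
            f"{list(bad.index[:5])}")
    return df


def read_dosing(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _check_columns(df, ["arm", "time_day", "dose_mg_per_kg", "route"], path)
    return df


def regimens_from_dosing(dosing: pd.DataFrame) -> dict[str, DoseRegimen]:
    regimens: dict[str, DoseRegimen] = {}
    for arm, grp in dosing.groupby("arm", sort=False):
        grp = grp.sort_values("time_day")
        regimens[str(arm)] = DoseRegimen(tuple(
            DoseEvent(float(r.time_day), float(r.dose_mg_per_kg), str(r.route))
            for r in grp.itertuples()))
    return regimens


def growth_from_config(cfg: dict) -> GrowthParameters:
    sec = dict(cfg.get("growth") or {})
    if not sec:
        raise ConfigError("a 'growth' section is required")
    return GrowthParameters(**sec)


def drug_from_config(cfg: dict) -> DrugEffectSpec | None:
    sec = dict(cfg.get("drug") or {})
    return DrugEffectSpec(**sec) if sec else None


def pk_from_config(cfg: dict) -> PKModelSpec | None:
    sec = dict(cfg.get("pk") or {})
    if not sec:
        return None
    per_dose = sec.pop("per_dose", None)
    if per_dose is not None:
        sec["per_dose_overrides"] = {float(k): dict(v)
                                     for k, v in per_dose.items()}
    if sec.pop("rates_per_hour", False):
        return PKModelSpec.per_hour(**sec)
    return PKModelSpec(**sec)


def simeoni_from_config(cfg: dict) -> SimeoniLinearParams | None:
    sec = dict(cfg.get("reference") or {})
    return SimeoniLinearParams(**sec) if sec else None


def _free_block(block) -> dict[str, tuple[float, float, float]]:
    out = {}
    for name, spec in (block or {}).items():
        if isinstance(spec, dict):
            out[name] = (float(spec["init"]),
                         float(spec.get("lower", -np.inf)),
                         float(spec.get("upper", np.inf)))
        else:
            init, lo, hi = spec
            out[name] = (float(init), float(lo), float(hi))
    return out


def fitconfig_from_config(cfg: dict) -> FitConfig:
    sec = dict(cfg.get("fit") or {})
    sec.pop("pps", None)  # consumed by the model builder, not the fit
    sec["free"] = _free_block(sec.get("free"))
    sec["free_drug"] = _free_block(sec.get("free_drug"))
    if "fixed" in sec and sec["fixed"]:
        sec["fixed"] = {str(k): float(v) for k, v in sec["fixed"].items()}
    return FitConfig(**sec)


def result_to_jsonable(result) -> dict:
    """FitResult -> plain-JSON dict for reports."""
    return {
        "estimates": {k: float(v) for k, v in result.estimates.items()},
        "cv_percent": {k: (None if v is None else float(v))
                       for k, v in result.cv_percent.items()},
        "ssr": float(result.ssr),
        "n_obs": int(result.n_obs),
        "converged": bool(result.converged),
        "fixed": {k: float(v) for k, v in result.fixed.items()},
        "grid_trace": [
            {k: (None if v is None else (v if isinstance(v, (str, bool))
                                         else float(v)))
             for k, v in node.items()}
            for node in result.grid_trace],
    }


def save_report(report: dict, path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, default=float))
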