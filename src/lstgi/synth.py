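"""Synthetic xenograft studies with known ground truth.

Three templates emulate the designs of the case studies the model family
was built for: a taxane given 30 mg/kg i.v. every 4 days (three doses from
day 8, biphasic growth, cycle-specific kill), a CK2 inhibitor given 10/20/30
mg/kg i.p. weekly for three weeks (linear-only growth, non-cycle-specific
linear kill, dose-specific PK), and a Pim-kinase inhibitor given 0.3-30
mg/kg orally once daily (exponential-only growth, non-cycle-specific
saturable kill, flip-flop oral PK).  Truth parameters default to published
fitted values used here as realistic fixtures.

One pooled tumor-size series per arm is generated (group-mean style);
observation noise is proportional by default, y = w * (1 + CV * eps) +
SD * eps', with non-positive draws resampled and the resample count logged
in the provenance block.  Identical seed and design regenerate the dataset
bit-identically.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .effects import (DrugEffectSpec, simulate_cycle_specific,
                      simulate_non_cycle_specific)
from .growth import GrowthParameters, simulate_unperturbed
from .pk import DoseRegimen, PKModelSpec, simulate_concentration

__all__ = ["StudyArm", "StudyDesign", "SyntheticDataset", "generate_study",
           "casestudy_template", "TEMPLATES"]


@dataclass(frozen=True)
class StudyArm:
    label: str
    regimen: DoseRegimen
    obs_times: tuple[float, ...]

    def __post_init__(self):
        times = self.obs_times
        if any(t < 0 for t in times) or any(
                b <= a for a, b in zip(times, times[1:])):
            raise ValueError("observation times must be non-negative and "
                             "strictly increasing")


@dataclass
class StudyDesign:
    name: str
    arms: list[StudyArm]
    growth: GrowthParameters
    drug: DrugEffectSpec | None
    pk_spec: PKModelSpec | None
    form: str | None = None
    noise_cv: float = 0.05
    noise_sd: float = 0.0
    seed: int = 0
    pps: int = 64

    def __post_init__(self):
        if self.noise_cv < 0 or self.noise_sd < 0:
            raise ValueError("noise magnitudes must be non-negative")


@dataclass
class SyntheticDataset:
    data: pd.DataFrame     # long format: arm, time_day, volume
    dosing: pd.DataFrame   # arm, time_day, dose_mg_per_kg, route
    provenance: dict

    def save(self, outdir):
        import json
        from pathlib import Path
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.data.to_csv(outdir / "observations.csv", index=False)
        self.dosing.to_csv(outdir / "dosing.csv", index=False)
        (outdir / "provenance.json").write_text(
            json.dumps(self.provenance, indent=2, default=str))


def _simulate_arm(design: StudyDesign, arm: StudyArm) -> np.ndarray:
    times = np.asarray(arm.obs_times, dtype=float)
    t_last = float(times.max()) + 1e-9
    if not arm.regimen.events or design.drug is None:
        traj = simulate_unperturbed(design.growth, t_last, form=design.form,
                                    pps=design.pps)
        return traj.w_at(times)
    profile = simulate_concentration(design.pk_spec, arm.regimen, t_last)
    sim = (simulate_cycle_specific
           if design.drug.mechanism == "cycle_specific"
           else simulate_non_cycle_specific)
    traj = sim(design.growth, design.drug, profile, t_last, form=design.form,
               pps=design.pps)
    return traj.w_at(times)


def generate_study(design: StudyDesign) -> SyntheticDataset:
    """Simulate every arm of the design and apply observation noise."""
    rng = np.random.default_rng(design.seed)
    rows, dose_rows = [], []
    resampled = 0
    for arm in design.arms:
        w_hat = _simulate_arm(design, arm)
        for t, w in zip(arm.obs_times, w_hat):
            y = -1.0
            while y <= 0:
                if y != -1.0:
                    resampled += 1
                y = (w * (1.0 + design.noise_cv * rng.standard_normal())
                     + design.noise_sd * rng.standard_normal())
                if design.noise_cv == 0 and design.noise_sd == 0:
                    y = w
                    break
            rows.append({"arm": arm.label, "time_day": t, "volume": y})
        for e in arm.regimen.events:
            dose_rows.append({"arm": arm.label, "time_day": e.time,
                              "dose_mg_per_kg": e.amount, "route": e.route})
    provenance = {
        "design": design.name,
        "seed": design.seed,
        "noise_cv": design.noise_cv,
        "noise_sd": design.noise_sd,
        "n_resampled_nonpositive": resampled,
        "truth": {
            "growth": dataclasses.asdict(design.growth),
            "drug": dataclasses.asdict(design.drug) if design.drug else None,
            "pk": dataclasses.asdict(design.pk_spec) if design.pk_spec else None,
            "form": design.form,
        },
    }
    dosing = pd.DataFrame(dose_rows,
                          columns=["arm", "time_day", "dose_mg_per_kg", "route"])
    return SyntheticDataset(pd.DataFrame(rows), dosing, provenance)


# ---------------------------------------------------------------------------
# case-study templates


def _paclitaxel_design(seed: int, noise_cv: float) -> StudyDesign:
    growth = GrowthParameters(T=1.46, k_in0=4.04e-2, w0=0.033, p0=1.44,
                              w_th=2.48, mode="full")
    drug = DrugEffectSpec(mechanism="cycle_specific", effect_form="emax",
                          T_A=0.536, Emax=1.0, EC50=9.45)
    pk = PKModelSpec.per_hour(n_compartments=2, kel=0.868, k12=0.006,
                              k21=0.0838, V=0.81)
    obs = tuple(float(t) for t in range(7, 41, 3))
    arms = [
        StudyArm("control", DoseRegimen(()), obs),
        StudyArm("paclitaxel-30",
                 DoseRegimen.repeated(30.0, "iv", start=8.0, interval=4.0, n=3),
                 obs),
    ]
    return StudyDesign("paclitaxel", arms, growth, drug, pk,
                       noise_cv=noise_cv, seed=seed)


def _az968_design(seed: int, noise_cv: float) -> StudyDesign:
    growth = GrowthParameters(T=1.28, k_in0=49.9, w0=180.0, p_wth=80.8,
                              mode="linear_phase")
    drug = DrugEffectSpec(mechanism="non_cycle_specific", effect_form="linear",
                          T_A=5.56, k2=2.30e-3)
    pk = PKModelSpec(
        n_compartments=2, kel=33.9, V=2.70, ka=46.8, k12=8.74, k21=11.2,
        per_dose_overrides={10.0: {"kel": 33.9, "V": 2.70},
                            20.0: {"kel": 26.0, "V": 2.07},
                            30.0: {"kel": 24.7, "V": 1.97}})
    # thrice-weekly measurements (dose day, +48 h, +120 h), final extra
    # point 216 h after the last weekly dose for treated arms
    obs_control = (0.0, 2.0, 5.0, 7.0, 9.0, 12.0, 14.0, 16.0, 19.0)
    obs_treated = obs_control + (23.0,)
    arms = [StudyArm("control", DoseRegimen(()), obs_control)]
    for dose in (10.0, 20.0, 30.0):
        arms.append(StudyArm(
            f"az968-{dose:g}",
            DoseRegimen.repeated(dose, "ip", start=0.0, interval=7.0, n=3),
            obs_treated))
    return StudyDesign("az968", arms, growth, drug, pk,
                       noise_cv=noise_cv, seed=seed)


def _azd1208_design(seed: int, noise_cv: float) -> StudyDesign:
    w0 = 170.0
    growth = GrowthParameters(T=3.0, k_in0=27.8, w0=w0, p0=1.57,
                              w_th=1e9 * w0, mode="full")
    drug = DrugEffectSpec(mechanism="non_cycle_specific", effect_form="emax",
                          T_A=1.92, Emax=0.159, EC50=182.0)
    pk = PKModelSpec(n_compartments=1, kel=5.52, ka=5.52, V=4.86)
    obs = (1.0, 4.0, 7.0, 10.0, 13.0, 16.0, 19.0, 22.0)
    arms = [StudyArm("control", DoseRegimen(()), obs)]
    for dose in (0.3, 1.0, 3.0, 10.0, 30.0):
        arms.append(StudyArm(
            f"azd1208-{dose:g}",
            DoseRegimen.repeated(dose, "po", start=1.0, interval=1.0, n=14),
            obs))
    return StudyDesign("azd1208", arms, growth, drug, pk,
                       noise_cv=noise_cv, seed=seed)


TEMPLATES = {
    "paclitaxel": _paclitaxel_design,
    "az968": _az968_design,
    "azd1208": _azd1208_design,
}


def casestudy_template(name: str, seed: int = 0,
                       noise_cv: float = 0.05) -> StudyDesign:
    """Fully populated design for one of the three case-study templates."""
    try:
        builder = TEMPLATES[name]
    except KeyError:
        raise ValueError(
            f"unknown template {name!r}; available: {sorted(TEMPLATES)}"
        ) from None
    return builder(seed, noise_cv)
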