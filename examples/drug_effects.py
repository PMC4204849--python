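"""Delayed tumor shrinkage under the two drug-effect mechanisms.

Simulates the sensitivity-analysis fixture (doses on days 10/20/30, kill
delay T_A = 4 d) with non-cycle-specific (continuous kill) and
cycle-specific (kill at division) drug action, and shows that the decline
of total tumor mass starts exactly T_A after dosing.
"""

import numpy as np

from lstgi import (DoseRegimen, DrugEffectSpec, GrowthParameters, PKModelSpec,
                   simulate_concentration, simulate_cycle_specific,
                   simulate_non_cycle_specific, simulate_unperturbed)

growth = GrowthParameters(T=1.0, k_in0=0.05, w0=0.05, p0=2.0, w_th=10.0)
pk = PKModelSpec(n_compartments=2, kel=20.0, k12=0.2, k21=2.0, V=1000.0)
regimen = DoseRegimen(((10.0, 10.0, "iv"), (20.0, 10.0, "iv"),
                       (30.0, 10.0, "iv")))
profile = simulate_concentration(pk, regimen, 45.0)

ncs = simulate_non_cycle_specific(
    growth,
    DrugEffectSpec(mechanism="non_cycle_specific", effect_form="linear",
                   T_A=4.0, k2=1.5),
    profile, 45.0)
cs = simulate_cycle_specific(
    growth,
    DrugEffectSpec(mechanism="cycle_specific", effect_form="emax",
                   T_A=4.0, Emax=1.0, EC50=0.01),
    profile, 45.0)
ctrl = simulate_unperturbed(growth, 45.0)


def onset(traj):
    ts = np.arange(10.0, 25.0, 0.02)
    w = traj.w_at(ts)
    return ts[np.where(np.diff(w) < 0)[0][0]]


print(f"control w(45 d)            : {ctrl.w_at(45.0):7.1f}")
print(f"non-cycle-specific w(45 d) : {ncs.w_at(45.0):7.1f}  "
      f"decline onset day {onset(ncs):.2f}")
print(f"cycle-specific w(45 d)     : {cs.w_at(45.0):7.1f}  "
      f"decline onset day {onset(cs):.2f}")
print("Both mechanisms shrink the tumor only T_A = 4 days after the day-10")
print("dose: killed cells stay in the apoptotic pool (still palpable mass)")
print("until their apoptosis lifespan elapses.")
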