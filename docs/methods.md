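# Methods

## The lifespan model of tumor growth

`lstgi` models a xenograft tumor as a population of cells that each live
for a fixed lifespan `T` (days) and divide at its end.  Tumor size `w`
(grams or mm³ — the model is unit-opaque and runs in whatever unit the
observations use) obeys a production/elimination balance

    dw/dt = k_in(t) - k_out(t),        k_out(t) = k_in(t - T),

where the elimination rate is the production rate lagged by one lifespan:
every cohort of newly produced cells disappears (by dividing) exactly `T`
days later.  Division feeds production back with an efficiency
`p(w) ∈ [1, 2]` — the number of daughter cells per division that join the
tumor:

    k_in(t) = p(w(t)) · k_in(t - T),
    k_in(t) = k_in0   for -T < t ≤ 0.

The constant pre-experiment history `k_in0` (mass/day) is an estimable
parameter; it decides when measurable growth begins but affects neither the
exponential rate nor the linear slope.  A time-varying history is
deliberately not supported.

Division efficiency decreases with tumor burden:

    p(w) = 1 + (p0 - 1) · (1 + (w / w_th)^ψ)^(-1/ψ),

which plateaus at `p0` below the threshold size `w_th` and decays like
`1 + (p0 - 1)·w_th/w` above it.  `ψ` (default 20, fixed rather than
estimated) controls the sharpness of the switch; `ψ → ∞` gives the exact
piecewise form.  The resulting trajectory is exponential at rate
`ln(p0)/T` while `w ≪ w_th` and asymptotically linear with slope

    slope = (p0 - 1) · w_th / T,

independent of `k_in0` and `w0`.  Three parameterizations are exposed:

* `full` — estimate `p0` and `w_th` (biphasic data);
* `linear_phase` — linear-only data: `p0` and `w_th` are not separately
  identifiable, only their product `p_wth = (p0 - 1)·w_th` is (the package
  demonstrates this by the conditioning of JᵀJ);
* `constant_p` — `p ≡ p0`, with the explicit solution
  `w(t) = w0 + k_in0·T·(p0^n - 1) + k_in0·p0^n·(p0 - 1)·(t - nT)`,
  `n = INT(t/T)`, and the exponential envelope
  `w0 + k_in0·T·(p0^(t/T) - 1) ≤ w(t) ≤ w0 + k_in0·T·(p0^(t/T + 1) - 1)`.

Exponential-only growth (one of the case-study shapes) is configured by a
`w_th` sentinel far beyond the observed sizes (templates use `1e9 · w0`),
so the efficiency never leaves its plateau.

## Drug effect

The tumor splits into proliferating mass `M` and apoptotic mass `A`
(`w = M + A`); drug-damaged cells enter `A` and leave it after an
apoptosis lifespan `T_A`, which is what delays observable shrinkage after
dosing — on every fixture the onset of decline falls `T_A` days after a
dose, to within the output grid.

**Non-cycle-specific kill** (any cell-cycle stage): removal at rate
`E(C(t))·M`, with `E = k2·C` (second-order, mL/ng/day) or a saturable
`E = Emax·C/(EC50 + C)` for studies with saturating dose ranges.  Only
cells surviving exposure over their whole lifespan divide:

    dM/dt = (p(w) - 1) · k_in(t-T) · S(t) - E(C(t)) · M,
    S(t)  = exp(-∫_{max(t-T,0)}^{t} E(C(s)) ds).

**Cycle-specific kill** (only at the division instant): a fraction
`E(C(t))` (Emax form required — it must be a fraction) of the cells
reaching the end of their lifespan is shunted to the apoptotic pool instead
of dividing:

    k_in(t) = p(w) · (1 - E(C(t))) · k_in(t-T),
    dM/dt   = k_in(t) - k_in(t-T).

Because the drug only acts on the subpopulation at the division instant,
fitted `EC50` values are compensatorily far below plasma concentrations,
and dose escalation saturates: escalating the sensitivity-fixture doses
4-fold changes the nadir depth by well under 2-fold.  The residual
dose-separation comes from the kill-window duration scaling with
`ln(dose)`.  Plasma concentration at the division instant is used as
printed; no accumulation window or effect compartment is modeled.

`p` is evaluated at the total burden `w = M + A` in both mechanisms (the
apoptotic mass still occupies the tumor); an `efficiency_of_total=False`
switch evaluates it at `M` only for sensitivity checks.

## Pharmacokinetic drivers

Linear compartmental PK in closed form, superposed over dose events:
i.v. bolus mono/bi-exponentials, first-order-absorption Bateman functions
(including the degenerate `kel = ka` flip-flop limit `C ∝ t·e^(-ka t)`)
and the two-compartment absorption tri-exponential.  Doses are mg/kg,
volumes L/kg (V/F orally), so `(mg/kg)/(L/kg) → µg/mL → ×1000 ng/mL`;
no animal body weight is needed anywhere.  Rate constants quoted per hour
are converted to 1/day at construction; all model time is days.
Empirically nonlinear kinetics are handled by dose-level-specific
`{kel, V}` overrides — each dose event evolves with its own constants and
the profiles superpose.  Each profile carries the exact antiderivative of
`C`, so the survival exponent is a difference of antiderivatives rather
than a per-step quadrature (for the saturable effect form, where no closed
antiderivative of `E(C)` exists, a dense trapezoid table with dose-time
nodes is precomputed once per trajectory).

## Numerics

The DDE is solved by the method of steps: the right-hand side is
discontinuous at every multiple of `T` (jumps propagate from the constant
history junction at `t = 0`), at dose times, and at those points shifted by
`T_A`.  The integration mesh contains the closure of `{0} ∪ dose times`
under addition of the active delays, refined to at least `pps` steps per
shortest delay (default 200 for simulation; fitting uses 24–32, adequate
below the 5% observation noise).  Within each segment a classical RK4 step
is taken; lagged signals are memoized on the mesh (with midpoint samples)
as piecewise-linear polylines whose jump nodes store both one-sided limits,
so each right-hand-side evaluation costs O(1) and no step straddles a
discontinuity.  Queries at jump nodes snap within 1e-9 relative to avoid
landing on the wrong side of a breakpoint by floating-point drift.

The production recursion `k_in(t) = p(w)·k_in(t-T)` is the primary
representation; the expanded product over `INT(t/T)+1` efficiency factors
is kept as a cross-check.  The apoptotic pool is integrated via its
cumulative inflow `I` with `A(t) = I(t) - I(t - T_A)`, which is exactly the
lifespan bookkeeping (`dA/dt = inflow(t) - inflow(t - T_A)`, `A(0) = 0`)
but keeps `A ≥ 0` by construction; `M` is validated and integration aborts
on a negative state rather than clipping.  Against an independent
fixed-step Heun oracle at step `T/2000` the solver agrees to better than
1e-5 relative over 20 lifespans, and it is exact for constant `p` (the
right-hand side is then piecewise constant).

The linearized transit-compartment reference model (constant growth rate
`λ1`, second-order kill `k2·C·x1`, damage chain with rate `k1`) uses three
transit stages by default; a published variant quotes the chain's mean
residence time with numerator 4 next to a value equal to `3/k1`, so the
stage count and the MTT numerator are both configurable and the
discrepancy is surfaced rather than resolved.

## Estimation

The model output is discontinuous in `T` and `T_A` (integer lag counts),
so those are grid-searched; at each node the continuous parameters are
fitted by least squares in a transformed space (log for positive
parameters, scaled logit for interval bounds such as `p0 ∈ [1, 2]` and
`Emax ∈ [0, 1]`), with 5 seeded multi-starts by default (1–2 in the heavier
workflows) because the DDE objective surface is rugged.  Residuals are
unweighted by default, mirroring the usual regression default; proportional
weighting is available and is used in the synthetic-recovery experiments,
where the generator's noise model is proportional and the matched weighting
is the maximum-likelihood choice.  A trial point whose simulation fails
(e.g. a potency that collapses the tumor) is scored as a uniformly large
residual so the optimizer retreats instead of aborting.  Ties between
grid nodes break toward smaller `T`, then smaller `T_A`.

The standard workflow is sequential: stage 1 grids `T` and fits the growth
parameters on the control arm; stage 2 fixes those, grids `T_A` (re-gridding
`T` is optional, off by default) and fits the drug parameters jointly
across treated arms; an optional stage 3 refits all continuous parameters
on all arms with the lifespans fixed.  Precision is reported as
`CV% = 100·SE/estimate` from the asymptotic covariance `s²(JᵀJ)⁻¹` of a
central-difference Jacobian in the natural parameter space; a singular
Jacobian yields "unavailable", never a fabricated number.  No bootstrap or
population (mixed-effects) estimation is provided, and the grid search
carries no conventional confidence statement.

Default grids are configurable; the shipped examples use grids of ~5 nodes
bracketing plausible xenograft doubling times (T within 0.25–8 d) with the
0.02–0.005 d steps reserved for refinement passes, because exhaustive fine
grids dominate runtime without changing the workflow's behavior.

## Synthetic studies

`casestudy_template` returns three designs emulating published xenograft
case studies, with truth parameters set to the published fitted values as
realistic fixtures: a taxane arm (biphasic growth in grams, cycle-specific
Emax kill with `Emax` fixed at 1, two-compartment i.v. PK, 30 mg/kg every
4 days from day 8), a CK2-inhibitor study (linear-only growth in mm³,
`p_wth` parameterization, linear kill, weekly i.p. dosing at 10/20/30
mg/kg with dose-specific PK constants, observations on the thrice-weekly
clinical schedule plus a 216 h post-dose point), and a Pim-inhibitor study
(exponential-only growth, saturable non-cycle-specific kill, flip-flop
oral PK, once-daily dosing at 0.3–30 mg/kg).  Observation days not printed
in the sources are chosen to mimic 2–3 measurements per week over the
studies' horizons.

One pooled series per arm is generated (group-mean style).  Noise is
proportional by default, `y = ŵ·(1 + CV·ε) + SD·ε′` with CV = 0.05 —
tumor-volume errors scale with size, and the sources state no residual
model — with non-positive draws resampled (counts logged in the provenance
block, which together with the seed regenerates a dataset bit-identically).
The generator emulates design, truth and noise but not per-animal
heterogeneity, caliper-measurement rounding, dropout, or inter-occasion PK
variability, so recovery results bound estimator behavior under the stated
noise model only, not under real-data misspecification.

Parameter-recovery behavior (checked in the test suite): on the
taxane-like design with 5% noise, 20 replicates recover `p0` and `w_th`
to a few percent (median); `EC50` is the weakly identified parameter —
the SSR separation between neighboring `T_A` grid nodes lies below the
noise floor at this design's sampling density, so the selected node
varies across replicates and `EC50` absorbs the node error, leaving its
median error at roughly a quarter of its value.  A noiseless replicate
recovers every continuous parameter within 1% and the true lifespan grid
node exactly.  Problem sizes (5-node grids, `pps` 24–32, 1–2 multi-starts)
are chosen as the smallest configuration whose noiseless run is exact
to <1%.

## Known limitations

* Single-lifespan cohort dynamics: no cell-age structure, no mixed
  sensitive/resistant populations, no cell-cycle-phase identification.
* Plasma PK drives the effect directly — no effect compartment or
  intra-tumor gradient, hence the compensatorily low cycle-specific EC50.
* The grid search is exhaustive and dominates fitting cost; its precision
  is the grid step.
* Steady-state analysis is limited to the trivial `p = 1` stasis case.
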