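# Methods

`cachexim` simulates chemotherapy-induced cachexia — skeletal-muscle
wasting caused by the treatment itself rather than by the tumour — in a
mouse host receiving 5-fluorouracil (5-FU), and scores dosing schedules by
their joint effect on lean mass and tumour burden.  This note documents the
model, the numerical choices, and what the synthetic-data experiments do
and do not establish.

## Model

### Pharmacokinetics

Drug disposition is a standard two-compartment linear model with bolus
input.  Plasma (C1) and tissue (C2) concentrations in ug/ml obey

    dC1/dt = k21 C2 V2/V1 − (k12 + k10) C1
    dC2/dt = k12 C1 V1/V2 − k21 C2

and each dose of d mg/kg adds 1000·d/V1 ug/ml to C1 instantaneously.
Defaults (literature estimates for 5-FU in mice): k10 = 151.2/day,
k12 = 5.62/day, k21 = 2.31/day, V1 = 710 ml/kg, V2 = 100 ml/kg.  The
plasma half-life implied by k10 is ~6.6 minutes, which makes the system
stiff for general-purpose integrators; we therefore solve it exactly,
segment by segment, from the eigendecomposition of the 2×2 rate matrix,
with doses applied as exact state jumps.  The running integral of C2 is
propagated in the same closed form, so the moving-average exposure

    y_tau(t) = (1/tau) ∫_{t−tau}^{t} C2(s) ds,   C2(s < 0) = 0

is exact at any evaluation time.  The zero pre-treatment history is a
modelling choice (drug-naive tissue at treatment start); it produces the
spin-up ramp that underlies the observed onset lag of mass loss.

Morphine comedication is modelled as a permanent 35% reduction of the
three rate constants (k10, k12, k21), volumes unchanged.  This raises the
per-dose tissue exposure by ~54%.

A structural consequence worth noting: C2 — and hence everything
downstream of it — is exactly independent of V1 (C1 scales as 1/V1, the
tissue influx as V1), so lean-mass sensitivity to V1 is identically zero.

### Muscle

Healthy muscle is a two-compartment stem-cell-lineage model: satellite
(stem) cell volume S and muscle-fibre volume M (mm³).  Stem cells divide
symmetrically, self-renewing with probability p(M) = p0 + p1/(1 + M/m)
and differentiating otherwise, at proliferation rate
nu(M) = nu0 + nu1/(1 + M/m); fibres die at rate d0:

    dS/dt = (2p − 1) nu S
    dM/dt = 2(1 − p) nu S − d0 M.

Lean mass is 0.002 g/mm³ × (S + M).  With defaults (p0 = 0.479,
p1 = 0.133, nu0 = 0.087, nu1 = 5.591/day, d0 = 0.05/day, m = 1000 mm³)
the positive equilibrium is available in closed form — p(M*) = 1/2 gives
M* = m(p1/(½ − p0) − 1) = 5333.3 mm³ and S* = d0 M*/nu(M*) = 275.0 mm³ —
and is used directly; long-run integration is retained only as a test
oracle.  The equilibrium stem ratio S/M is 0.0516 (~5%).

Two host configurations are built in: a young (6-week) growing host at
(S, M) = (267.5, 4732.5) mm³ — 10 g lean mass, stem ratio 0.0565 — and an
aged (2-year) host at the equilibrium (275, 5333) mm³.  A second young
variant (268.5, 4732.5) quoted elsewhere in the source literature is
available as `YOUNG_HOST_AGING_VARIANT`; the two differ by 1 mm³ of S and
the package defaults to the former.  The discrepancy is documented, not
resolved.  Aging is additionally modelled as p1 → 0.98·p1 (decayed
stem-cell viability), which lowers the equilibrium lean mass by 2.46%.

Note the young host does not approach its equilibrium monotonically: its
starting stem ratio exceeds the homeostatic one, so lean mass overshoots
to ~11.30 g near day 55 before relaxing to 11.217 g over ~300 days (the
slow recovery eigenvalue is ≈ −0.031/day).

### Chemotherapy coupling

Chemotherapy suppresses successful proliferation and differentiation via a
cubic function of the tau-day average exposure:

    dS/dt = (1 − (y_tau/Rd)³) (2p − 1) nu S
    dM/dt = (1 − (y_tau/Rd)³) 2(1 − p) nu S − d0 M.

Rd (ug/ml) is the exposure threshold at which net turnover stalls; tau
(days) sets the memory of the exposure average.  The cubic exponent
captures the strongly nonlinear dose separation of the calibration data
(linear/quadratic shapes cannot), and the factor is deliberately **not
clamped below zero**: exposures above Rd drive net loss, which is the
regime that distinguishes the high-dose arms.  Because both division terms
are scaled symmetrically, the stem ratio is only transiently disturbed and
recovery shows no runaway overshoot.

At extreme exposures the model leaves its domain: sustained y_tau well
above Rd can drive M through zero (daily doses ≳ 48 mg/kg, beyond the
14–35 mg/kg daily arms actually tested, where 4/5 mice died at 35).  The
simulator treats a negative compartment as an integration fault and
raises rather than continuing a meaningless trajectory.

### Tumour

Tumour volume follows an exponential-linear growth law with a log-kill
term proportional to tissue concentration:

    dT/dt = mu0 T (1 + (mu0 T/mu1)^eta)^(−1/eta) − kappa C2 T

with mu0 = 0.446/day, mu1 = 116 mm³/day, eta = 20, kappa = 0.13 ml/(ug·day),
T(0) = 10 mm³.  eta only shapes the exponential-to-linear hand-off; curves
for eta ≥ 20 agree to < 2% pointwise (eta = 4, the smoothest admissible
transition, differs by up to ~6%).  The tumour is one-way coupled: it
reads C2 but feeds nothing back (no cancer-induced cachexia), so the
young/aged host distinction never changes the tumour response.

## Numerics

The solve is staged.  PK and exposure are exact (above).  The tissue stage
integrates (S, M[, T]) with LSODA at rtol 1e-8 / atol 1e-10, evaluating
y_tau(t) and C2(t) through the exact PK solution at the solver's own times
— no interpolation layer sits between the stages, so the output grid
(default 0.005 day) is purely a sampling choice and halving it changes
day-28 lean mass by well under 1e-4 g.  The default horizon is 56 days
(28 treatment + 28 observation), matching the source experiment.

The fitting and sensitivity hot paths use a second integrator: a
fixed-step classical RK4 (step 0.005 day; 0.02 day inside the grid search)
vectorised over whole (tau, Rd) parameter grids, with y_tau³ precomputed
exactly at every RK4 substage time.  Rd enters the dynamics only through
the scalar multiplier 1 − y³/Rd³, so an entire Rd grid advances in
lock-step as one array recursion.  Against the LSODA reference this path
agrees to ~1e-6 g in lean mass.  Fixed steps also make finite-difference
sensitivities clean: perturbed and nominal runs share the identical
discretisation, so adaptive-stepping noise cannot contaminate a 1e-5
relative difference.

## Parameter fitting

Rd and tau are the only fitted parameters; everything else is taken from
prior literature estimates (kappa was chosen, not fitted, so that some
standard schedules clearly control the tumour).  The cost is the total sum
of squared deviations (g²) between each non-zero dose arm and its model
prediction — all doses fit at once; the control arm is excluded.  The
search is hybrid: integer tau swept over a window (1–15 by default), and
for each tau a two-stage grid search on Rd (coarse 0.05 ug/ml over
[1, 20], then 0.01 around the coarse minimum; ties break toward smaller
Rd, boundary minima raise a warning).  The bounds and steps bracket the
published per-family fits (6.18 and 7.86 ug/ml) with margin and make them
representable on the fine grid.  Model predictions are interpolated
linearly from a 0.1-day output grid to the observation days; PK/exposure
stages are cached per (schedule, dose, tau) since Rd does not affect them.

Global parameters combine two family fits: tau* is the midpoint of the two
per-family argmin tau values (half-integer midpoints round toward the
daily-family argmin — an arbitrary, documented choice, flagged in the
result), and Rd* is the mean of the two families' best Rd at tau*.  The
published analysis reports per-family optima (tau = 11, Rd = 6.18 daily;
tau = 5, Rd = 7.86 for 5-on/2-off) and global values (tau = 8, Rd = 6.8);
those numbers require the digitized experimental curves, which were never
deposited, so they serve here as documented references rather than test
assertions.  What is asserted instead is end-to-end recovery on synthetic
data (below).

## Synthetic data

The generator reproduces the *structure* of the calibration data: per-arm
mean lean-mass series for a daily family (0, 14, 17, 20, 24, 29, 35 mg/kg)
and a 5-on/2-off family (0, 24, 35, 42, 50, 60 mg/kg), observed every
2 days over 56 days, from a host starting at 25 g body weight × 40% lean
composition = 10 g lean mass.  Arms are simulated at known (tau, Rd) —
(8, 6.8) by default — and independent Gaussian noise (default sd 0.2 g;
the source provides no error model, so the level is configurable and the
recovery experiments sweep it) is added on top.  Generation is
deterministic in the seed, and datasets round-trip exactly through the
long-format CSV schema (family, dose_mg_per_kg, day, lean_mass_g,
replicate).

What passing recovery tests show: the pipeline identifies (tau, Rd) to
±1 day / ±0.3 ug/ml from data whose noise, cadence and dose design mimic
the source experiment, in ≥ 90% of seeded replicates.  What they do not
show: anything about digitization artifacts, between-animal variance,
or the informativeness of the *real* curves — the synthetic arms are
means from the model's own family, so recovery is a consistency check of
the estimation machinery, not external validation.  Recovery experiments
sweep tau over a ±4-day window around the generating value (a problem-size
choice; the profile is steep and unimodal there).

## Sensitivity analysis

Dynamic (time-resolved) local sensitivities of lean mass, by one-sided
finite differences with relative step eps = 1e-5 on a daily output grid;
the relative coefficient S_rel = S·rho/LM is reported alongside.  The
minus direction uses the backward difference so both directions estimate
the same derivative (they agree to < 0.5% where the coefficient is
non-negligible, and to < 1% against a central-difference check at
eps = 1e-6).  tau is perturbed continuously — the moving average is well
defined for non-integer windows — even though fitting restricts tau to
integers.  Tumour-only parameters are excluded from the all-parameter scan
by construction (one-way coupling; the kappa series is identically zero).

Two findings from this implementation's scan under 35 mg/kg daily dosing:
p0 dominates every other parameter (peak |S_rel| ≈ 23 — it shifts the
equilibrium itself), and the four exposure-scaling PK parameters
(k10, k12, k21, V2) are nearly degenerate (within 0.2% of each other,
peak |S_rel| ≈ 1.56, the same as Rd) because each rescales y_tau by a
power of ±1.  Sensitivities of equilibrium-shifting parameters (p0, p1, m)
do not decay after treatment — they tend to the log-derivative of the
equilibrium — whereas the treatment-coupling coefficients (Rd, tau) decay
on the ~1/d0 recovery timescale.

## Efficacy metrics

Treatment effects are normalised by each trajectory's own initial values
(the quantities known at clinical presentation), not by an untreated
control: lean_fraction = LM(t)/LM(0), tumour_fraction = T(t)/T(0), and the
instantaneous therapeutic efficacy is their ratio.  A schedule's score
against a reference (conventionally 24 mg/kg daily, the most lean-sparing
standard) uses trapezoidal AUCs of the normalised curves over an explicit
window — [0, 56] days by default, covering both loss and recovery; the
window is a required argument precisely because the choice is not forced:

    total_te = [AUC_lean / AUC_lean,ref] / [AUC_tumour / AUC_tumour,ref].

Normalised (rather than raw) curves are integrated; the ratios coincide
when initial values match.  Higher is better; the metric carries **no
toxicity penalty**, so high-dose schedules that would not be tolerated in
vivo can still score well.  A control-relative lean-mass deficit is
provided as a separate diagnostic for the aging comparisons.

## Schedules

Schedules are finite explicit event lists (time in days, dose in mg/kg),
so the simulator's event handling is family-agnostic.  Builders cover
daily, k-on/j-off cycles, arbitrary weekly on/off patterns, every-other-day
and metronomic (1–6 equal doses/day at fixed weekly total; intraday times
are k/n of a day from the day's start — the source says only "equally
spaced").  Day indexing is 0-based with treatment start at t = 0; weekly
patterns quoted 1-based elsewhere map day 1 to offset 0.  Built-in suites
reproduce the standard-weekly-dose table (168–175 mg/kg/week), the weekly
pattern table, metronomic and maximum-tolerated-dose (168 weekly /
336 biweekly / 672 monthly) comparisons, and the aging and morphine
scenario pairs.  The biweekly/monthly MTD doses are constructed to deliver
the same 672 mg/kg four-week total; the source describes them only as
weekly/biweekly/monthly high-dose equivalents.

## Known limitations

- No toxicity or mortality model: high-dose arms that killed animals in
  the source experiment are simulated as if survivable, and the efficacy
  metric will happily rank them.
- The muscle model loses meaning (M → 0) under sustained exposure far
  above Rd; the simulator faults rather than extrapolating.
- One mean trajectory per arm; no between-animal variability, immune
  compartment, or host–tumour interaction.
- The fitted-parameter references (6.18/7.86 ug/ml, 11/5 days) cannot be
  reproduced without the undeposited digitized dataset; the package's
  claims about the fitting pipeline rest on synthetic-data recovery.
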