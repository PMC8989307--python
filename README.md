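# cachexim

Modelling chemotherapy-induced cachexia and dose scheduling.

Certain chemotherapy agents — 5-fluorouracil (5-FU) among them — cause
loss of skeletal muscle (cachexia) as an off-target effect, with a
strongly *nonlinear* dose dependence: in mice, daily doses up to
~20 mg/kg track the untreated controls while 35 mg/kg causes severe,
accelerating loss.  `cachexim` is a small systems-pharmacology package
for exploring that trade-off.  It couples three stages:

1. **Pharmacokinetics** — a two-compartment linear model for plasma and
   tissue 5-FU concentration under bolus dosing, solved exactly
   (piecewise matrix exponential), with the τ-day moving-average tissue
   exposure y_τ(t) = (1/τ)∫ₜ₋τᵗ C₂(s) ds derived in closed form.
2. **Muscle** — a stem-cell-lineage model of muscle tissue (satellite
   cells S, fibres M, both mm³; lean mass = 0.002(S+M) g) in which
   chemotherapy suppresses successful proliferation and differentiation
   through a cubic pharmacodynamic factor 1 − (y_τ/R_d)³.
3. **Tumour** — an exponential-linear growth law with log-kill
   proportional to tissue concentration, one-way coupled.

On top of the simulator it provides the pieces a modelling study needs:
schedule builders (daily, k-on/j-off, weekly patterns, every-other-day,
metronomic, MTD), grid-search estimation of the two pharmacodynamic
parameters (R_d, τ) from multi-dose lean-mass data, dynamic parameter
sensitivities, AUC-based therapeutic-efficacy scores against a reference
regimen, a synthetic dose-response data generator for end-to-end
parameter-recovery experiments, and a CLI.  Intended users: modellers in
PK/PD and mathematical oncology who want a tested, reproducible baseline
implementation of this class of model.

See `docs/methods.md` for the model equations, default parameters,
numerical scheme and known limitations.

## Worked example

Score the classic week-day schedule (35 mg/kg, 5-on/2-off) against the
standard daily regimen (24 mg/kg × 28 days) on a young growing host with
a 10 mm³ tumour:

```python
from cachexim import (Scenario, TumourParams, make_cycle, make_daily,
                      run, scores)

daily    = Scenario(schedule=make_daily(24),      tp=TumourParams())
five_two = Scenario(schedule=make_cycle(5, 2, 35), tp=TumourParams())
ref, treated = run(daily), run(five_two)

d28 = treated.at_day(28.0)
print(f"day 28: lean mass {d28['lean']:.2f} g, tumour {d28['T']:.2f} mm3, "
      f"stem ratio {d28['stem_ratio']:.4f}")
s = scores(treated, ref, window=(0.0, 56.0),
           label="5on2off:35", reference_label="daily:24")
print(f"lean AUC ratio   {s.lean_auc_ratio:.4f}")
print(f"tumour AUC ratio {s.tumour_auc_ratio:.4f}")
print(f"total TE         {s.total_te:.4f}")
```

prints

```
day 28: lean mass 10.18 g, tumour 1.16 mm3, stem ratio 0.0613
lean AUC ratio   0.9950
tumour AUC ratio 0.8688
total TE         1.1452
```

Reading: at the end of treatment the host still carries ~10.2 g of lean
mass (the untreated control has grown to ~11.2 g — roughly a 10% deficit)
and the stem-cell ratio is transiently elevated above its ~5% homeostatic
value as the feedback replenishes lost fibres.  Relative to the daily
reference over the full 56-day window, the 5-on/2-off schedule preserves
slightly *less* lean mass (lean AUC ratio 0.995 < 1) but controls the
tumour much better (tumour AUC ratio 0.869; its minimum volume is
0.49 mm³ vs 2.01 mm³ under daily dosing), for a total therapeutic
efficacy of 1.145 — better overall than the daily standard, with the
usual caveat that the score carries no toxicity penalty.

The same computation from the shell:

```
cachexim efficacy --schedule 5on2off:35 --out scores.csv
cachexim suite table2 --outdir out/table2      # the full weekly-standard table
cachexim synth --family both --seed 1 --out data.csv
cachexim fit --data data.csv --out fits       # grid search (R_d, tau) per family
cachexim sensitivity --schedule daily:35 --param Rd --out sens.csv
```

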