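# ecusim — individualized eculizumab dosing simulation for aHUS

Eculizumab, an anti-C5 monoclonal antibody, is a lifesaving but extremely
expensive treatment for atypical haemolytic uraemic syndrome (aHUS).  The
label prescribes a fixed weight-banded schedule that is often suboptimal
early in therapy and supratherapeutic later on.  `ecusim` is a population
pharmacokinetic–pharmacodynamic (PK–PD) simulation package for exploring
alternative eculizumab dosing strategies in silico and for forecasting
individual exposure from sparse therapeutic-drug-monitoring (TDM) data.

It is aimed at clinical pharmacologists and pharmacometricians who want to

* regenerate the published virtual-trial endpoints (target-attainment
  percentages and drug costs) for the standard, weight-based-loading,
  trough-guided (TDM) and fixed 4-week regimens, and
* reuse the model as a building block for model-informed precision dosing
  (individual MAP estimation and trough forecasting).

## The model

**PK.**  One compartment with parallel first-order and Michaelis–Menten
(target-mediated) elimination of the drug amount *A* (mg):

    dA/dt = input(t) − (CL/V)·A − Vmax·C/(Km + C),   C = A/V

with population estimates (70-kg reference subject) CL = 0.163 L/day,
V = 6.42 L, Vmax = 29.6 mg/day, Km = 37.9 mg/L.  Body weight scales CL and
Vmax allometrically (exponent 0.75) and V proportionally (exponent 1.0).
Between-subject variability is lognormal (CL 43.4% CV, V 37.1% CV) with
inter-occasion variability on CL (34.4% CV), one occasion per dosing
interval.

**PD.**  Classical complement pathway (CP) activity *E* (% of normal sera)
follows an inhibitory sigmoid Emax model of the free concentration *C*:

    E = Base · (1 − Imax·C^γ / (IC50^γ + C^γ))

with Base = 100.7%, Imax = 0.96, IC50 = 22.0 mg/L, γ = 5.42 (IIV on Base
23% CV and IC50 38.5% CV).  CP activity < 10% defines complete complement
blockade, the efficacy target; for the typical subject the target is met
above ≈ 36.3 mg/L.

**Virtual trials.**  A 2000-subject virtual cohort (ages 1–79, 48% female,
median weight 61.6 kg) is generated from printed survey summaries, dosed
according to weight-band tables (label regimen, single weight-based
loading dose, trough-guided individualization, fixed 4-week interval), and
simulated with a vectorized Runge–Kutta integrator.  Endpoints: fraction
of subjects with CP < 10% over time, realized interval/dose classes under
TDM, and vial-based drug costs (300-mg vials at US$6523).

## Worked example

```python
import numpy as np
from ecusim import *

# typical 70-kg subject, weight-based loading strategy (1800 mg day 1,
# 1200 mg on day 15, then 1200 mg every 14 days)
ind = IndividualParameters(subject_id=0, cl_i=0.163, v_i=6.42, vmax_i=29.6,
                           km_i=37.9, base_i=100.7, ic50_i=22.0,
                           gamma_i=5.42, imax_i=0.96)
reg = alternative_loading_regimen(70.0, horizon=28.0)
times = np.arange(0.0, 28.1, 0.1)
prof = solve_concentration_profile(ind, reg.dose_events, times)
tr = trough_before(prof, 14.0)
print(f"trough before 2nd dose: {tr:.1f} mg/L")
print(f"CP activity at that trough: {predict_cp_activity(ind, tr):.2f} %")
print(f"target threshold concentration: {cp_threshold_concentration(ind):.1f} mg/L")

# a small Monte Carlo trial of the same strategy
cohort = generate_cohort(200, rng_seed=1)
res = run_trial(TrialSpec(cohort=cohort, strategy="alt_loading",
                          study="loading", horizon=28.0, seed=1))
print(f"day-7 attainment: {100*attainment_at(res, 6.0):.1f} %")
print(f"mean 28-day drug cost: ${mean_cost(res, 'first28d'):,.0f}")
```

prints

```
trough before 2nd dose: 150.8 mg/L
CP activity at that trough: 4.03 %
target threshold concentration: 36.3 mg/L
day-7 attainment: 100.0 %
mean 28-day drug cost: $76,874
```

The typical subject's trough two weeks after the loading dose (150.8 mg/L)
sits far above the 36.3 mg/L threshold, so complement stays fully blocked
(CP 4.03%, effectively the Emax floor); in the 200-subject trial every
subject is below 10% CP activity on day 7, at a mean first-month drug
cost of about $77k per patient.

A command-line interface wraps the same machinery:

```
ecusim simulate --strategy alt-loading --n 2000 --seed 1 --out out/
ecusim compare-methods pairs.csv
ecusim fit --doses doses.csv --obs obs.csv --weight 70 --next-dose-time 42
ecusim cohort --n 2000 --seed 1 --out cohort.csv
```

`simulate` writes the attainment curve (CSV + PNG), per-subject costs and
an endpoint summary (`outcomes.json`); every output carries the seed and a
configuration hash so runs are byte-for-byte reproducible.

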