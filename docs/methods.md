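# Methods

## Structural PK model

Free eculizumab is described by a single well-stirred compartment with
parallel linear and saturable elimination of the drug amount A (mg):

    dA/dt = input(t) − (CL_occ/V)·A − Vmax·A/(Km·V + A),   C = A/V

The saturable (Michaelis–Menten) pathway represents target-mediated
disposition: binding to C5 and elimination of the complex.  Doses are
intravenous boluses by default — infusion times on the label (< 1 h) are
negligible against 7–28-day dosing intervals — but the reference solver
also supports zero-order infusions of finite duration.

Population parameters (typical 70-kg subject):

| parameter | meaning | default | unit |
|---|---|---|---|
| CL | linear clearance | 0.163 | L/day |
| V | volume of distribution | 6.42 | L |
| Vmax | maximal saturable elimination rate | 29.6 | mg/day |
| Km | concentration at half-maximal rate | 37.9 | mg/L |

Body weight is the only covariate: CL and Vmax scale as (W/70)^0.75 and V
as (W/70)^1.0, the standard theory-based allometric exponents.  The
exponents are configuration fields so alternative covariate models can be
explored.  Km carries no covariate.

## Variability and residual error

Between-subject variability (IIV) is multiplicative lognormal,
parameterized from the reported CV%: ω² = ln(1 + CV²).  IIV acts on CL
(43.4%), V (37.1%), Base (23%) and IC50 (38.5%).  Inter-occasion
variability (34.4% CV) applies to CL only, with an "occasion" defined as
the interval beginning at each administration.  Random effects are
mutually independent (no correlations are reported) and Vmax, Km, Imax
and γ carry no variability.

Residual errors: PK observations have a combined error
obs = pred·(1+εp) + εa with assay-specific proportional terms
(Radboudumc 0.0247, Sanquin 0.248) and additive SD 4.33 mg/L; PD
observations have a proportional error (0.089).  The printed proportional
terms are interpreted as variances σ² (the common mixed-effects reporting
convention); a flag switches to the SD interpretation.  Negative draws
are truncated at zero.

## PD model and target attainment

CP activity follows the inhibitory sigmoid Emax model
E = Base·(1 − Imax·C^γ/(IC50^γ + C^γ)) with Base 100.7%, Imax 0.96,
IC50 22.0 mg/L, γ 5.42.  The efficacy target is complete complement
blockade, CP < 10%.  Because E is strictly decreasing in C, attainment is
evaluated by inverting the relation once per subject: the individual
threshold concentration is IC50_i·(x/(1−x))^(1/γ) with
x = (1 − 10/Base_i)/Imax (36.3 mg/L for the typical subject).  Subjects
whose Emax floor Base_i·(1−Imax) exceeds 10% can never attain the target;
subjects whose baseline is already below 10% always do.  Attainment uses
error-free individual predictions (no residual noise): the smoothness of
the published attainment curves and the 99.95% figure at n = 2000 imply
model-prediction-based classification.  A noise mode exists for trough
measurement in the TDM policy (off by default).

## Virtual population

The simulation cohort emulates the survey-derived population reported
only through printed summaries (2000 subjects, ages 1–79, 48% female,
median age 24.8 y, median weight 61.6 kg, range 8.3–155.6, median height
159 cm).  Age is a two-stratum mixture — children uniform on [1, 18) with
mixing weight 0.437, adults uniform on [18, 79] — which places the median
at ≈ 24.8 y.  Weight and height are age- and sex-conditional lognormals
around growth-curve median anchors (ages 1–79, log-linear interpolation;
adult sex multipliers 1.08/0.92 for weight ramped in over ages 12–18)
with spread CV 20% (adults) / 15% (children) for weight and 4% for
height, truncated to the printed ranges.

What this emulator does *not* reproduce: the joint age–weight–height
covariance of the real survey, its obesity right tail, and any sampling
weights.  Passing cohort tests therefore show that the marginal medians
and ranges match the printed summaries — not that endpoint values
conditional on the within-band weight distribution are exact.  This
matters: the loading-dose weight bands make per-band exposure depend on
where subjects sit inside a band, so band-edge-sensitive endpoints (the
TDM interval-extension classes, and to a lesser degree every attainment
percentage) inherit a 2–7 pp sensitivity to the emulated weight
distribution.  In our runs attainment endpoints sit ~2 pp above, and the
3-week extension class ~6 pp above, the published values, consistent with
an under-weighted heavy tail.

## Dosing regimens

Printed day *d* maps to simulation time t = d − 1 (first dose at t = 0).
Weight bands are half-open [lo, hi); band boundaries such as 40.0 kg
belong to the upper band.  All doses are multiples of the 300-mg vial.

* **Standard (label)**: weekly induction, then fixed maintenance every
  14 days (every 21 days in the 5–10 kg band); adults: 900 mg weekly ×4,
  then 1200 mg q14d from day 29.
* **Alternative loading**: one weight-banded loading dose on day 1
  (300–2400 mg), the band's maintenance dose on day 15, then standard
  maintenance dosing.  For adults this means 3 instead of 5 infusions in
  the first 28 days.
* **Fixed 4-week interval**: weight-banded maintenance dose (900–3000 mg)
  every 28 days.

Costs are counted in whole vials at US$6523 per 300-mg vial.  Yearly
maintenance cost uses fractional annualization (365.25/interval) ×
vial cost of the maintenance dose, which compares 14/21/28-day intervals
smoothly; first-28-day cost sums doses at t ∈ [0, 28] inclusive (adults:
16 vials standard vs 14 alternative, a 12.5% saving).

## Trough-guided (TDM) policy

The individualized strategy is the loading-dose regimen followed by
PK-guided maintenance: troughs are measured immediately before the 2nd
dose (day 15, t = 14) and before the 3rd dose (one maintenance interval
later), and at each checkpoint the regimen is adjusted — trough below
100 mg/L (2nd dose) / 50 mg/L (3rd dose): dose +300 mg; trough ≥
200 mg/L: interval +7 days (cap 28 days); otherwise unchanged.  After
the second checkpoint the regimen is frozen.

Anchoring the checkpoints on the loading-dose course is a deliberate
design choice.  The two obvious alternatives fail on their own terms:
starting maintenance cold (trough₁ = 89 mg/L for the typical subject)
would dose-increase half the cohort, and measuring after the full label
induction (trough₁ = 284 mg/L) would interval-extend almost everyone —
both contradict the intended behaviour that the typical subject's troughs
(150.8 and 189.5 mg/L) fall in the "unchanged" bands and that only about
a third of subjects earn an extension.  The policy's intent is precisely
"a weight-based loading dose followed by PK-guided dosing".

Open choices exposed in configuration: whether troughs are measured with
assay noise (default: error-free model predictions), and the interval
cap.  Dose increases may occur at both checkpoints (+600 mg total).

## Trial engine and problem sizes

Loading studies simulate t ∈ [0, 28] days on a 0.1-day grid; "day 7"
endpoints are evaluated at t = 6 (pre-dose where a dose falls on t = 7;
an alternative t = 7 evaluation only differs in the standard arm's
pre-dose value).  Maintenance studies run the full course through a
run-in of 10 maintenance intervals after the last regimen change, then
evaluate a 365-day steady-state window per subject: time-averaged
fraction of time in target (attainment), troughs at maintenance dose
times (trough bands), realized final dose/interval (TDM classes), and
annualized costs.  The 4-week strategy is evaluated at weekly checkpoints
across a steady-state interval; its 4-week value is the pre-dose point.
Default problem size is the full 2000-subject cohort; the longest
horizon (TDM with a 28-day realized interval) is ≈ 730 days.  These sizes
run in seconds thanks to the vectorized integrator.

## Numerics

* Batch integrator: classical RK4 stepping directly on the 0.1-day output
  grid, vectorized across subjects; dose events are instantaneous amount
  additions between steps, and the stored value at a dose instant is the
  pre-dose left limit (so troughs are read directly off the grid).  The
  sub-step count is chosen automatically so k·h ≤ 0.2 for the stiffest
  subject; at typical parameters (k ≈ 0.03–0.1/day) one step suffices and
  the local truncation error is far below 1e-9.
* Reference solver: piecewise LSODA between dose events at
  rtol = atol = 1e-10.  The two solvers agree to < 0.1% (asserted in
  tests, measured ~1e-9 relative); the linear-elimination limit matches
  the closed-form bolus superposition to < 1e-6 relative.
* Negative states are clipped at zero (the drift vanishes at A = 0, so
  clipping only removes sub-epsilon round-off excursions).
* MAP estimation: quasi-Newton (L-BFGS-B) on η = (η_CL, η_V) with bounds
  ±4ω and multi-start from 0 and ±1ω; objective tolerance 1e-10.  The
  residual variance is anchored on the *observed* value
  (σ²prop·obs² + σ²add), the usual dose-individualization convention;
  with prediction-anchored variance the log-variance term biases even
  noiseless recovery by several percent.  Predictions inside the
  objective use the batch integrator on a 0.25-day grid (observation
  times must sit on that grid).  Expected behaviour, verified in tests:
  a known η_CL is recovered within 2% from six noiseless troughs; with
  the ~16% proportional assay error, prior shrinkage leaves a
  several-percent median per-subject bias even under a rich 8-sample
  design spanning four dosing intervals — an inherent property of MAP
  estimates, not an optimizer failure.  Trough-only designs shrink η_V
  much harder than rich designs (no peak information).
* Passing–Bablok regression follows the original rank-based procedure:
  pairwise slopes with slopes equal to −1 discarded, offset median with
  K = #(slopes < −1), distribution-free CIs; ties at identical points are
  dropped.  Scale equivariance and agreement with a brute-force O(n²)
  oracle are asserted in tests.

## Known limitations

* The cohort emulator reproduces printed marginals only (see above); TDM
  outcome classes are the most sensitive endpoints, off by up to ~7 pp.
* The exact covariate functional form of the original model (estimated
  vs fixed exponents, possible covariates on Vmax/Km) is not public;
  fixed allometry is assumed.
* No mechanistic C5 turnover: target-mediated elimination is collapsed
  into the Michaelis–Menten term, so acute-phase variation in target load
  appears only as inter-occasion variability.
* The TDM policy adjusts at two checkpoints only and then freezes, per
  the studied strategy; continuous Bayesian re-dosing is out of scope
  (the MAP primitive exists for building one).
* Costs cover drug acquisition only (whole vials); administration and
  outpatient costs are excluded.
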