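"""Monte Carlo virtual-trial engine.

Simulates a virtual cohort under a dosing strategy and computes the
trial endpoints: the fraction of subjects with complete complement
blockade (CP activity < 10%) over time, steady-state maintenance
attainment, trough-band fractions, realized TDM interval/dose classes,
and vial-based drug costs.

Strategies
----------
standard
    Approved label regimen.  With ``study="loading"`` the first weeks of
    therapy are simulated; with ``study="maintenance"`` the full course is
    run through a 10-interval post-induction run-in and endpoints are
    evaluated over the following steady-state year.
alt_loading
    Single weight-banded loading dose, maintenance dose on day 15, then
    standard maintenance dosing (loading study).
tdm
    The individualized course: alternative loading dose followed by
    PK-guided maintenance dosing with trough checkpoints before the 2nd
    and 3rd dose; the post-checkpoint regimen is held and evaluated over a
    steady-state year after a 10-interval run-in (maintenance study).
q4w
    Fixed 4-week-interval maintenance regimen, evaluated at steady state.

Target-attainment classification uses error-free individual predictions
of CP activity: a subject attains the target at time t iff their
concentration exceeds the individual threshold concentration obtained by
inverting the Emax relation at 10% CP activity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .parameters import (PopulationModel, apply_residual_error,
                         sample_individual, subject_rng)
from .pk import simulate_batch
from .regimens import (ALT_LOADING_TABLE, Q4W_TABLE, alternative_loading_regimen,
                       annualize_cost, maintenance_spec, standard_regimen,
                       vial_cost)
from .tdm import adjust

__all__ = ["TrialSpec", "TrialResult", "run_trial", "attainment_at",
           "extension_fractions", "trough_band_fraction", "mean_cost"]

RUN_IN_INTERVALS = 10
EVAL_YEAR_DAYS = 365.0


@dataclass
class TrialSpec:
    """Specification of one virtual trial."""

    cohort: Sequence                  # VirtualSubject sequence
    strategy: str                     # standard | alt_loading | tdm | q4w
    study: str = "loading"            # loading | maintenance
    horizon: float = 28.0             # loading-study horizon, days
    dt: float = 0.1                   # simulation/evaluation grid, days
    threshold: float = 10.0           # CP activity efficacy target, %
    seed: int = 0
    run_in_intervals: int = RUN_IN_INTERVALS
    measure_trough_with_error: bool = False
    model: PopulationModel = field(default_factory=PopulationModel)

    def __post_init__(self) -> None:
        if self.strategy not in ("standard", "alt_loading", "tdm", "q4w"):
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if self.strategy in ("tdm", "q4w"):
            self.study = "maintenance"
        if not 0 < self.threshold < 100:
            raise ValueError("threshold must lie in (0, 100)")
        if self.study == "loading" and self.horizon < 28:
            raise ValueError("loading studies need horizon >= 28 days")


@dataclass
class TrialResult:
    """Endpoints of one virtual trial (one row per subject where per-subject)."""

    strategy: str
    study: str
    seed: int
    threshold: float
    times: np.ndarray                 # simulation grid, days
    attainment_curve: np.ndarray      # fraction of cohort below threshold
    ss_attainment: np.ndarray | None  # per-subject time-in-target, steady year
    troughs: list | None              # per-subject maintenance troughs (windows)
    final_dose: np.ndarray | None     # tdm: realized maintenance dose, mg
    final_interval: np.ndarray | None  # tdm: realized interval, days
    first28_cost: np.ndarray          # per-subject cost of doses in [0, 28] d
    annual_cost: np.ndarray | None    # per-subject yearly maintenance cost
    n_subjects: int = 0

    def __post_init__(self) -> None:
        self.n_subjects = len(self.first28_cost)


def _threshold_conc(model: PopulationModel, base_i, ic50_i, threshold):
    """Per-subject concentration at which CP activity crosses ``threshold``.

    inf where the Emax asymptote stays above the threshold (target
    unreachable); 0 where the baseline is already below it.
    """
    base_i = np.asarray(base_i, float)
    ic50_i = np.asarray(ic50_i, float)
    imax, gamma = model.pd.imax, model.pd.gamma
    x = (1.0 - threshold / base_i) / imax
    thr = np.full_like(base_i, np.inf)
    reachable = x < 1.0
    with np.errstate(divide="ignore", invalid="ignore"):
        thr[reachable] = (ic50_i[reachable]
                          * (x[reachable] / (1.0 - x[reachable]))
                          ** (1.0 / gamma))
    thr[base_i <= threshold] = 0.0
    return thr


def _attains(conc, thr):
    """Boolean attainment matrix; a zero threshold (baseline already below
    the target) attains at any concentration."""
    return (conc > thr[:, None]) | (thr[:, None] <= 0.0)


def _events_array(regimen_events) -> np.ndarray:
    return np.array([[d.time, d.amount] for d in regimen_events], float)


def _sample_cohort(spec: TrialSpec, n_occasions: int):
    pars = {k: np.empty(len(spec.cohort)) for k in
            ("cl", "v", "vmax", "km", "base", "ic50")}
    occ = np.empty((len(spec.cohort), n_occasions))
    for i, subj in enumerate(spec.cohort):
        ind = sample_individual(spec.model.pk, spec.model.pd, subj,
                                n_occasions=n_occasions,
                                rng_seed=subject_rng(spec.seed, i))
        pars["cl"][i] = ind.cl_i
        pars["v"][i] = ind.v_i
        pars["vmax"][i] = ind.vmax_i
        pars["km"][i] = ind.km_i
        pars["base"][i] = ind.base_i
        pars["ic50"][i] = ind.ic50_i
        occ[i] = ind.occasion_cl_multipliers
    return pars, occ


def run_trial(spec: TrialSpec) -> TrialResult:
    """Run the Monte Carlo virtual trial described by ``spec``."""
    n = len(spec.cohort)
    weights = np.array([s.weight for s in spec.cohort])
    dt = spec.dt

    if spec.study == "loading":
        horizon = float(spec.horizon)
        n_occ = int(horizon / 7) + 3
        pars, occ = _sample_cohort(spec, n_occ)
        builder = (standard_regimen if spec.strategy == "standard"
                   else alternative_loading_regimen)
        regs = [builder(w, horizon) for w in weights]
        schedules = [_events_array(r.dose_events) for r in regs]
        times, conc = simulate_batch(pars["cl"], pars["v"], pars["vmax"],
                                     pars["km"], occ, schedules, horizon, dt)
        thr = _threshold_conc(spec.model, pars["base"], pars["ic50"],
                              spec.threshold)
        below = _attains(conc, thr)
        first28 = np.array([vial_cost(r.total_mg(28.0)) for r in regs], float)
        annual = np.array([annualize_cost(r.maintenance_dose,
                                          r.maintenance_interval)
                           for r in regs])
        return TrialResult(strategy=spec.strategy, study="loading",
                           seed=spec.seed, threshold=spec.threshold,
                           times=times,
                           attainment_curve=below.mean(axis=0),
                           ss_attainment=None, troughs=None,
                           final_dose=None, final_interval=None,
                           first28_cost=first28, annual_cost=annual)

    # ---- maintenance studies -------------------------------------------
    if spec.strategy == "standard":
        return _run_standard_maintenance(spec, weights)
    if spec.strategy == "q4w":
        return _run_q4w(spec, weights)
    if spec.strategy == "tdm":
        return _run_tdm(spec, weights)
    raise ValueError(f"strategy {spec.strategy!r} has no maintenance study")


def _window_metrics(times, conc, thr, windows, dose_times_per_subj):
    """Per-subject time-in-target and maintenance troughs in the windows."""
    n = conc.shape[0]
    ss = np.empty(n)
    troughs = []
    dt = times[1] - times[0]
    for i in range(n):
        w0, w1 = windows[i]
        j0, j1 = int(round(w0 / dt)), int(round(w1 / dt))
        below = conc[i, j0:j1 + 1] > thr[i]
        ss[i] = below.mean()
        dts = dose_times_per_subj[i]
        dts = dts[(dts >= w0) & (dts <= w1)]
        idx = np.round(dts / dt).astype(int)
        troughs.append(conc[i, idx])
    return ss, troughs


def _run_standard_maintenance(spec: TrialSpec, weights):
    n = len(weights)
    m_dose = np.empty(n)
    m_int = np.empty(n)
    m_start = np.empty(n)
    for i, w in enumerate(weights):
        m_dose[i], m_int[i], m_start[i] = maintenance_spec(w)
    win0 = m_start + spec.run_in_intervals * m_int
    win1 = win0 + EVAL_YEAR_DAYS
    horizon = float(win1.max())
    n_occ = int(horizon / 7) + 3
    pars, occ = _sample_cohort(spec, n_occ)
    regs = [standard_regimen(w, horizon) for w in weights]
    schedules = [_events_array(r.dose_events) for r in regs]
    times, conc = simulate_batch(pars["cl"], pars["v"], pars["vmax"],
                                 pars["km"], occ, schedules, horizon, spec.dt)
    thr = _threshold_conc(spec.model, pars["base"], pars["ic50"],
                          spec.threshold)
    below = _attains(conc, thr)
    maint_times = [sched[:, 0][sched[:, 0] >= m_start[i]]
                   for i, sched in enumerate(schedules)]
    ss, troughs = _window_metrics(times, conc, thr,
                                  np.column_stack([win0, win1]), maint_times)
    first28 = np.array([vial_cost(r.total_mg(28.0)) for r in regs], float)
    annual = np.array([annualize_cost(d, iv) for d, iv in zip(m_dose, m_int)])
    return TrialResult(strategy="standard", study="maintenance",
                       seed=spec.seed, threshold=spec.threshold, times=times,
                       attainment_curve=below.mean(axis=0),
                       ss_attainment=ss, troughs=troughs,
                       final_dose=m_dose, final_interval=m_int,
                       first28_cost=first28, annual_cost=annual)


def _run_q4w(spec: TrialSpec, weights):
    n = len(weights)
    doses = np.array([float(Q4W_TABLE.lookup(w)["dose"]) for w in weights])
    win0 = np.full(n, spec.run_in_intervals * 28.0)
    win1 = win0 + EVAL_YEAR_DAYS
    horizon = float(win1.max()) + 28.0
    n_occ = int(horizon / 28) + 3
    pars, occ = _sample_cohort(spec, n_occ)
    dose_times = np.arange(0.0, horizon + 1e-9, 28.0)
    schedules = [np.column_stack([dose_times, np.full_like(dose_times, d)])
                 for d in doses]
    times, conc = simulate_batch(pars["cl"], pars["v"], pars["vmax"],
                                 pars["km"], occ, schedules, horizon, spec.dt)
    thr = _threshold_conc(spec.model, pars["base"], pars["ic50"],
                          spec.threshold)
    below = _attains(conc, thr)
    maint_times = [dose_times[dose_times > 0]] * n
    ss, troughs = _window_metrics(times, conc, thr,
                                  np.column_stack([win0, win1]), maint_times)
    first28 = np.array([vial_cost(2 * d) for d in doses], float)  # 2 doses <= 28 d
    annual = np.array([annualize_cost(d, 28.0) for d in doses])
    return TrialResult(strategy="q4w", study="maintenance",
                       seed=spec.seed, threshold=spec.threshold, times=times,
                       attainment_curve=below.mean(axis=0),
                       ss_attainment=ss, troughs=troughs,
                       final_dose=doses, final_interval=np.full(n, 28.0),
                       first28_cost=first28, annual_cost=annual)


def _run_tdm(spec: TrialSpec, weights):
    n = len(weights)
    loads = np.array([float(ALT_LOADING_TABLE.lookup(w)["load"])
                      for w in weights])
    m_dose = np.empty(n)
    m_int = np.empty(n)
    for i, w in enumerate(weights):
        m_dose[i], m_int[i], _ = maintenance_spec(w)

    # conservative upper bound on administrations (weekly) for IOV sampling
    horizon_bound = 14 + 28 + spec.run_in_intervals * 28 + EVAL_YEAR_DAYS + 28
    n_occ = int(horizon_bound / 7) + 3
    pars, occ = _sample_cohort(spec, n_occ)
    err_rngs = [subject_rng(spec.seed + 2**20, i) for i in range(n)]

    def measure(troughs_true, i):
        if spec.measure_trough_with_error:
            return apply_residual_error(troughs_true, "pk_radboud",
                                        err_rngs[i], pop=spec.model)
        return troughs_true

    dt = spec.dt
    t2 = 14.0
    # pass 1: loading dose only, trough before 2nd dose at t = 14
    sched1 = [np.array([[0.0, load]]) for load in loads]
    _, conc1 = simulate_batch(pars["cl"], pars["v"], pars["vmax"], pars["km"],
                              occ, sched1, t2, dt)
    j14 = int(round(t2 / dt))
    d1 = np.empty(n)
    i1 = np.empty(n)
    trough1 = np.empty(n)
    for i in range(n):
        trough1[i] = measure(conc1[i, j14], i)
        d1[i], i1[i] = adjust("before_2nd_dose", trough1[i],
                              m_dose[i], m_int[i])

    # pass 2: loading + 2nd dose, trough before 3rd dose at t = 14 + i1
    t3 = t2 + i1
    sched2 = [np.array([[0.0, loads[i]], [t2, d1[i]]]) for i in range(n)]
    _, conc2 = simulate_batch(pars["cl"], pars["v"], pars["vmax"], pars["km"],
                              occ, sched2, float(t3.max()), dt)
    d2 = np.empty(n)
    i2 = np.empty(n)
    trough2 = np.empty(n)
    for i in range(n):
        trough2[i] = measure(conc2[i, int(round(t3[i] / dt))], i)
        d2[i], i2[i] = adjust("before_3rd_dose", trough2[i], d1[i], i1[i])

    # pass 3: full realized course through run-in + steady-state year
    win0 = t3 + spec.run_in_intervals * i2
    win1 = win0 + EVAL_YEAR_DAYS
    horizon = float(win1.max())
    schedules = []
    maint_times = []
    for i in range(n):
        ts = np.arange(t3[i], horizon + 1e-9, i2[i])
        sched = np.concatenate([
            np.array([[0.0, loads[i]], [t2, d1[i]]]),
            np.column_stack([ts, np.full_like(ts, d2[i])])])
        schedules.append(sched)
        maint_times.append(ts)
    times, conc = simulate_batch(pars["cl"], pars["v"], pars["vmax"],
                                 pars["km"], occ, schedules, horizon, dt)
    thr = _threshold_conc(spec.model, pars["base"], pars["ic50"],
                          spec.threshold)
    below = _attains(conc, thr)
    ss, troughs = _window_metrics(times, conc, thr,
                                  np.column_stack([win0, win1]), maint_times)
    first28 = np.array(
        [vial_cost(s[:, 1][s[:, 0] <= 28.0].sum()) for s in schedules])
    annual = np.array([(365.25 / i2[i]) * vial_cost(d2[i]) for i in range(n)])
    return TrialResult(strategy="tdm", study="maintenance",
                       seed=spec.seed, threshold=spec.threshold, times=times,
                       attainment_curve=below.mean(axis=0),
                       ss_attainment=ss, troughs=troughs,
                       final_dose=d2, final_interval=i2,
                       first28_cost=first28.astype(float), annual_cost=annual)


def attainment_at(result: TrialResult, time: float) -> float:
    """Fraction of the cohort below the CP threshold at an on-grid time."""
    idx = np.flatnonzero(np.isclose(result.times, time, atol=1e-9))
    if idx.size == 0:
        raise ValueError(
            f"time {time} is not on the evaluation grid; interpolation refused")
    return float(result.attainment_curve[idx[0]])


def extension_fractions(result: TrialResult) -> dict[float, float]:
    """Fractions of subjects by final realized dosing interval (TDM only)."""
    if result.strategy != "tdm":
        raise ValueError("extension fractions are defined for the tdm strategy")
    out = {}
    for interval in (14.0, 21.0, 28.0):
        out[interval] = float(np.mean(result.final_interval == interval))
    return out


def trough_band_fraction(result: TrialResult, lo: float, hi: float) -> float:
    """Fraction of maintenance troughs in [lo, hi) over the steady year."""
    if not lo < hi:
        raise ValueError("lo must be < hi")
    if result.troughs is None:
        raise ValueError("trial has no maintenance trough summaries")
    pooled = np.concatenate(result.troughs)
    return float(np.mean((pooled >= lo) & (pooled < hi)))


def mean_cost(result: TrialResult, window: str) -> float:
    """Cohort-mean drug cost (USD) for a cost window.

    ``first28d``: vial cost of doses administered at t in [0, 28] days.
    ``per_year_maintenance``: annualized maintenance cost (realized
    schedule for the TDM strategy).
    """
    if window == "first28d":
        return float(result.first28_cost.mean())
    if window == "per_year_maintenance":
        if result.annual_cost is None:
            raise ValueError("no yearly maintenance cost for this trial")
        return float(result.annual_cost.mean())
    raise ValueError(f"unknown cost window {window!r}")
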