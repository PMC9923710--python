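"""Trough-guided individualized (TDM) dosing policy.

The individualized course starts with the weight-banded loading dose
(alternative loading strategy), followed by PK-guided maintenance dosing:
the trough concentration is measured immediately before the 2nd dose
(day 15, t = 14) and before the 3rd dose (one maintenance interval later),
and at each checkpoint the regimen is adjusted:

==============  ==============  ===========  ===========
trough, 2nd     trough, 3rd     interval     dose
==============  ==============  ===========  ===========
< 100 mg/L      < 50 mg/L       unchanged    +300 mg
100-200 mg/L    50-200 mg/L     unchanged    unchanged
>= 200 mg/L     >= 200 mg/L     +1 week      unchanged
==============  ==============  ===========  ===========

Thresholds are half-open as printed.  After the second checkpoint the
regimen is frozen.  Interval extensions compound (+7 days at each
checkpoint) up to a 28-day cap; the interval never falls below, and the
dose never below, the band's standard maintenance values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .parameters import IndividualParameters, PopulationModel, apply_residual_error
from .pk import DoseEvent, solve_concentration_profile, trough_before
from .regimens import ALT_LOADING_TABLE, maintenance_spec

__all__ = ["CHECKPOINTS", "TdmCourse", "adjust", "simulate_tdm_course",
           "INTERVAL_CAP", "DOSE_INCREMENT"]

CHECKPOINTS = ("before_2nd_dose", "before_3rd_dose")
LOW_THRESHOLDS = {"before_2nd_dose": 100.0, "before_3rd_dose": 50.0}
HIGH_THRESHOLD = 200.0
INTERVAL_CAP = 28.0
DOSE_INCREMENT = 300.0


@dataclass
class TdmCourse:
    """Realized individualized course."""

    dose_events: tuple[DoseEvent, ...]
    dose_history: tuple[float, ...]       # maintenance dose after each checkpoint
    interval_history: tuple[float, ...]   # interval after each checkpoint
    troughs: tuple[float, ...]            # measured checkpoint troughs
    final_dose: float
    final_interval: float


def adjust(checkpoint: str,
           trough: float,
           current_dose: float,
           current_interval: float,
           interval_cap: float = INTERVAL_CAP,
           dose_increment: float = DOSE_INCREMENT) -> tuple[float, float]:
    """Apply the trough-band rule at one checkpoint."""
    if checkpoint not in CHECKPOINTS:
        raise ValueError(f"unknown checkpoint {checkpoint!r}")
    if trough < 0:
        raise ValueError("trough must be non-negative")
    if trough < LOW_THRESHOLDS[checkpoint]:
        return current_dose + dose_increment, current_interval
    if trough >= HIGH_THRESHOLD:
        return current_dose, min(current_interval + 7.0, interval_cap)
    return current_dose, current_interval


def simulate_tdm_course(ind: IndividualParameters,
                        weight: float,
                        horizon: float,
                        rng_seed=0,
                        measure_with_error: bool = False,
                        pop: PopulationModel | None = None,
                        dt: float = 0.1) -> TdmCourse:
    """Simulate one subject's individualized course out to ``horizon`` days.

    The profile is re-simulated after each adjustment; with
    ``measure_with_error`` the checkpoint troughs are perturbed by the
    Radboudumc PK residual-error model before the rule is applied
    (the default is error-free model-predicted troughs).
    """
    load = float(ALT_LOADING_TABLE.lookup(weight)["load"])
    m_dose, m_interval, _ = maintenance_spec(weight)
    if horizon < 14.0 + 3 * m_interval:
        raise ValueError("horizon must cover at least three maintenance intervals")
    rng = (rng_seed if isinstance(rng_seed, np.random.Generator)
           else np.random.default_rng(rng_seed))

    def measure(doses, t_check):
        times = np.arange(0.0, t_check + dt / 2, dt)
        prof = solve_concentration_profile(ind, doses, times)
        trough = trough_before(prof, t_check)
        if measure_with_error:
            trough = apply_residual_error(trough, "pk_radboud", rng, pop=pop)
        return trough

    dose, interval = m_dose, m_interval
    # checkpoint 1: trough before the 2nd dose (day 15)
    t2 = 14.0
    trough1 = measure([DoseEvent(0.0, load)], t2)
    dose, interval = adjust("before_2nd_dose", trough1, dose, interval)
    d1, i1 = dose, interval
    # checkpoint 2: trough before the 3rd dose
    t3 = t2 + i1
    trough2 = measure([DoseEvent(0.0, load), DoseEvent(t2, d1)], t3)
    dose, interval = adjust("before_3rd_dose", trough2, dose, interval)
    d2, i2 = dose, interval

    events = [DoseEvent(0.0, load), DoseEvent(t2, d1)]
    t = t3
    while t <= horizon:
        events.append(DoseEvent(t, d2))
        t += i2
    return TdmCourse(dose_events=tuple(events),
                     dose_history=(m_dose, d1, d2),
                     interval_history=(m_interval, i1, i2),
                     troughs=(trough1, trough2),
                     final_dose=d2, final_interval=i2)
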