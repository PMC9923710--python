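"""Weight-banded eculizumab dosing regimens and vial-based drug costs.

Three regimens are encoded as weight-band lookup tables:

* the approved label regimen (weekly induction, then fixed maintenance
  every 14 days -- every 21 days in the 5-10 kg band);
* an alternative loading strategy (one weight-banded loading dose on day 1,
  the maintenance dose on day 15, then standard maintenance dosing);
* a fixed 4-week-interval maintenance regimen (for e.g. holidays).

Day numbering: "day d" of the printed schedules corresponds to simulation
time ``t = d - 1`` days, i.e. the first dose is given at t = 0.  Weight
bands are half-open ``[lo, hi)``; the top band is closed above, and a
boundary weight such as 40.0 kg belongs to the ">=40 kg" band.  All doses
are multiples of the 300-mg vial (US$6523 per vial).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .pk import DoseEvent

__all__ = [
    "VIAL_MG", "VIAL_COST_USD", "Regimen", "WeightBandTable",
    "standard_regimen", "alternative_loading_regimen", "q4w_regimen",
    "maintenance_spec", "vial_cost", "annualize_cost",
    "STANDARD_TABLE", "ALT_LOADING_TABLE", "Q4W_TABLE",
]

VIAL_MG = 300
VIAL_COST_USD = 6523


@dataclass(frozen=True)
class Regimen:
    """A realized dose schedule plus its steady maintenance settings."""

    name: str
    dose_events: tuple[DoseEvent, ...]
    maintenance_dose: float     # mg
    maintenance_interval: float  # days

    def total_mg(self, t_max: float = math.inf) -> float:
        """Total dose administered at times <= ``t_max``."""
        return sum(d.amount for d in self.dose_events if d.time <= t_max)


@dataclass(frozen=True)
class WeightBandTable:
    """Ordered weight bands, each mapping to a per-phase dose spec."""

    name: str
    bands: tuple[tuple[float, float, dict], ...]

    def lookup(self, weight: float) -> dict:
        if weight < self.bands[0][0]:
            raise ValueError(
                f"weight {weight} kg below the lowest supported band "
                f"({self.bands[0][0]} kg) of table {self.name!r}")
        for lo, hi, spec in self.bands:
            if lo <= weight < hi or (hi == math.inf and weight >= lo):
                return spec
        raise AssertionError("bands must partition [lo, inf)")


# Approved label regimen.  induction: list of (week, dose mg);
# maintenance: dose mg, starting week, interval days.
STANDARD_TABLE = WeightBandTable(
    name="standard",
    bands=(
        (5.0, 10.0, {"induction": [(1, 300)],
                     "maintenance_dose": 300, "maintenance_week": 2,
                     "interval": 21}),
        (10.0, 20.0, {"induction": [(1, 600)],
                      "maintenance_dose": 300, "maintenance_week": 2,
                      "interval": 14}),
        (20.0, 30.0, {"induction": [(1, 600), (2, 600)],
                      "maintenance_dose": 600, "maintenance_week": 3,
                      "interval": 14}),
        (30.0, 40.0, {"induction": [(1, 600), (2, 600)],
                      "maintenance_dose": 900, "maintenance_week": 3,
                      "interval": 14}),
        (40.0, math.inf, {"induction": [(1, 900), (2, 900), (3, 900), (4, 900)],
                          "maintenance_dose": 1200, "maintenance_week": 5,
                          "interval": 14}),
    ))

# Alternative loading strategy: one loading dose on day 1, the day-15 dose,
# then standard maintenance dosing of the Table-1 band.
ALT_LOADING_TABLE = WeightBandTable(
    name="alt_loading",
    bands=(
        (5.0, 10.0, {"load": 300, "day15": 300}),
        (10.0, 20.0, {"load": 600, "day15": 300}),
        (20.0, 30.0, {"load": 600, "day15": 600}),
        (30.0, 40.0, {"load": 900, "day15": 900}),
        (40.0, 60.0, {"load": 1500, "day15": 1200}),
        (60.0, 90.0, {"load": 1800, "day15": 1200}),
        (90.0, 120.0, {"load": 2100, "day15": 1200}),
        (120.0, math.inf, {"load": 2400, "day15": 1200}),
    ))

# Fixed 4-week-interval maintenance doses.
Q4W_TABLE = WeightBandTable(
    name="q4w",
    bands=(
        (5.0, 10.0, {"dose": 900}),
        (10.0, 20.0, {"dose": 1200}),
        (20.0, 30.0, {"dose": 1500}),
        (30.0, 40.0, {"dose": 1800}),
        (40.0, 60.0, {"dose": 2100}),
        (60.0, 90.0, {"dose": 2400}),
        (90.0, 120.0, {"dose": 2700}),
        (120.0, math.inf, {"dose": 3000}),
    ))


def maintenance_spec(weight: float) -> tuple[float, float, float]:
    """Label maintenance (dose mg, interval days, first dose time days)."""
    spec = STANDARD_TABLE.lookup(weight)
    t_first = (spec["maintenance_week"] - 1) * 7.0
    return float(spec["maintenance_dose"]), float(spec["interval"]), t_first


def standard_regimen(weight: float, horizon: float) -> Regimen:
    """Approved label regimen out to ``horizon`` days."""
    spec = STANDARD_TABLE.lookup(weight)
    events = [DoseEvent(time=(wk - 1) * 7.0, amount=float(mg))
              for wk, mg in spec["induction"] if (wk - 1) * 7.0 <= horizon]
    t = (spec["maintenance_week"] - 1) * 7.0
    while t <= horizon:
        events.append(DoseEvent(time=t, amount=float(spec["maintenance_dose"])))
        t += spec["interval"]
    return Regimen(name="standard", dose_events=tuple(events),
                   maintenance_dose=float(spec["maintenance_dose"]),
                   maintenance_interval=float(spec["interval"]))


def alternative_loading_regimen(weight: float, horizon: float) -> Regimen:
    """Single weight-banded load (day 1), day-15 dose, then standard
    maintenance dosing of the label band."""
    alt = ALT_LOADING_TABLE.lookup(weight)
    m_dose, m_interval, _ = maintenance_spec(weight)
    events = []
    if horizon >= 0:
        events.append(DoseEvent(time=0.0, amount=float(alt["load"])))
    t = 14.0
    if t <= horizon:
        events.append(DoseEvent(time=t, amount=float(alt["day15"])))
    t += m_interval
    while t <= horizon:
        events.append(DoseEvent(time=t, amount=m_dose))
        t += m_interval
    return Regimen(name="alt_loading", dose_events=tuple(events),
                   maintenance_dose=m_dose, maintenance_interval=m_interval)


def q4w_regimen(weight: float, horizon: float) -> Regimen:
    """Fixed 4-week-interval maintenance regimen from t = 0."""
    spec = Q4W_TABLE.lookup(weight)
    events = []
    t = 0.0
    while t <= horizon:
        events.append(DoseEvent(time=t, amount=float(spec["dose"])))
        t += 28.0
    return Regimen(name="q4w", dose_events=tuple(events),
                   maintenance_dose=float(spec["dose"]),
                   maintenance_interval=28.0)


def vial_cost(total_mg: float) -> int:
    """Drug cost in USD for a total amount, counted in whole 300-mg vials."""
    if total_mg < 0:
        raise ValueError("total_mg must be >= 0")
    return int(math.ceil(total_mg / VIAL_MG)) * VIAL_COST_USD


def annualize_cost(maintenance_dose: float, interval: float) -> float:
    """Yearly maintenance drug cost, fractional annualization 365.25/interval."""
    if interval <= 0:
        raise ValueError("interval must be positive")
    return (365.25 / interval) * vial_cost(maintenance_dose)
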