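"""Synthetic virtual cohort emulating an NHANES-like simulation population.

The original simulation population (2000 subjects, ages 1-79, 48% female,
median weight 61.6 kg with range 8.3-155.6 kg, median height 159 cm) was
drawn from the NHANES survey, which is not redistributed here.  This module
generates a parametric stand-in matched to those printed summary
statistics: age is a two-stratum mixture (a child stratum uniform on
[1, 18) and an adult stratum uniform on [18, 79]) whose mixing weight puts
the median at ~24.8 years; weight and height are age- and sex-conditional
lognormals around growth-curve median anchors with log-linear
interpolation.  Marginal medians and ranges are asserted in the test
suite; joint covariance structure of the real survey is NOT reproduced.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["VirtualSubject", "generate_cohort", "load_cohort",
           "cohort_to_frame", "growth_median_weight", "growth_median_height"]

# Fraction of the cohort in the child stratum; chosen so the overall median
# age is ~24.8 y: p + (1-p)*(24.8-18)/61 = 0.5  =>  p ~ 0.437.
CHILD_FRACTION = 0.437
FEMALE_FRACTION = 0.48
WEIGHT_RANGE = (8.3, 155.6)
HEIGHT_RANGE = (70.0, 202.0)

# Growth-curve median body-weight anchors (kg, sexes combined for
# children); log-linearly interpolated in age.
_W_AGES = np.array([1.0, 2.0, 5.0, 10.0, 15.0, 18.0, 30.0, 60.0, 79.0])
_W_MEDS = np.array([10.0, 12.7, 18.5, 32.0, 55.0, 68.0, 75.0, 76.0, 74.0])
# Median height anchors (cm).
_H_AGES = _W_AGES
_H_MEDS = np.array([75.0, 87.0, 109.0, 138.0, 165.0, 170.0, 170.0,
                    168.0, 166.0])

# Adult sex effect as a multiplier ramped in linearly over ages 12-18.
_W_SEX_MULT = {"male": 1.08, "female": 0.92}
_H_SEX_MULT = {"male": 1.040, "female": 0.956}

WEIGHT_CV_ADULT = 0.20
WEIGHT_CV_CHILD = 0.15
HEIGHT_CV = 0.040


@dataclass(frozen=True)
class VirtualSubject:
    subject_id: int
    age: float          # years
    sex: str            # "female" | "male"
    weight: float       # kg
    height: float       # cm

    def __post_init__(self) -> None:
        if not 1.0 <= self.age <= 79.0:
            raise ValueError(f"age {self.age} outside [1, 79]")
        if self.sex not in ("female", "male"):
            raise ValueError(f"sex must be 'female' or 'male', got {self.sex!r}")
        if not 5.0 <= self.weight <= 160.0:
            raise ValueError(f"weight {self.weight} outside [5, 160]")
        if not 60.0 <= self.height <= 210.0:
            raise ValueError(f"height {self.height} outside [60, 210]")


def _sex_ramp(age, adult_mult):
    """Sex multiplier: 1 below age 12, full adult value from age 18."""
    frac = np.clip((np.asarray(age, float) - 12.0) / 6.0, 0.0, 1.0)
    return 1.0 + frac * (adult_mult - 1.0)


def growth_median_weight(age, sex="female"):
    """Growth-curve median weight (kg) at a given age and sex."""
    m = np.exp(np.interp(np.log(np.asarray(age, float)),
                         np.log(_W_AGES), np.log(_W_MEDS)))
    return m * _sex_ramp(age, _W_SEX_MULT[sex])


def growth_median_height(age, sex="female"):
    """Growth-curve median height (cm) at a given age and sex."""
    m = np.exp(np.interp(np.log(np.asarray(age, float)),
                         np.log(_H_AGES), np.log(_H_MEDS)))
    return m * _sex_ramp(age, _H_SEX_MULT[sex])


def generate_cohort(n: int,
                    age_range: tuple[float, float] = (1.0, 79.0),
                    rng_seed: int = 0,
                    weight_cv_adult: float = WEIGHT_CV_ADULT,
                    weight_cv_child: float = WEIGHT_CV_CHILD,
                    height_cv: float = HEIGHT_CV) -> list[VirtualSubject]:
    """Generate ``n`` virtual subjects; deterministic under ``rng_seed``.

    Setting the CV parameters to zero collapses weight/height to their
    growth-curve medians.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    lo, hi = age_range
    if not lo < hi:
        raise ValueError("empty age range")
    rng = np.random.default_rng(rng_seed)
    child_hi = min(18.0, hi)
    subjects = []
    for i in range(n):
        if lo < child_hi and rng.random() < CHILD_FRACTION:
            age = rng.uniform(lo, child_hi)
        else:
            age = rng.uniform(max(lo, 18.0), hi) if hi > 18.0 else rng.uniform(lo, hi)
        sex = "female" if rng.random() < FEMALE_FRACTION else "male"
        cv_w = weight_cv_child if age < 18 else weight_cv_adult
        sigma_w = np.sqrt(np.log1p(cv_w**2))
        weight = float(growth_median_weight(age, sex)
                       * np.exp(sigma_w * rng.standard_normal()))
        weight = float(np.clip(weight, *WEIGHT_RANGE))
        sigma_h = np.sqrt(np.log1p(height_cv**2))
        height = float(growth_median_height(age, sex)
                       * np.exp(sigma_h * rng.standard_normal()))
        height = float(np.clip(height, *HEIGHT_RANGE))
        subjects.append(VirtualSubject(subject_id=i, age=float(age),
                                       sex=sex, weight=weight, height=height))
    return subjects


def cohort_to_frame(cohort) -> pd.DataFrame:
    return pd.DataFrame(
        {"subject_id": [s.subject_id for s in cohort],
         "age": [s.age for s in cohort],
         "sex": [s.sex for s in cohort],
         "weight": [s.weight for s in cohort],
         "height": [s.height for s in cohort]})


def load_cohort(path) -> list[VirtualSubject]:
    """Read a cohort CSV (subject_id, age, sex, weight, height).

    Rows violating the subject invariants are rejected with row-level
    diagnostics; a header-only file yields an empty cohort with a warning.
    """
    df = pd.read_csv(path, comment="#")
    required = ["subject_id", "age", "sex", "weight", "height"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"cohort file missing column(s): {missing}")
    if df.empty:
        warnings.warn(f"cohort file {path} contains no subjects")
        return []
    subjects = []
    errors = []
    for row_no, row in df.iterrows():
        try:
            subjects.append(VirtualSubject(
                subject_id=int(row["subject_id"]),
                age=float(row["age"]),
                sex=str(row["sex"]),
                weight=float(row["weight"]),
                height=float(row["height"])))
        except (ValueError, TypeError) as exc:
            errors.append(f"row {row_no}: {exc}")
    if errors:
        raise ValueError("invalid cohort rows:\n" + "\n".join(errors))
    return subjects
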