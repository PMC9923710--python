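"""Population PK-PD parameters of eculizumab and random-effect sampling.

The pharmacokinetic model is a one-compartment model with parallel
first-order (CL) and Michaelis-Menten (Vmax, Km) elimination; body weight
enters allometrically on CL, Vmax and V referenced to 70 kg.  The
pharmacodynamic model maps the free eculizumab concentration C (mg/L) to
classical complement pathway (CP) activity E (% of normal) through an
inhibitory sigmoid Emax relation

    E = Base * (1 - Imax * C**gamma / (IC50**gamma + C**gamma)).

Between-subject (IIV) and between-occasion (IOV) variability are
multiplicative lognormal random effects reported as CV%; an "occasion" is
the dosing interval beginning at each administration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "PopulationPKParameters",
    "PopulationPDParameters",
    "PopulationModel",
    "IndividualParameters",
    "cv_to_omega",
    "scale_by_weight",
    "sample_individual",
    "apply_residual_error",
    "subject_rng",
]


def cv_to_omega(cv_percent: float) -> float:
    """Convert a lognormal coefficient of variation in percent to omega.

    omega is the standard deviation of the underlying normal random effect:
    ``omega = sqrt(ln(1 + (cv/100)**2))``.
    """
    if cv_percent < 0:
        raise ValueError(f"CV% must be non-negative, got {cv_percent}")
    return math.sqrt(math.log1p((cv_percent / 100.0) ** 2))


@dataclass(frozen=True)
class PopulationPKParameters:
    """Population PK estimates (typical 70-kg subject).

    ``prop_err_*`` are the assay-specific proportional residual-error terms
    (Radboudumc and Sanquin ELISAs), interpreted as variances sigma^2 by
    default (``prop_err_is_variance``).
    """

    cl_typ: float = 0.163          # linear clearance, L/day
    v_typ: float = 6.42            # volume of distribution, L
    vmax_typ: float = 29.6         # maximal saturable elimination rate, mg/day
    km: float = 37.9               # conc. at half-maximal saturable rate, mg/L
    iiv_cl_cv: float = 43.4        # IIV on CL, CV%
    iiv_v_cv: float = 37.1         # IIV on V, CV%
    iov_cl_cv: float = 34.4        # IOV on CL, CV%
    add_err: float = 4.33          # additive residual SD, mg/L
    prop_err_radboud: float = 0.0247
    prop_err_sanquin: float = 0.248
    ref_weight: float = 70.0       # covariate reference body weight, kg
    allometric_cl: float = 0.75    # exponent on CL and Vmax
    allometric_v: float = 1.0      # exponent on V
    prop_err_is_variance: bool = True

    def __post_init__(self) -> None:
        for name in ("cl_typ", "v_typ", "vmax_typ", "km", "add_err",
                     "prop_err_radboud", "prop_err_sanquin", "ref_weight"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        for name in ("iiv_cl_cv", "iiv_v_cv", "iov_cl_cv"):
            cv = getattr(self, name)
            if not 0 <= cv < 200:
                raise ValueError(f"{name} must lie in [0, 200), got {cv}")

    def prop_var(self, assay: str) -> float:
        """Proportional residual variance for an assay tag."""
        if assay == "radboud":
            term = self.prop_err_radboud
        elif assay == "sanquin":
            term = self.prop_err_sanquin
        else:
            raise ValueError(f"unknown assay {assay!r}")
        return term if self.prop_err_is_variance else term**2


@dataclass(frozen=True)
class PopulationPDParameters:
    """Population estimates of the sequential inhibitory Emax PD model."""

    base: float = 100.7            # baseline CP activity, %
    imax: float = 0.96             # maximal inhibition fraction
    ic50: float = 22.0             # conc. at half-maximal inhibition, mg/L
    gamma: float = 5.42            # Hill coefficient
    iiv_base_cv: float = 23.0      # IIV on Base, CV%
    iiv_ic50_cv: float = 38.5      # IIV on IC50, CV%
    prop_err: float = 0.089        # proportional residual term
    prop_err_is_variance: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.imax <= 1:
            raise ValueError("imax must lie in (0, 1]")
        if self.ic50 <= 0 or self.gamma <= 0:
            raise ValueError("ic50 and gamma must be strictly positive")
        if not 0 < self.base <= 200:
            raise ValueError("base must lie in (0, 200]")

    @property
    def prop_var(self) -> float:
        return self.prop_err if self.prop_err_is_variance else self.prop_err**2


@dataclass(frozen=True)
class PopulationModel:
    """A PK model and its sequential PD model, used as sampling/MAP prior."""

    pk: PopulationPKParameters = field(default_factory=PopulationPKParameters)
    pd: PopulationPDParameters = field(default_factory=PopulationPDParameters)

    def with_overrides(self, **kwargs) -> "PopulationModel":
        pk_fields = {k: v for k, v in kwargs.items()
                     if k in PopulationPKParameters.__dataclass_fields__}
        pd_fields = {k: v for k, v in kwargs.items()
                     if k in PopulationPDParameters.__dataclass_fields__}
        unknown = set(kwargs) - set(pk_fields) - set(pd_fields)
        if unknown:
            raise ValueError(f"unknown parameter(s): {sorted(unknown)}")
        return PopulationModel(pk=replace(self.pk, **pk_fields),
                               pd=replace(self.pd, **pd_fields))


@dataclass
class IndividualParameters:
    """Realized per-subject PK-PD parameters.

    ``cl_i`` is the individual linear clearance before the occasion effect;
    the effective clearance during occasion k is
    ``cl_i * occasion_cl_multipliers[k]``.
    """

    subject_id: int
    cl_i: float
    v_i: float
    vmax_i: float
    km_i: float
    base_i: float
    ic50_i: float
    gamma_i: float
    imax_i: float
    occasion_cl_multipliers: np.ndarray = field(
        default_factory=lambda: np.ones(1))

    def __post_init__(self) -> None:
        self.occasion_cl_multipliers = np.asarray(
            self.occasion_cl_multipliers, dtype=float)
        vals = [self.cl_i, self.v_i, self.km_i, self.base_i,
                self.ic50_i, self.gamma_i, self.imax_i]
        if any(v <= 0 for v in vals):
            raise ValueError("all individual parameters must be positive")
        if self.vmax_i < 0:  # 0 = purely linear elimination
            raise ValueError("vmax_i must be non-negative")
        if np.any(self.occasion_cl_multipliers <= 0):
            raise ValueError("occasion multipliers must be positive")


def scale_by_weight(pop: PopulationPKParameters, weight: float) -> dict:
    """Typical individual PK parameters at a given body weight.

    CL and Vmax scale as ``(weight/ref)**0.75``, V as ``(weight/ref)**1.0``
    and Km is weight-independent (exponents configurable on ``pop``).
    """
    if weight <= 0:
        raise ValueError(f"weight must be positive, got {weight}")
    frac = weight / pop.ref_weight
    return {
        "cl": pop.cl_typ * frac**pop.allometric_cl,
        "v": pop.v_typ * frac**pop.allometric_v,
        "vmax": pop.vmax_typ * frac**pop.allometric_cl,
        "km": pop.km,
    }


def subject_rng(master_seed: int, subject_index: int) -> np.random.Generator:
    """Deterministic per-subject random substream from one master seed."""
    ss = np.random.SeedSequence(entropy=int(master_seed),
                                spawn_key=(int(subject_index),))
    return np.random.default_rng(ss)


def sample_individual(pop_pk: PopulationPKParameters,
                      pop_pd: PopulationPDParameters,
                      subject,
                      n_occasions: int = 1,
                      rng_seed=0) -> IndividualParameters:
    """Draw one subject's individual parameters.

    Lognormal IIV is applied to CL, V (PK) and Base, IC50 (PD); one
    lognormal occasion multiplier per dosing occasion perturbs CL.  ``imax``,
    ``gamma``, ``vmax`` and ``km`` carry no reported variability and stay at
    their (weight-scaled) typical values.

    ``subject`` needs ``weight`` and ``subject_id`` attributes; ``rng_seed``
    may be an integer seed or a ``numpy.random.Generator``.
    """
    if n_occasions < 1:
        raise ValueError("n_occasions must be >= 1")
    if isinstance(rng_seed, np.random.Generator):
        rng = rng_seed
    else:
        rng = np.random.default_rng(rng_seed)
    typ = scale_by_weight(pop_pk, subject.weight)
    om_cl = cv_to_omega(pop_pk.iiv_cl_cv)
    om_v = cv_to_omega(pop_pk.iiv_v_cv)
    om_base = cv_to_omega(pop_pd.iiv_base_cv)
    om_ic50 = cv_to_omega(pop_pd.iiv_ic50_cv)
    om_iov = cv_to_omega(pop_pk.iov_cl_cv)
    eta = rng.standard_normal(4)
    kappas = rng.standard_normal(n_occasions)
    return IndividualParameters(
        subject_id=getattr(subject, "subject_id", 0),
        cl_i=typ["cl"] * math.exp(om_cl * eta[0]),
        v_i=typ["v"] * math.exp(om_v * eta[1]),
        vmax_i=typ["vmax"],
        km_i=typ["km"],
        base_i=pop_pd.base * math.exp(om_base * eta[2]),
        ic50_i=pop_pd.ic50 * math.exp(om_ic50 * eta[3]),
        gamma_i=pop_pd.gamma,
        imax_i=pop_pd.imax,
        occasion_cl_multipliers=np.exp(om_iov * kappas),
    )


def apply_residual_error(true_value,
                         error_model: str,
                         rng_seed=0,
                         pop: PopulationModel | None = None):
    """Perturb model-predicted values with the residual-error model.

    PK observations: ``obs = true*(1 + eps_p) + eps_a`` with assay-specific
    proportional variance and additive SD 4.33 mg/L.  PD observations:
    ``obs = true*(1 + eps_p)``.  Negative draws are truncated at zero.
    Accepts scalars or arrays.
    """
    if pop is None:
        pop = PopulationModel()
    if isinstance(rng_seed, np.random.Generator):
        rng = rng_seed
    else:
        rng = np.random.default_rng(rng_seed)
    true_value = np.asarray(true_value, dtype=float)
    if np.any(true_value < 0):
        raise ValueError("true_value must be non-negative")
    if error_model in ("pk_radboud", "pk_sanquin"):
        assay = error_model.removeprefix("pk_")
        sd_p = math.sqrt(pop.pk.prop_var(assay))
        eps_p = rng.normal(0.0, sd_p, size=true_value.shape)
        eps_a = rng.normal(0.0, pop.pk.add_err, size=true_value.shape)
        obs = true_value * (1.0 + eps_p) + eps_a
    elif error_model == "pd":
        sd_p = math.sqrt(pop.pd.prop_var)
        eps_p = rng.normal(0.0, sd_p, size=true_value.shape)
        obs = true_value * (1.0 + eps_p)
    else:
        raise ValueError(f"unknown error model {error_model!r}")
    obs = np.maximum(obs, 0.0)
    return float(obs) if obs.ndim == 0 else obs
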