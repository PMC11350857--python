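"""Population model: covariates, lognormal interindividual variability, residual error.

The final covariate model places a single power-law effect of estimated GFR
on clearance::

    CL_i = CL_pop * (GFR_i / GFR_ref)**beta_GFR_CL * exp(eta_CL)
    V_i  = V_pop  * exp(eta_V)

with eta ~ N(0, omega**2) on the log scale (lognormal parameters) and an
additive Gaussian residual on the concentration scale.  Observed
concentrations below the assay's lower limit of quantification (LLOQ,
8 mg/L) are recorded as a fixed substitute value (4 mg/L), mirroring routine
TDM reporting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .pk import IndividualParameters

__all__ = [
    "PopulationParameters",
    "Subject",
    "RandomEffects",
    "TABLE_PARAMS",
    "individual_CL",
    "individual_V",
    "sample_individual",
    "add_residual_error",
    "ckd_epi",
]

#: Default LLOQ of the ceftazidime assay (mg/L) and the value recorded for
#: sub-LLOQ samples.
LLOQ = 8.0
LLOQ_SUBSTITUTE = 4.0


@dataclass(frozen=True)
class PopulationParameters:
    """Fixed effects, covariate coefficient, random-effect SDs and residual SD.

    Defaults are the published estimates for ceftazidime under continuous
    infusion in ICU adults: CL 4.45 L/h, Vd 88 L, GFR exponent 0.9 (reference
    GFR 73.90 mL/min/1.73 m^2), log-scale SDs 0.46 (CL) and 0.57 (V), additive
    residual SD 0.39 mg/L.
    """

    CL_pop: float = 4.45  # L/h
    V_pop: float = 88.0  # L
    beta_GFR_CL: float = 0.9  # dimensionless exponent
    omega_CL: float = 0.46  # SD of log-scale random effect
    omega_V: float = 0.57  # SD of log-scale random effect
    sigma_add: float = 0.39  # mg/L
    GFR_median_ref: float = 73.90  # mL/min/1.73 m^2
    corr_CL_V: float = 0.0  # correlation hook; 0 = independent etas (default)

    def __post_init__(self) -> None:
        for name in ("CL_pop", "V_pop", "GFR_median_ref"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("omega_CL", "omega_V", "sigma_add"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if not -1.0 <= self.corr_CL_V <= 1.0:
            raise ValueError("corr_CL_V must be in [-1, 1]")

    def replace(self, **kw) -> "PopulationParameters":
        return replace(self, **kw)

    def to_dict(self) -> dict:
        return {
            "CL_pop": self.CL_pop,
            "V_pop": self.V_pop,
            "beta_GFR_CL": self.beta_GFR_CL,
            "omega_CL": self.omega_CL,
            "omega_V": self.omega_V,
            "sigma_add": self.sigma_add,
            "GFR_median_ref": self.GFR_median_ref,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PopulationParameters":
        return cls(**{k: float(v) for k, v in d.items() if k in cls.__dataclass_fields__})


#: The published final-model estimates (also the dataclass defaults).
TABLE_PARAMS = PopulationParameters()


@dataclass(frozen=True)
class Subject:
    """One patient: identifier plus baseline covariates.

    GFR (mL/min/1.73 m^2) is required to simulate or fit under the final
    model; the remaining covariates are optional descriptors.
    """

    id: str | int
    GFR: float
    weight: Optional[float] = None  # kg
    age: Optional[float] = None  # years
    sex: Optional[str] = None  # "M" / "F"
    serum_creatinine: Optional[float] = None  # umol/L
    BMI: Optional[float] = None  # kg/m^2

    def __post_init__(self) -> None:
        if not self.GFR > 0:
            raise ValueError(f"subject {self.id}: GFR must be > 0, got {self.GFR}")


@dataclass(frozen=True)
class RandomEffects:
    """Log-scale per-subject deviations from the typical parameters."""

    eta_CL: float = 0.0
    eta_V: float = 0.0

    def __post_init__(self) -> None:
        if not (math.isfinite(self.eta_CL) and math.isfinite(self.eta_V)):
            raise ValueError("etas must be finite")


def individual_CL(pop: PopulationParameters, GFR: float, eta_CL: float = 0.0) -> float:
    """Individual clearance (L/h) under the GFR power model."""
    if GFR <= 0:
        raise ValueError(f"GFR must be > 0, got {GFR}")
    return pop.CL_pop * (GFR / pop.GFR_median_ref) ** pop.beta_GFR_CL * math.exp(eta_CL)


def individual_V(pop: PopulationParameters, eta_V: float = 0.0) -> float:
    """Individual volume of distribution (L); no covariate is retained on V."""
    return pop.V_pop * math.exp(eta_V)


def individual_parameters(
    pop: PopulationParameters, subject: Subject, etas: RandomEffects
) -> IndividualParameters:
    """Map covariates plus random effects to realized (CL, V)."""
    return IndividualParameters(
        CL=individual_CL(pop, subject.GFR, etas.eta_CL),
        V=individual_V(pop, etas.eta_V),
    )


def sample_etas(pop: PopulationParameters, rng: np.random.Generator) -> RandomEffects:
    """Draw one pair of log-scale random effects (optionally correlated)."""
    z = rng.standard_normal(2)
    eta_cl = pop.omega_CL * z[0]
    rho = pop.corr_CL_V
    eta_v = pop.omega_V * (rho * z[0] + math.sqrt(max(0.0, 1.0 - rho**2)) * z[1])
    return RandomEffects(eta_CL=eta_cl, eta_V=eta_v)


def sample_individual(
    pop: PopulationParameters, subject: Subject, rng: np.random.Generator
) -> IndividualParameters:
    """Draw one subject's realized parameters; lognormal about the typical values.

    With both omegas zero the draw is degenerate at the typical individual,
    and marginal medians at reference covariates equal the typical values.
    """
    return individual_parameters(pop, subject, sample_etas(pop, rng))


def add_residual_error(
    true_conc: np.ndarray | float,
    sigma_add: float,
    rng: np.random.Generator,
    lloq: float = LLOQ,
    lloq_substitute: float = LLOQ_SUBSTITUTE,
) -> np.ndarray:
    """Additive Gaussian measurement error with sub-LLOQ substitution.

    Any noisy value below ``lloq`` is recorded as ``lloq_substitute`` — the
    laboratory's reporting rule — so the returned values are never in
    ``(0, lloq)`` other than the substitute, and never negative.
    """
    c = np.atleast_1d(np.asarray(true_conc, dtype=float))
    obs = c + sigma_add * rng.standard_normal(c.shape)
    obs = np.where(obs < lloq, lloq_substitute, obs)
    return obs


_CKD_EPI_2009 = {
    # sex -> (kappa mg/dL, alpha, sex multiplier)
    "F": (0.7, -0.329, 1.018),
    "M": (0.9, -0.411, 1.0),
}

#: mg/dL per umol/L for creatinine.
_UMOL_PER_MGDL = 88.42


def ckd_epi(
    serum_creatinine_umol_l: float,
    age_years: float,
    sex: str,
    race_black: bool = False,
) -> float:
    """Estimated GFR (mL/min/1.73 m^2) by the CKD-EPI 2009 creatinine equation.

    The race coefficient is off by default (French laboratory convention);
    pass ``race_black=True`` for the original 1.159 multiplier.
    """
    if serum_creatinine_umol_l <= 0 or age_years <= 0:
        raise ValueError("creatinine and age must be positive")
    sex = sex.upper()[0]
    if sex not in _CKD_EPI_2009:
        raise ValueError("sex must be 'M' or 'F'")
    kappa, alpha, mult = _CKD_EPI_2009[sex]
    scr = serum_creatinine_umol_l / _UMOL_PER_MGDL
    ratio = scr / kappa
    egfr = (
        141.0
        * min(ratio, 1.0) ** alpha
        * max(ratio, 1.0) ** -1.209
        * 0.993**age_years
        * mult
    )
    if race_black:
        egfr *= 1.159
    return egfr
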