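"""Per-type annual fracture probabilities under given management rates.

The cohort is represented as a two-stratum mixture: a high-risk stratum
(share ``at_risk_share``) whose per-type annual probability is the baseline
multiplied by ``at_risk_multiplier``, and the remainder at the baseline.
Treatment targets the high-risk stratum first (the care pathway runs
assessment → identification of those at risk → treatment), spilling over to
the low-risk stratum only once everyone at risk is treated.  Adherent
treated women have their per-type probability multiplied by the treatment
mix's relative risk; non-adherent treated women receive, by default, no
benefit (a partial-efficacy fraction is exposed for sensitivity analyses).

A FRAX-like generative risk function is provided for individual-level
synthetic cohorts: a Gompertz-style log-linear age term, a gradient of risk
per T-score standard deviation, and multiplicative clinical-risk-factor
(CRF) terms, converted to an annual probability.  It mirrors the structure
of published fracture-risk tools without reproducing any proprietary
coefficient table.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
from pydantic import BaseModel, Field, model_validator

from .inputs import FractureType
from .interventions import ManagementRates

logger = logging.getLogger(__name__)

#: Default stand-in stratification constants (model constants, not estimates).
DEFAULT_AT_RISK_SHARE = 0.30
DEFAULT_AT_RISK_MULTIPLIER = 4.0


class RiskProfile(BaseModel):
    """Stratified per-type annual fracture probabilities for one country-year."""

    model_config = {"frozen": True}

    baseline: dict[FractureType, float]
    at_risk_share: float = Field(default=DEFAULT_AT_RISK_SHARE, ge=0, le=1)
    at_risk_multiplier: float = Field(default=DEFAULT_AT_RISK_MULTIPLIER, ge=1)

    @model_validator(mode="after")
    def _probabilities(self):
        for ft in FractureType:
            if ft not in self.baseline:
                raise ValueError(f"baseline missing fracture type {ft.value}")
            b = self.baseline[ft]
            if not 0.0 <= b <= 1.0:
                raise ValueError(f"baseline[{ft.value}]={b} outside [0, 1]")
        return self

    def stratum_probability(self, ft: FractureType, at_risk: bool) -> float:
        b = self.baseline[ft]
        return min(self.at_risk_multiplier * b, 1.0) if at_risk else b


class RiskFunctionParams(BaseModel):
    """Coefficients of the FRAX-like generative risk function (per type).

    ``baseline_rate`` is the annual fracture hazard at the reference point
    (age 70, T-score 0, no CRFs); ``age_slope`` is the log-linear increase
    per year of age; ``t_score_gradient`` the risk ratio per SD decrease in
    T-score; ``crf_multipliers`` the risk ratio per present clinical risk
    factor.
    """

    model_config = {"frozen": True}

    baseline_rate: dict[FractureType, float]
    age_slope: dict[FractureType, float]
    t_score_gradient: dict[FractureType, float]
    crf_multipliers: tuple[float, ...] = ()

    @model_validator(mode="after")
    def _valid(self):
        for ft in FractureType:
            if not 0.0 < self.baseline_rate[ft] < 1.0:
                raise ValueError(f"baseline_rate[{ft.value}] outside (0, 1)")
            if not np.isfinite(self.age_slope[ft]):
                raise ValueError("age slope must be finite")
            if self.t_score_gradient[ft] <= 0:
                raise ValueError("t-score gradient must be positive")
        if any(m <= 0 for m in self.crf_multipliers):
            raise ValueError("CRF multipliers must be positive")
        return self


def default_risk_function_params() -> RiskFunctionParams:
    """Plausible coefficients for women aged 70+ (synthetic-cohort default).

    Hazards and slopes are in the range reported for European fracture
    epidemiology (hip incidence roughly doubling every 6–7 years of age;
    gradient of risk ≈1.4–2.6 per SD); they are illustrative constants, not
    fitted values.
    """
    return RiskFunctionParams(
        baseline_rate={
            FractureType.HIP: 0.008,
            FractureType.VERTEBRAL: 0.006,
            FractureType.NHNV: 0.025,
        },
        age_slope={
            FractureType.HIP: 0.10,
            FractureType.VERTEBRAL: 0.06,
            FractureType.NHNV: 0.04,
        },
        t_score_gradient={
            FractureType.HIP: 2.2,
            FractureType.VERTEBRAL: 1.8,
            FractureType.NHNV: 1.4,
        },
        crf_multipliers=(1.8, 1.4, 1.3),
    )


def cap_probabilities(
    risk: Mapping[FractureType, float]
) -> dict[FractureType, float]:
    """Clip per-type probabilities into [0, 1] (at most one fracture per type per year)."""
    out = {}
    for ft, p in risk.items():
        clipped = min(max(float(p), 0.0), 1.0)
        if clipped != p:
            logger.warning("probability %s=%.4f clipped to %.1f", ft, p, clipped)
        out[ft] = clipped
    return out


def frax_like_risk(
    age: float | np.ndarray,
    t_score: float | np.ndarray,
    crf_flags: Sequence[int] | np.ndarray,
    params: RiskFunctionParams,
) -> dict[FractureType, np.ndarray]:
    """Per-type annual fracture probability for individual covariates.

    ``crf_flags`` has one 0/1 indicator per entry of
    ``params.crf_multipliers``; for vectorised evaluation it may be an array
    of shape (n, n_crf) with ``age``/``t_score`` arrays of length n.

    The probability increases with age and with decreasing T-score, and is
    clipped into [0, 1].  Ages below 70 are outside the modelled population.
    """
    age = np.asarray(age, dtype=float)
    t_score = np.asarray(t_score, dtype=float)
    flags = np.atleast_2d(np.asarray(crf_flags, dtype=float))
    if np.any(age < 70):
        raise ValueError("the modelled population is women aged 70 and over")
    if flags.shape[-1] != len(params.crf_multipliers):
        raise ValueError(
            f"expected {len(params.crf_multipliers)} CRF flags, got {flags.shape[-1]}"
        )
    crf_term = np.prod(np.where(flags > 0, np.asarray(params.crf_multipliers), 1.0), axis=-1)
    out: dict[FractureType, np.ndarray] = {}
    for ft in FractureType:
        # baseline is a probability; scale on the hazard scale so the
        # reference point (age 70, T-score 0, no CRFs) is recovered exactly
        base_hazard = -np.log1p(-params.baseline_rate[ft])
        hazard = (
            base_hazard
            * np.exp(params.age_slope[ft] * (age - 70.0))
            * params.t_score_gradient[ft] ** (-t_score)
            * crf_term
        )
        out[ft] = np.clip(1.0 - np.exp(-hazard), 0.0, 1.0)
    return out


def treated_stratum_weights(
    at_risk_share: float, treatment_rate: float
) -> tuple[float, float]:
    """Population weights of (treated & at-risk, treated & not-at-risk).

    Treatment fills the at-risk stratum first; any excess spills over.
    """
    w_at = min(treatment_rate, at_risk_share)
    w_nt = max(treatment_rate - at_risk_share, 0.0)
    return w_at, w_nt


def population_risk(
    profile: RiskProfile,
    rates: ManagementRates,
    rr: Mapping[FractureType, float],
    *,
    nonadherent_efficacy: float = 0.0,
) -> dict[FractureType, float]:
    """Population-average per-type annual fracture probability.

    Mixture over the four (stratum × treated) cells, with the adherent share
    of each treated cell receiving the full treatment relative risk and the
    non-adherent share a fraction ``nonadherent_efficacy`` of the risk
    reduction (0 by default: no benefit without adherence).
    """
    if not 0.0 <= nonadherent_efficacy <= 1.0:
        raise ValueError("nonadherent_efficacy outside [0, 1]")
    s = profile.at_risk_share
    alpha = rates.adherence_rate
    w_at, w_nt = treated_stratum_weights(s, rates.treatment_rate)
    out: dict[FractureType, float] = {}
    for ft in FractureType:
        p_ar = profile.stratum_probability(ft, at_risk=True)
        p_nr = profile.stratum_probability(ft, at_risk=False)
        reduction = (1.0 - rr[ft]) * (alpha + (1.0 - alpha) * nonadherent_efficacy)
        avg = s * p_ar + (1.0 - s) * p_nr - reduction * (w_at * p_ar + w_nt * p_nr)
        out[ft] = avg
    return cap_probabilities(out)
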