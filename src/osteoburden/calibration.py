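"""Back-solve baseline stratum risks and cost scales from observed burden.

The cohort equations are linear in the baseline per-type probability as long
as the at-risk stratum is below the one-fracture-per-type cap, so the
status-quo model can be inverted in closed form:

    q_t = b_t · D_t,
    D_t = s·m + (1−s) − α_eff·(1−RR_t)·(w_at·m + w_nt)

where q_t is the target population-average per-type probability (the
observed per-type incidence), s/m the at-risk share and multiplier, α_eff
the effective adherence (adherent share plus any partial non-adherent
efficacy) and (w_at, w_nt) the treated weights per stratum.  The solved
baseline is independent of the target only through q_t, and the status-quo
population average reproduces q_t for ANY (s, m) choice — stratification
redistributes risk without changing the mean.

Cost calibration is a single multiplicative factor on the fracture-cost
component (unit costs are printed inputs; the unobserved residual is in
fracture-care pathways), chosen so the modelled total matches the observed
total; the structural medication and assessment components are untouched.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from pydantic import BaseModel, Field

from .inputs import CountryParams, FractureType, GlobalAssumptions
from .interventions import ManagementRates, status_quo_rates
from .risk import (
    DEFAULT_AT_RISK_MULTIPLIER,
    DEFAULT_AT_RISK_SHARE,
    RiskProfile,
    treated_stratum_weights,
)

logger = logging.getLogger(__name__)


class CalibrationTarget(BaseModel):
    """Observed status-quo burden for one country-year, per 100,000 women 70+."""

    model_config = {"frozen": True}

    country_code: str
    year: int
    fractures_per_100k: float = Field(gt=0)
    cost_per_100k: float | None = Field(default=None, gt=0)  # € millions per 100k


class InfeasibleTargetError(ValueError):
    """The target incidence cannot be reached with probabilities in [0, 1]."""


def calibrate_baseline(
    target: CalibrationTarget,
    params: CountryParams,
    assumptions: GlobalAssumptions,
    *,
    at_risk_share: float = DEFAULT_AT_RISK_SHARE,
    at_risk_multiplier: float = DEFAULT_AT_RISK_MULTIPLIER,
    nonadherent_efficacy: float = 0.0,
) -> RiskProfile:
    """Solve the baseline per-type probabilities reproducing ``target``.

    The total target incidence is split across fracture types by the
    country's fracture-type distribution, then each type's baseline is
    solved in closed form under the status-quo management rates.
    """
    rates = status_quo_rates(assumptions, params)
    s = at_risk_share
    m = at_risk_multiplier
    alpha_eff = rates.adherence_rate + (1.0 - rates.adherence_rate) * nonadherent_efficacy
    w_at, w_nt = treated_stratum_weights(s, rates.treatment_rate)
    q_total = target.fractures_per_100k / 1e5
    baseline: dict[FractureType, float] = {}
    for ft in FractureType:
        q_t = q_total * params.fracture_distribution[ft]
        denom = s * m + (1.0 - s) - alpha_eff * (1.0 - params.treatment_rr[ft]) * (
            w_at * m + w_nt
        )
        b = q_t / denom
        if not 0.0 <= b <= 1.0 or m * b > 1.0:
            raise InfeasibleTargetError(
                f"{target.country_code}/{target.year}: target {target.fractures_per_100k}"
                f"/100k for {ft.value} requires baseline {b:.4f} (at-risk {m * b:.4f});"
                " probabilities must stay in [0, 1]"
            )
        baseline[ft] = b
    return RiskProfile(
        baseline=baseline, at_risk_share=s, at_risk_multiplier=m
    )


def calibrate_cost_scale(target_cost: float, modelled_cost: float) -> float:
    """Multiplicative factor aligning a modelled cost with an observed one.

    Both arguments must be positive and on the same scale (totals or
    per-100k); the factor applies to the fracture-cost component only.
    """
    if target_cost <= 0 or modelled_cost <= 0:
        raise ValueError("costs must be positive to calibrate a scale factor")
    factor = target_cost / modelled_cost
    if abs(factor - 1.0) > 0.25:
        logger.info("cost scale factor %.3f deviates >25%% from unity", factor)
    return factor


@dataclass(frozen=True)
class CalibrationRecord:
    """Per country-year calibration report row."""

    country_code: str
    year: int
    baseline: dict[FractureType, float]
    at_risk_share: float
    at_risk_multiplier: float
    cost_scale: float
    fracture_residual_per_100k: float
    cost_residual_per_100k: float
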