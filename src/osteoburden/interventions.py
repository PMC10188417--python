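"""Intervention levers: transform status-quo management rates.

Three hypothetical disease-management interventions are modelled, each at an
improvement fraction f:

* ``assessment`` — more women undergo fracture-risk assessment, which feeds
  through to treatment uptake via the identification and at-risk-treatment
  rates:  new_treatment = t_sq + (a_new − a_sq) · id_rate · at_risk_treat.
* ``adherence`` — the non-adherent share of treated women shrinks by f:
  new_adherence = a + f·(1 − a)  (so 40% adherence at f=0.5 becomes 70%).
* ``combined`` — hierarchical composition: the treated population is first
  enlarged through the assessment lever, then the improved adherence applies
  to that enlarged treated population.

Two readings of "an f% improvement in risk assessment rates" are supported:
``relative`` (rate × (1+f)) and ``gap`` (rate + f·(1 − rate), the same
gap-closing arithmetic the adherence lever uses).  ``relative`` is the
default; neither is hard-coded anywhere downstream.
"""

from __future__ import annotations

import enum
import logging

from pydantic import BaseModel, Field

from .inputs import CountryParams, GlobalAssumptions

logger = logging.getLogger(__name__)


class Lever(str, enum.Enum):
    ASSESSMENT = "assessment"
    ADHERENCE = "adherence"
    COMBINED = "combined"


class AssessmentMode(str, enum.Enum):
    RELATIVE = "relative"
    GAP = "gap"


class InterventionSpec(BaseModel):
    """Which lever to improve, by what fraction, and how to read the assessment lever."""

    model_config = {"frozen": True}

    lever: Lever
    improvement: float = Field(ge=0, le=1)
    assessment_mode: AssessmentMode = AssessmentMode.RELATIVE
    label: str = ""

    def with_label(self) -> "InterventionSpec":
        if self.label:
            return self
        idx = {Lever.ASSESSMENT: 1, Lever.ADHERENCE: 2, Lever.COMBINED: 3}[self.lever]
        return self.model_copy(update={"label": f"{idx}_{round(self.improvement * 100)}"})


class ManagementRates(BaseModel):
    """Assessment / treatment / adherence rates in force under one scenario."""

    model_config = {"frozen": True}

    assessment_rate: float = Field(ge=0, le=1)
    treatment_rate: float = Field(ge=0, le=1)
    adherence_rate: float = Field(ge=0, le=1)


def _check_unit(name: str, x: float) -> None:
    if not 0.0 <= x <= 1.0:
        raise ValueError(f"{name}={x} outside [0, 1]")


def improved_adherence_rate(adherence_sq: float, f: float) -> float:
    """Close fraction ``f`` of the non-adherence gap: a + f·(1 − a)."""
    _check_unit("adherence_sq", adherence_sq)
    _check_unit("f", f)
    return adherence_sq + f * (1.0 - adherence_sq)


def improved_assessment_rate(
    assessment_sq: float, f: float, mode: AssessmentMode | str = AssessmentMode.RELATIVE
) -> float:
    """Improve the risk-assessment rate by fraction ``f`` (relative or gap mode)."""
    _check_unit("assessment_sq", assessment_sq)
    _check_unit("f", f)
    mode = AssessmentMode(mode)
    if mode is AssessmentMode.RELATIVE:
        return min(assessment_sq * (1.0 + f), 1.0)
    return assessment_sq + f * (1.0 - assessment_sq)


def new_treatment_rate(
    treatment_sq: float,
    assessment_new: float,
    assessment_sq: float,
    identification_rate: float,
    at_risk_treatment_rate: float,
) -> float:
    """Treatment uptake implied by an enlarged assessed population.

    new = t_sq + (a_new − a_sq) × identification_rate × at_risk_treatment_rate,
    clipped at 1.  Interventions never reduce assessment, so a_new < a_sq is a
    domain error.
    """
    for name, x in (
        ("treatment_sq", treatment_sq),
        ("assessment_new", assessment_new),
        ("assessment_sq", assessment_sq),
        ("identification_rate", identification_rate),
        ("at_risk_treatment_rate", at_risk_treatment_rate),
    ):
        _check_unit(name, x)
    if assessment_new < assessment_sq:
        raise ValueError(
            f"assessment_new={assessment_new} < assessment_sq={assessment_sq}: "
            "interventions never reduce the assessment rate"
        )
    new = treatment_sq + (assessment_new - assessment_sq) * identification_rate * at_risk_treatment_rate
    if new > 1.0:
        logger.warning("treatment rate %.4f clipped to 1.0", new)
        new = 1.0
    return new


def status_quo_rates(assumptions: GlobalAssumptions, params: CountryParams) -> ManagementRates:
    return ManagementRates(
        assessment_rate=assumptions.assessment_rate_sq,
        treatment_rate=params.treatment_rate_sq,
        adherence_rate=assumptions.adherence_sq,
    )


def apply_intervention(
    spec: InterventionSpec, assumptions: GlobalAssumptions, params: CountryParams
) -> ManagementRates:
    """Management rates in force for one country under ``spec``.

    f=0 reproduces the status-quo rates exactly for every lever.  The
    combined lever is hierarchical: the treatment rate is computed from the
    improved assessment rate first, then the improved adherence applies to
    the enlarged treated population.
    """
    sq = status_quo_rates(assumptions, params)
    assessment = sq.assessment_rate
    treatment = sq.treatment_rate
    adherence = sq.adherence_rate
    f = spec.improvement
    if spec.lever in (Lever.ASSESSMENT, Lever.COMBINED):
        assessment = improved_assessment_rate(sq.assessment_rate, f, spec.assessment_mode)
        treatment = new_treatment_rate(
            sq.treatment_rate,
            assessment,
            sq.assessment_rate,
            params.identification_rate,
            params.at_risk_treatment_rate,
        )
    if spec.lever in (Lever.ADHERENCE, Lever.COMBINED):
        adherence = improved_adherence_rate(sq.adherence_rate, f)
    return ManagementRates(
        assessment_rate=assessment, treatment_rate=treatment, adherence_rate=adherence
    )


def default_scenario_grid(
    assessment_mode: AssessmentMode | str = AssessmentMode.RELATIVE,
) -> list[InterventionSpec]:
    """The published scenario grid: each lever at 10%, 50% and 100% improvement."""
    mode = AssessmentMode(assessment_mode)
    return [
        InterventionSpec(lever=lever, improvement=f, assessment_mode=mode).with_label()
        for f in (0.10, 0.50, 1.00)
        for lever in (Lever.ASSESSMENT, Lever.ADHERENCE, Lever.COMBINED)
    ]
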