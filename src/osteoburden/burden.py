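"""Fracture counts, costs of care, per-100,000 normalisation and net benefits.

Counts are expected values (population × probability) carried as real
numbers through all arithmetic and rounded half-away-from-zero only at the
reporting boundary.  Costs of care have three components, all in € millions
(2020):

* fracture — first-year direct medical cost per incident fracture, by type
  (optionally scaled by a calibrated factor, see :mod:`osteoburden.calibration`);
* medication — annual anti-osteoporosis medication cost for every treated
  woman (by default regardless of adherence);
* assessment — one BMD measurement per assessed woman per year.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from .inputs import CountryParams, FractureType, PopulationProjection
from .interventions import ManagementRates


def round_half_away(x: float, decimals: int = 0) -> float:
    """Round half away from zero (display convention for counts and rates)."""
    scale = 10.0 ** decimals
    return float(np.sign(x) * np.floor(np.abs(x) * scale + 0.5) / scale)


@dataclass(frozen=True)
class BurdenEstimate:
    """Annual fracture and cost burden for one country (or aggregate) and year."""

    country_code: str
    year: int
    population: int
    fractures_by_type: dict[FractureType, float]
    cost_fracture: float   # € millions
    cost_medication: float  # € millions
    cost_assessment: float  # € millions

    @property
    def fracture_total(self) -> float:
        return sum(self.fractures_by_type.values())

    @property
    def cost_total(self) -> float:
        return self.cost_fracture + self.cost_medication + self.cost_assessment

    @property
    def per_100k_fractures(self) -> float:
        return per_100k(self.fracture_total, self.population)

    @property
    def per_100k_cost(self) -> float:
        return per_100k(self.cost_total, self.population)

    def rounded_counts(self) -> dict[FractureType, int]:
        return {ft: int(round_half_away(c)) for ft, c in self.fractures_by_type.items()}


@dataclass(frozen=True)
class NetBenefit:
    """Differences from the status quo (negative = prevented / saved)."""

    country_code: str
    year: int
    delta_fractures: float
    delta_cost: float           # € millions
    pct_fractures: float        # 100 × delta / status quo
    pct_cost: float


def annual_fractures(
    n: int, risk: Mapping[FractureType, float]
) -> dict[FractureType, float]:
    """Expected per-type fracture counts: N × per-type probability."""
    if n <= 0:
        raise ValueError("population must be positive")
    return {ft: n * float(risk[ft]) for ft in FractureType}


def annual_costs(
    counts: Mapping[FractureType, float],
    params: CountryParams,
    rates: ManagementRates,
    n: int,
    *,
    cost_scale: float = 1.0,
    med_cost_scaled_by_adherence: bool = False,
) -> tuple[float, float, float]:
    """Cost components (fracture, medication, assessment) in € millions."""
    fracture = cost_scale * sum(
        counts[ft] * params.fracture_cost[ft] for ft in FractureType
    ) / 1e6
    med_rate = rates.treatment_rate * (
        rates.adherence_rate if med_cost_scaled_by_adherence else 1.0
    )
    medication = n * med_rate * params.med_cost_annual / 1e6
    assessment = n * rates.assessment_rate * params.bmd_cost / 1e6
    return fracture, medication, assessment


def per_100k(value: float, n: int) -> float:
    """Normalise an annual quantity to a population of 100,000 women aged 70+."""
    if n <= 0:
        raise ValueError("population must be positive")
    return value / n * 1e5


def net_benefit(status_quo: BurdenEstimate, intervention: BurdenEstimate) -> NetBenefit:
    """Signed differences (intervention − status quo) with relative percentages."""
    if (status_quo.country_code, status_quo.year) != (
        intervention.country_code,
        intervention.year,
    ):
        raise ValueError(
            f"mismatched keys: {status_quo.country_code}/{status_quo.year} vs "
            f"{intervention.country_code}/{intervention.year}"
        )
    df = intervention.fracture_total - status_quo.fracture_total
    dc = intervention.cost_total - status_quo.cost_total
    return NetBenefit(
        country_code=status_quo.country_code,
        year=status_quo.year,
        delta_fractures=df,
        delta_cost=dc,
        pct_fractures=100.0 * df / status_quo.fracture_total if status_quo.fracture_total else 0.0,
        pct_cost=100.0 * dc / status_quo.cost_total if status_quo.cost_total else 0.0,
    )


AGGREGATE_CODE = "ALL"


def aggregate(
    estimates: Iterable[BurdenEstimate], pop: PopulationProjection | None = None
) -> BurdenEstimate:
    """Sum burden estimates for one year across countries; per-100k recomputed.

    When ``pop`` is given, every country present in it for the year must be
    represented exactly once.
    """
    ests = list(estimates)
    if not ests:
        raise ValueError("no estimates to aggregate")
    years = {e.year for e in ests}
    if len(years) > 1:
        raise ValueError(f"cannot aggregate across years {sorted(years)}")
    year = ests[0].year
    seen = [e.country_code for e in ests]
    if len(set(seen)) != len(seen):
        raise ValueError("duplicate country in aggregate")
    if pop is not None:
        expected = {cc for (cc, yr) in pop.sizes if yr == year}
        missing = expected - set(seen)
        if missing:
            raise ValueError(f"aggregate missing countries: {sorted(missing)}")
    return BurdenEstimate(
        country_code=AGGREGATE_CODE,
        year=year,
        population=sum(e.population for e in ests),
        fractures_by_type={
            ft: sum(e.fractures_by_type[ft] for e in ests) for ft in FractureType
        },
        cost_fracture=sum(e.cost_fracture for e in ests),
        cost_medication=sum(e.cost_medication for e in ests),
        cost_assessment=sum(e.cost_assessment for e in ests),
    )
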