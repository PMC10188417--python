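"""Typed model inputs: country parameters, population projections, observed burden.

All management rates and fracture-type shares are stored as fractions in
[0, 1]; all monetary amounts are 2020 euros (inputs are assumed pre-adjusted
with each country's consumer price index — see :func:`cpi_adjust` for the
optional utility).  The bundled fixtures transcribe the published inputs for
the eight modelled countries (Belgium, France, Germany, Ireland, Poland,
Slovakia, Switzerland, United Kingdom) and the five snapshot years
2020/2025/2030/2035/2040.
"""

from __future__ import annotations

import enum
import logging
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator

logger = logging.getLogger(__name__)

SNAPSHOT_YEARS: tuple[int, ...] = (2020, 2025, 2030, 2035, 2040)

#: ISO-3166 alpha-2 codes of the eight modelled countries.
FIXTURE_COUNTRIES: tuple[str, ...] = ("BE", "FR", "DE", "IE", "PL", "SK", "CH", "GB")

#: Tolerance for the printed fracture-type mix: whole percentages round to ±2pp.
_DIST_SUM_TOL = 0.02


class FractureType(str, enum.Enum):
    """The three modelled osteoporotic fracture categories."""

    HIP = "hip"
    VERTEBRAL = "vertebral"
    NHNV = "nhnv"  # non-hip, non-vertebral


class ValidationError(ValueError):
    """Raised when an input table violates a model invariant."""


def _as_type_map(values: Mapping) -> dict[FractureType, float]:
    out = {}
    for ft in FractureType:
        key = ft if ft in values else ft.value
        if key not in values:
            raise ValidationError(f"missing fracture type {ft.value!r}")
        out[ft] = float(values[key])
    return out


class CountryParams(BaseModel):
    """One country's fracture and treatment inputs.

    Parameters
    ----------
    fracture_distribution
        Share of incident fractures per type; renormalised to sum to 1.
    treatment_rr
        Relative risk per fracture type of the country's anti-osteoporosis
        treatment mix versus placebo (treatment-mix-weighted).
    fracture_cost
        First-year direct medical cost per fracture, € per event.
    med_cost_annual
        Weighted annual anti-osteoporosis medication cost, € per treated
        woman-year.
    bmd_cost
        Unit cost of a BMD measurement, € per assessment.
    treatment_rate_sq
        Status-quo treatment rate among women aged 70+.
    identification_rate
        Share of assessed women identified as being at high fracture risk.
    at_risk_treatment_rate
        Share of identified at-risk women who start treatment.
    """

    model_config = {"frozen": True}

    country_code: str = Field(min_length=2, max_length=2)
    country_name: str = ""
    fracture_distribution: dict[FractureType, float]
    treatment_rr: dict[FractureType, float]
    fracture_cost: dict[FractureType, float]
    med_cost_annual: float = Field(ge=0)
    bmd_cost: float = Field(ge=0)
    treatment_rate_sq: float = Field(ge=0, le=1)
    identification_rate: float = Field(ge=0, le=1)
    at_risk_treatment_rate: float = Field(ge=0, le=1)

    @field_validator("fracture_distribution", "treatment_rr", "fracture_cost", mode="before")
    @classmethod
    def _complete(cls, v):
        return _as_type_map(v)

    @model_validator(mode="after")
    def _invariants(self):
        for ft, share in self.fracture_distribution.items():
            if not 0.0 <= share <= 1.0:
                raise ValidationError(
                    f"{self.country_code}: fracture share {ft.value}={share} outside [0, 1]"
                )
        total = sum(self.fracture_distribution.values())
        if abs(total - 1.0) > _DIST_SUM_TOL:
            raise ValidationError(
                f"{self.country_code}: fracture distribution sums to {total:.3f}, not 1"
            )
        if abs(total - 1.0) > 1e-12:
            # printed whole percentages; renormalise proportionally
            logger.debug(
                "%s: renormalising fracture distribution by 1/%.4f", self.country_code, total
            )
            object.__setattr__(
                self,
                "fracture_distribution",
                {ft: share / total for ft, share in self.fracture_distribution.items()},
            )
        for ft, rr in self.treatment_rr.items():
            if not 0.0 < rr <= 1.0:
                raise ValidationError(
                    f"{self.country_code}: treatment RR {ft.value}={rr} outside (0, 1]"
                )
        for ft, c in self.fracture_cost.items():
            if c < 0:
                raise ValidationError(f"{self.country_code}: negative cost for {ft.value}")
        return self


class GlobalAssumptions(BaseModel):
    """Management rates assumed identical across countries under the status quo."""

    model_config = {"frozen": True}

    assessment_rate_sq: float = Field(default=0.25, ge=0, le=1)
    adherence_sq: float = Field(default=0.40, ge=0, le=1)


class PopulationProjection(BaseModel):
    """Projected number of women aged 70+ per (country, snapshot year)."""

    model_config = {"frozen": True}

    sizes: dict[tuple[str, int], int]

    @model_validator(mode="after")
    def _positive(self):
        for key, n in self.sizes.items():
            if n <= 0:
                raise ValidationError(f"non-positive population for {key}")
        return self

    def __getitem__(self, key: tuple[str, int]) -> int:
        return self.sizes[key]

    @property
    def countries(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(cc for cc, _ in self.sizes))

    @property
    def years(self) -> tuple[int, ...]:
        return tuple(sorted({yr for _, yr in self.sizes}))

    def total(self, year: int) -> int:
        return sum(n for (_, yr), n in self.sizes.items() if yr == year)


class StatusQuoBurden(BaseModel):
    """Observed annual burden per (country, year): calibration targets only.

    ``cost_millions`` is the total annual cost of care in € millions (2020).
    """

    model_config = {"frozen": True}

    fractures: dict[tuple[str, int], float]
    cost_millions: dict[tuple[str, int], float]

    @model_validator(mode="after")
    def _nonnegative(self):
        for name, mapping in (("fractures", self.fractures), ("costs", self.cost_millions)):
            for key, v in mapping.items():
                if v < 0:
                    raise ValidationError(f"negative {name} for {key}")
        return self


# ---------------------------------------------------------------------------
# readers / writers

_TABLE1_COLUMNS = [
    "country_code", "dist_hip", "dist_vertebral", "dist_nhnv",
    "rr_hip", "rr_vertebral", "rr_nhnv",
    "cost_hip", "cost_vertebral", "cost_nhnv",
    "med_cost_annual", "bmd_cost",
    "treatment_rate_sq", "identification_rate", "at_risk_treatment_rate",
]


def load_country_params(path: str | Path | None = None) -> list[CountryParams]:
    """Read a country-parameter table (CSV); defaults to the bundled fixture.

    Raises :class:`ValidationError` naming the offending row and field when a
    column is missing or a value violates its invariant.
    """
    df = pd.read_csv(_resolve(path, "table1_inputs.csv"))
    missing = [c for c in _TABLE1_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"country parameter table missing columns: {missing}")
    out = []
    for _, row in df.iterrows():
        try:
            out.append(
                CountryParams(
                    country_code=row["country_code"],
                    country_name=row.get("country_name", ""),
                    fracture_distribution={
                        "hip": row["dist_hip"],
                        "vertebral": row["dist_vertebral"],
                        "nhnv": row["dist_nhnv"],
                    },
                    treatment_rr={
                        "hip": row["rr_hip"],
                        "vertebral": row["rr_vertebral"],
                        "nhnv": row["rr_nhnv"],
                    },
                    fracture_cost={
                        "hip": row["cost_hip"],
                        "vertebral": row["cost_vertebral"],
                        "nhnv": row["cost_nhnv"],
                    },
                    med_cost_annual=row["med_cost_annual"],
                    bmd_cost=row["bmd_cost"],
                    treatment_rate_sq=row["treatment_rate_sq"],
                    identification_rate=row["identification_rate"],
                    at_risk_treatment_rate=row["at_risk_treatment_rate"],
                )
            )
        except (ValidationError, ValueError) as exc:
            raise ValidationError(
                f"row {row['country_code']!r}: {exc}"
            ) from exc
    return out


def write_country_params(params: Iterable[CountryParams], path: str | Path) -> None:
    rows = []
    for p in params:
        rows.append(
            {
                "country_code": p.country_code,
                "country_name": p.country_name,
                "dist_hip": p.fracture_distribution[FractureType.HIP],
                "dist_vertebral": p.fracture_distribution[FractureType.VERTEBRAL],
                "dist_nhnv": p.fracture_distribution[FractureType.NHNV],
                "rr_hip": p.treatment_rr[FractureType.HIP],
                "rr_vertebral": p.treatment_rr[FractureType.VERTEBRAL],
                "rr_nhnv": p.treatment_rr[FractureType.NHNV],
                "cost_hip": p.fracture_cost[FractureType.HIP],
                "cost_vertebral": p.fracture_cost[FractureType.VERTEBRAL],
                "cost_nhnv": p.fracture_cost[FractureType.NHNV],
                "med_cost_annual": p.med_cost_annual,
                "bmd_cost": p.bmd_cost,
                "treatment_rate_sq": p.treatment_rate_sq,
                "identification_rate": p.identification_rate,
                "at_risk_treatment_rate": p.at_risk_treatment_rate,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def load_population(
    path: str | Path | None = None,
    *,
    countries: Iterable[str] | None = None,
    years: Iterable[int] | None = None,
) -> PopulationProjection:
    """Read a population projection (CSV: country_code, year, population).

    The grid must be complete over ``countries`` × ``years`` (defaulting to
    the eight fixture countries and five snapshot years when the bundled
    fixture is read, otherwise to the countries/years present in the file).
    """
    df = pd.read_csv(_resolve(path, "table2_population.csv"))
    for col in ("country_code", "year", "population"):
        if col not in df.columns:
            raise ValidationError(f"population table missing column {col!r}")
    sizes = {
        (str(r.country_code), int(r.year)): int(r.population) for r in df.itertuples()
    }
    if countries is None:
        countries = FIXTURE_COUNTRIES if path is None else tuple(
            dict.fromkeys(df["country_code"].astype(str))
        )
    if years is None:
        years = SNAPSHOT_YEARS if path is None else tuple(sorted(df["year"].unique()))
    gaps = [
        (cc, yr) for cc in countries for yr in years if (cc, int(yr)) not in sizes
    ]
    if gaps:
        raise ValidationError(f"population grid incomplete; missing cells: {gaps}")
    return PopulationProjection(sizes=sizes)


def write_population(pop: PopulationProjection, path: str | Path) -> None:
    rows = [
        {"country_code": cc, "year": yr, "population": n}
        for (cc, yr), n in sorted(pop.sizes.items())
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def load_burden(path: str | Path | None = None) -> StatusQuoBurden:
    """Read observed status-quo burden (CSV: country_code, year, fracture_count, cost_millions)."""
    df = pd.read_csv(_resolve(path, "table2_burden.csv"))
    for col in ("country_code", "year", "fracture_count", "cost_millions"):
        if col not in df.columns:
            raise ValidationError(f"burden table missing column {col!r}")
    fractures = {
        (str(r.country_code), int(r.year)): float(r.fracture_count) for r in df.itertuples()
    }
    costs = {
        (str(r.country_code), int(r.year)): float(r.cost_millions) for r in df.itertuples()
    }
    return StatusQuoBurden(fractures=fractures, cost_millions=costs)


def _resolve(path: str | Path | None, fixture: str):
    if path is not None:
        return Path(path)
    return resources.files("osteoburden.data") / fixture


def cpi_adjust(amount: float, cpi_from: float, cpi_to: float) -> float:
    """Rescale a monetary amount between consumer-price-index levels.

    Not applied anywhere by default: the bundled unit costs are already in
    2020 euros.
    """
    if cpi_from <= 0 or cpi_to <= 0:
        raise ValueError("CPI index values must be positive")
    return amount * cpi_to / cpi_from
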