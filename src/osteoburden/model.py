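"""Model/Results facade over calibration and scenario projection.

:class:`FractureBurdenModel` bundles the inputs of the cross-sectional
cohort model — country parameters, population projections and observed
status-quo burden — with the stand-in risk-stratification constants.
``fit()`` back-solves the baseline per-type fracture probabilities and the
fracture-cost scale for every country-year so the status-quo model
reproduces the observed burden, and returns a
:class:`FractureBurdenResults` carrying the calibrated quantities,
residual diagnostics, scenario projection and plotting.

Typical use::

    model = FractureBurdenModel.from_fixtures()
    res = model.fit()
    print(res.summary())
    scen = res.run_scenarios()           # published 3-lever × 3-fraction grid
    scen.net_benefit_frame()
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .burden import (
    AGGREGATE_CODE,
    BurdenEstimate,
    NetBenefit,
    aggregate,
    annual_costs,
    annual_fractures,
    net_benefit,
    per_100k,
)
from .calibration import (
    CalibrationRecord,
    CalibrationTarget,
    calibrate_baseline,
    calibrate_cost_scale,
)
from .inputs import (
    CountryParams,
    FractureType,
    GlobalAssumptions,
    PopulationProjection,
    StatusQuoBurden,
    load_burden,
    load_country_params,
    load_population,
)
from .interventions import (
    InterventionSpec,
    ManagementRates,
    apply_intervention,
    default_scenario_grid,
    status_quo_rates,
)
from .risk import (
    DEFAULT_AT_RISK_MULTIPLIER,
    DEFAULT_AT_RISK_SHARE,
    RiskProfile,
    population_risk,
)

STATUS_QUO_LABEL = "status_quo"


class FractureBurdenModel:
    """Cross-sectional cohort model of osteoporotic fracture burden.

    Parameters
    ----------
    countries
        One :class:`~osteoburden.inputs.CountryParams` per modelled country.
    population
        Women aged 70+ per (country, snapshot year).
    burden
        Observed status-quo fracture counts and costs (calibration targets).
    assumptions
        Status-quo assessment and adherence rates (defaults 25% / 40%).
    at_risk_share, at_risk_multiplier
        Stand-in risk stratification: share of the population at high risk
        and the ratio of their per-type probability to baseline.  Model
        constants reported in all outputs; the status-quo calibration is
        invariant to them.
    nonadherent_efficacy
        Fraction of the treatment risk reduction retained without adherence
        (default 0: no benefit).
    med_cost_scaled_by_adherence
        Charge medication costs only for the adherent share when True.
    """

    def __init__(
        self,
        countries: list[CountryParams],
        population: PopulationProjection,
        burden: StatusQuoBurden,
        assumptions: GlobalAssumptions | None = None,
        *,
        at_risk_share: float = DEFAULT_AT_RISK_SHARE,
        at_risk_multiplier: float = DEFAULT_AT_RISK_MULTIPLIER,
        nonadherent_efficacy: float = 0.0,
        med_cost_scaled_by_adherence: bool = False,
    ) -> None:
        self.countries = {p.country_code: p for p in countries}
        self.population = population
        self.burden = burden
        self.assumptions = assumptions or GlobalAssumptions()
        self.at_risk_share = at_risk_share
        self.at_risk_multiplier = at_risk_multiplier
        self.nonadherent_efficacy = nonadherent_efficacy
        self.med_cost_scaled_by_adherence = med_cost_scaled_by_adherence
        missing = [
            key for key in self.burden.fractures if key[0] not in self.countries
        ]
        if missing:
            raise ValueError(f"burden targets for unknown countries: {missing}")

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_tables(
        cls,
        params_path=None,
        population_path=None,
        burden_path=None,
        **kwargs,
    ) -> "FractureBurdenModel":
        """Build from CSV tables (``None`` falls back to the bundled fixtures)."""
        return cls(
            load_country_params(params_path),
            load_population(population_path),
            load_burden(burden_path),
            **kwargs,
        )

    @classmethod
    def from_fixtures(cls, **kwargs) -> "FractureBurdenModel":
        """Build from the bundled eight-country published inputs."""
        return cls.from_tables(**kwargs)

    @property
    def years(self) -> tuple[int, ...]:
        return self.population.years

    # -- fitting ------------------------------------------------------------

    def fit(self) -> "FractureBurdenResults":
        """Calibrate baseline risks and cost scales for every country-year."""
        profiles: dict[tuple[str, int], RiskProfile] = {}
        cost_scales: dict[tuple[str, int], float] = {}
        records: list[CalibrationRecord] = []
        for (cc, yr), target_count in sorted(self.burden.fractures.items()):
            params = self.countries[cc]
            n = self.population[(cc, yr)]
            target = CalibrationTarget(
                country_code=cc,
                year=yr,
                fractures_per_100k=per_100k(target_count, n),
                cost_per_100k=per_100k(self.burden.cost_millions[(cc, yr)], n),
            )
            profile = calibrate_baseline(
                target,
                params,
                self.assumptions,
                at_risk_share=self.at_risk_share,
                at_risk_multiplier=self.at_risk_multiplier,
                nonadherent_efficacy=self.nonadherent_efficacy,
            )
            profiles[(cc, yr)] = profile
            rates = status_quo_rates(self.assumptions, params)
            est_raw = self._estimate(cc, yr, profile, rates, cost_scale=1.0)
            target_cost = self.burden.cost_millions[(cc, yr)]
            scale = calibrate_cost_scale(
                target_cost - est_raw.cost_medication - est_raw.cost_assessment,
                est_raw.cost_fracture,
            )
            cost_scales[(cc, yr)] = scale
            est = self._estimate(cc, yr, profile, rates, cost_scale=scale)
            records.append(
                CalibrationRecord(
                    country_code=cc,
                    year=yr,
                    baseline=profile.baseline,
                    at_risk_share=profile.at_risk_share,
                    at_risk_multiplier=profile.at_risk_multiplier,
                    cost_scale=scale,
                    fracture_residual_per_100k=est.per_100k_fractures
                    - target.fractures_per_100k,
                    cost_residual_per_100k=est.per_100k_cost - target.cost_per_100k,
                )
            )
        return FractureBurdenResults(self, profiles, cost_scales, records)

    # -- projection helpers -------------------------------------------------

    def _estimate(
        self,
        cc: str,
        yr: int,
        profile: RiskProfile,
        rates: ManagementRates,
        cost_scale: float,
    ) -> BurdenEstimate:
        params = self.countries[cc]
        n = self.population[(cc, yr)]
        risk = population_risk(
            profile, rates, params.treatment_rr,
            nonadherent_efficacy=self.nonadherent_efficacy,
        )
        counts = annual_fractures(n, risk)
        fr, med, ass = annual_costs(
            counts, params, rates, n,
            cost_scale=cost_scale,
            med_cost_scaled_by_adherence=self.med_cost_scaled_by_adherence,
        )
        return BurdenEstimate(
            country_code=cc, year=yr, population=n,
            fractures_by_type=counts,
            cost_fracture=fr, cost_medication=med, cost_assessment=ass,
        )


@dataclass
class ScenarioResults:
    """Burden estimates for a scenario grid plus net benefits vs status quo."""

    estimates: dict[str, dict[tuple[str, int], BurdenEstimate]]
    aggregates: dict[str, dict[int, BurdenEstimate]]
    net_benefits: dict[str, dict[tuple[str, int], NetBenefit]]
    specs: dict[str, InterventionSpec]

    @property
    def labels(self) -> list[str]:
        return list(self.estimates)

    def to_frame(self) -> pd.DataFrame:
        """Tidy frame: one row per scenario × country (incl. aggregate) × year."""
        rows = []
        for label, ests in self.estimates.items():
            pool = list(ests.values()) + list(self.aggregates[label].values())
            for e in pool:
                nb = self.net_benefits.get(label, {}).get((e.country_code, e.year))
                rows.append(
                    {
                        "scenario": label,
                        "country_code": e.country_code,
                        "year": e.year,
                        "population": e.population,
                        "fractures_hip": e.fractures_by_type[FractureType.HIP],
                        "fractures_vertebral": e.fractures_by_type[FractureType.VERTEBRAL],
                        "fractures_nhnv": e.fractures_by_type[FractureType.NHNV],
                        "fractures_total": e.fracture_total,
                        "fractures_per_100k": e.per_100k_fractures,
                        "cost_fracture_m": e.cost_fracture,
                        "cost_medication_m": e.cost_medication,
                        "cost_assessment_m": e.cost_assessment,
                        "cost_total_m": e.cost_total,
                        "cost_per_100k_m": e.per_100k_cost,
                        "delta_fractures": nb.delta_fractures if nb else 0.0,
                        "delta_cost_m": nb.delta_cost if nb else 0.0,
                        "pct_fractures": nb.pct_fractures if nb else 0.0,
                        "pct_cost": nb.pct_cost if nb else 0.0,
                    }
                )
        return (
            pd.DataFrame(rows)
            .sort_values(["scenario", "country_code", "year"])
            .reset_index(drop=True)
        )

    def net_benefit_frame(self) -> pd.DataFrame:
        df = self.to_frame()
        return df[df.scenario != STATUS_QUO_LABEL][
            ["scenario", "country_code", "year",
             "delta_fractures", "delta_cost_m", "pct_fractures", "pct_cost"]
        ].reset_index(drop=True)


class FractureBurdenResults:
    """Calibrated model: estimates, diagnostics, projection and plotting."""

    def __init__(
        self,
        model: FractureBurdenModel,
        profiles: dict[tuple[str, int], RiskProfile],
        cost_scales: dict[tuple[str, int], float],
        records: list[CalibrationRecord],
    ) -> None:
        self.model = model
        self.profiles = profiles
        self.cost_scales = cost_scales
        self.records = records

    # -- diagnostics --------------------------------------------------------

    def calibration_report(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            rows.append(
                {
                    "country_code": r.country_code,
                    "year": r.year,
                    "base_hip": r.baseline[FractureType.HIP],
                    "base_vertebral": r.baseline[FractureType.VERTEBRAL],
                    "base_nhnv": r.baseline[FractureType.NHNV],
                    "at_risk_share": r.at_risk_share,
                    "at_risk_multiplier": r.at_risk_multiplier,
                    "cost_scale": r.cost_scale,
                    "fracture_residual_per_100k": r.fracture_residual_per_100k,
                    "cost_residual_per_100k": r.cost_residual_per_100k,
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        rep = self.calibration_report()
        lines = [
            "Osteoporotic fracture burden model — calibration summary",
            "=" * 60,
            f"countries: {len(self.model.countries)}   "
            f"years: {', '.join(map(str, self.model.years))}",
            f"status quo: assessment {self.model.assumptions.assessment_rate_sq:.0%}, "
            f"adherence {self.model.assumptions.adherence_sq:.0%}",
            f"at-risk share {self.model.at_risk_share:.2f}, "
            f"multiplier {self.model.at_risk_multiplier:.1f}",
            "",
            rep.to_string(
                index=False,
                float_format=lambda x: f"{x:.6g}",
            ),
            "",
            f"max |fracture residual| = "
            f"{rep.fracture_residual_per_100k.abs().max():.2e} per 100k",
            f"max |cost residual| = {rep.cost_residual_per_100k.abs().max():.2e} "
            f"€M per 100k",
        ]
        return "\n".join(lines)

    # -- projection ---------------------------------------------------------

    def project(
        self, spec: InterventionSpec | None = None
    ) -> dict[tuple[str, int], BurdenEstimate]:
        """Burden estimates per country-year under ``spec`` (status quo if None)."""
        out: dict[tuple[str, int], BurdenEstimate] = {}
        for (cc, yr), profile in self.profiles.items():
            params = self.model.countries[cc]
            if spec is None:
                rates = status_quo_rates(self.model.assumptions, params)
            else:
                rates = apply_intervention(spec, self.model.assumptions, params)
            out[(cc, yr)] = self.model._estimate(
                cc, yr, profile, rates, self.cost_scales[(cc, yr)]
            )
        return out

    def run_scenarios(
        self, specs: list[InterventionSpec] | None = None
    ) -> ScenarioResults:
        """Run the scenario grid (default: 3 levers × 10/50/100%) plus status quo."""
        if specs is None:
            specs = default_scenario_grid()
        specs = [s.with_label() for s in specs]
        labels = [s.label for s in specs]
        if len(set(labels)) != len(labels) or STATUS_QUO_LABEL in labels:
            raise ValueError("scenario labels must be unique and not 'status_quo'")
        estimates = {STATUS_QUO_LABEL: self.project(None)}
        spec_map: dict[str, InterventionSpec] = {}
        for s in specs:
            estimates[s.label] = self.project(s)
            spec_map[s.label] = s
        aggregates = {
            label: {
                yr: aggregate(
                    [e for e in ests.values() if e.year == yr], self.model.population
                )
                for yr in self.model.years
            }
            for label, ests in estimates.items()
        }
        nbs: dict[str, dict[tuple[str, int], NetBenefit]] = {}
        for label in spec_map:
            nb: dict[tuple[str, int], NetBenefit] = {}
            for key, est in estimates[label].items():
                nb[key] = net_benefit(estimates[STATUS_QUO_LABEL][key], est)
            for yr, agg in aggregates[label].items():
                nb[(AGGREGATE_CODE, yr)] = net_benefit(
                    aggregates[STATUS_QUO_LABEL][yr], agg
                )
            nbs[label] = nb
        return ScenarioResults(
            estimates=estimates, aggregates=aggregates,
            net_benefits=nbs, specs=spec_map,
        )

    # -- plotting -----------------------------------------------------------

    def plot_burden(self, scenarios: ScenarioResults | None = None, ax=None):
        """Line chart of aggregate annual fractures per year, per scenario."""
        import matplotlib.pyplot as plt

        scen = scenarios or self.run_scenarios()
        if ax is None:
            _, ax = plt.subplots(figsize=(7, 4.5))
        years = list(self.model.years)
        for label, per_year in scen.aggregates.items():
            ax.plot(
                years,
                [per_year[y].fracture_total / 1e6 for y in years],
                marker="o",
                label=label,
            )
        ax.set_xlabel("year")
        ax.set_ylabel("annual fractures (millions)")
        ax.set_title("Projected annual osteoporotic fractures, women ≥70")
        ax.legend(fontsize=8)
        return ax
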