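"""Report rendering and the config-driven pipeline (load → calibrate → scenarios).

Rendered tables mirror the published layout: an absolute-burden table with
per-100,000 sub-rows, and a net-benefit table showing "Δ (relative %)" with
spaced minus signs (e.g. ``− 217,843 (− 17.6%)``).  The pipeline writes a
tidy CSV, the rendered tables and a machine-readable JSON manifest (config
hash, seed, version); identical configs produce byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Any

import yaml

from . import __version__
from .burden import AGGREGATE_CODE, round_half_away
from .inputs import GlobalAssumptions
from .interventions import AssessmentMode, InterventionSpec, Lever, default_scenario_grid
from .model import STATUS_QUO_LABEL, FractureBurdenModel, ScenarioResults

logger = logging.getLogger(__name__)

DEFAULT_CONFIG: dict[str, Any] = {
    "inputs": {"country_params": None, "population": None, "burden": None},
    "assumptions": {"assessment_rate_sq": 0.25, "adherence_sq": 0.40},
    "profile": {"at_risk_share": 0.30, "at_risk_multiplier": 4.0},
    "options": {
        "nonadherent_efficacy": 0.0,
        "med_cost_scaled_by_adherence": False,
        "assessment_mode": "relative",
    },
    "scenarios": None,  # None -> the default 9-scenario grid; [] -> status quo only
    "seed": 0,
}


def load_config(path: str | Path | None) -> dict[str, Any]:
    """Read a YAML/JSON config, layered over the documented defaults."""
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise ValueError(f"config {path} must be a mapping")
        for key, value in user.items():
            if isinstance(value, dict) and isinstance(cfg.get(key), dict):
                cfg[key].update(value)
            else:
                cfg[key] = value
    return cfg


def scenario_specs_from_config(cfg: dict[str, Any]) -> list[InterventionSpec]:
    mode = AssessmentMode(cfg["options"].get("assessment_mode", "relative"))
    raw = cfg.get("scenarios")
    if raw is None:
        return default_scenario_grid(mode)
    specs = []
    for item in raw:
        specs.append(
            InterventionSpec(
                lever=Lever(item["lever"]),
                improvement=float(item["improvement"]),
                assessment_mode=AssessmentMode(item.get("assessment_mode", mode)),
                label=item.get("label", ""),
            ).with_label()
        )
    return specs


def model_from_config(cfg: dict[str, Any]) -> FractureBurdenModel:
    inputs = cfg.get("inputs", {})
    return FractureBurdenModel.from_tables(
        inputs.get("country_params"),
        inputs.get("population"),
        inputs.get("burden"),
        assumptions=GlobalAssumptions(**cfg["assumptions"]),
        at_risk_share=cfg["profile"]["at_risk_share"],
        at_risk_multiplier=cfg["profile"]["at_risk_multiplier"],
        nonadherent_efficacy=cfg["options"]["nonadherent_efficacy"],
        med_cost_scaled_by_adherence=cfg["options"]["med_cost_scaled_by_adherence"],
    )


def run_scenarios(
    config: str | Path | dict[str, Any] | None = None,
    out_dir: str | Path | None = None,
    fmt: str = "csv",
) -> ScenarioResults:
    """Full pipeline: load inputs, calibrate, run the scenario grid, write outputs."""
    cfg = config if isinstance(config, dict) else load_config(config)
    model = model_from_config(cfg)
    results = model.fit().run_scenarios(scenario_specs_from_config(cfg))
    if out_dir is not None:
        write_outputs(results, cfg, out_dir, fmt=fmt)
    return results


def write_outputs(
    results: ScenarioResults,
    cfg: dict[str, Any],
    out_dir: str | Path,
    fmt: str = "csv",
) -> list[Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    df = results.to_frame()
    if fmt in ("csv", "markdown"):
        path = out / "burden.csv"
        df.to_csv(path, index=False, float_format="%.6f")
        written.append(path)
        nb_path = out / "net_benefit.csv"
        results.net_benefit_frame().to_csv(nb_path, index=False, float_format="%.6f")
        written.append(nb_path)
    if fmt == "markdown":
        path = out / "tables.md"
        path.write_text(render_tables(results))
        written.append(path)
    if fmt == "json":
        path = out / "burden.json"
        path.write_text(df.to_json(orient="records", double_precision=6))
        written.append(path)
    manifest = {
        "version": __version__,
        "seed": cfg.get("seed", 0),
        "config_sha256": hashlib.sha256(
            json.dumps(cfg, sort_keys=True).encode()
        ).hexdigest(),
        "scenarios": results.labels,
        "outputs": [p.name for p in written],
    }
    mpath = out / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    written.append(mpath)
    logger.info("wrote %d files to %s (config %s)", len(written), out,
                manifest["config_sha256"][:12])
    return written


# ---------------------------------------------------------------------------
# rendering


def _signed(value: float, decimals: int = 0) -> str:
    """Format with a spaced sign, thousands separators: '− 217,843'."""
    v = round_half_away(value, decimals)
    sign = "− " if v < 0 else ("+ " if v > 0 else "")
    if decimals == 0:
        return f"{sign}{abs(v):,.0f}"
    return f"{sign}{abs(v):,.{decimals}f}"


def render_tables(results: ScenarioResults) -> str:
    """Markdown rendering of the status-quo burden and net-benefit tables."""
    if not results.estimates:
        raise ValueError("no results to render")
    years = sorted({yr for _, yr in results.estimates[STATUS_QUO_LABEL]})
    sq = results.estimates[STATUS_QUO_LABEL]
    agg = results.aggregates[STATUS_QUO_LABEL]
    countries = sorted({cc for cc, _ in sq})
    lines = [
        "## Projected population, annual fractures and costs of care (status quo)",
        "",
        "| Country | Measure | " + " | ".join(map(str, years)) + " |",
        "|---" * (len(years) + 2) + "|",
    ]

    def _rows(label, ests):
        pop = " | ".join(f"{ests[y].population:,}" for y in years)
        fr = " | ".join(f"{round_half_away(ests[y].fracture_total):,.0f}" for y in years)
        fr100 = " | ".join(f"{round_half_away(ests[y].per_100k_fractures):,.0f}" for y in years)
        cost = " | ".join(f"€{round_half_away(ests[y].cost_total):,.0f}" for y in years)
        c100 = " | ".join(f"€{round_half_away(ests[y].per_100k_cost, 1):.1f}" for y in years)
        lines.append(f"| {label} | population | {pop} |")
        lines.append(f"| {label} | fractures | {fr} |")
        lines.append(f"| {label} | fractures /100,000 | {fr100} |")
        lines.append(f"| {label} | costs, €M | {cost} |")
        lines.append(f"| {label} | costs /100,000, €M | {c100} |")

    for cc in countries:
        _rows(cc, {y: sq[(cc, y)] for y in years})
    _rows("Total", agg)

    scenario_labels = [l for l in results.labels if l != STATUS_QUO_LABEL]
    if scenario_labels:
        lines += [
            "",
            "## Net benefits from status quo (relative percentage reduction)",
            "",
            "| Intervention | Outcome | " + " | ".join(map(str, years)) + " |",
            "|---" * (len(years) + 2) + "|",
        ]
        for label in scenario_labels:
            nb = results.net_benefits[label]
            fr = " | ".join(
                f"{_signed(nb[(AGGREGATE_CODE, y)].delta_fractures)} "
                f"({_signed(nb[(AGGREGATE_CODE, y)].pct_fractures, 1)}%)"
                for y in years
            )
            cost = " | ".join(
                f"{_signed(nb[(AGGREGATE_CODE, y)].delta_cost)} "
                f"({_signed(nb[(AGGREGATE_CODE, y)].pct_cost, 1)}%)"
                for y in years
            )
            lines.append(f"| {label} | fractures | {fr} |")
            lines.append(f"| {label} | costs, €M | {cost} |")
    return "\n".join(lines) + "\n"
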