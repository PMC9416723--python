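"""Full tiered assessment runs and machine-readable reports.

The conceptual flow is: screening on the common metabolites (Tier S) →
substance-specific assessment (Tier I) → combined potency-weighted
refinement (Tier C) → optional probabilistic refinement.  Refinement stages
run only where an upstream concern flag exists, and every Tier-S concern is
either followed up or carries an explicit "not refined" note, so the flow is
auditable from the report alone.
"""

from __future__ import annotations

import datetime as _dt
import logging
from pathlib import Path
from typing import Any, Mapping, Optional, Union

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict

from . import __version__
from .errors import HbmError
from .exposure import ExposureSummary, load_default_exposure, read_exposure_table
from .guidance import screening_values
from .probabilistic import (
    BELGIAN_EXPOSURE_LOGLOGISTIC,
    FUE_WEIBULL,
    McSettings,
    loglogistic,
    mc_exceedance,
    weibull,
)
from .registry import Registry, load_registry
from .tiers import (
    CombinedAssessment,
    DEFAULT_ALLOCATION,
    RcrResult,
    Tier,
    contribution_to_3pba,
    refined_combined_rcr,
    run_tier_i,
    run_tier_s,
    sum_rcrs,
    tier_i_guidance,
)

log = logging.getLogger(__name__)

PathLike = Union[str, Path]

DEFAULT_CONFIG: dict[str, Any] = {
    "registry": {},
    "exposure": {"path": None},
    "tiers": {
        "residual_substance": "tau-fluvalinate",
        "reference_substance": "lambda-cyhalothrin",
        "allocation": dict(DEFAULT_ALLOCATION),
        "contributing_substances": {
            "lambda-cyhalothrin": "ClF3CA",
            "cypermethrin": "DCCA",
            "deltamethrin": "DBCA",
        },
    },
    "monte_carlo": {"enabled": False, "n_iterations": 10_000},
    "output": {"timestamp": False},
}


class TieredReport(BaseModel):
    model_config = ConfigDict(frozen=True)

    metadata: dict[str, Any]
    tier_s: list[RcrResult]
    tier_i: list[RcrResult]
    tier_c: list[CombinedAssessment]
    sum_of_rcrs: dict[str, float]
    probabilistic: list[dict[str, Any]]
    notes: list[str]
    errors: list[str] = []


def _merge_config(user: Optional[Mapping[str, Any]]) -> dict[str, Any]:
    cfg = {k: (dict(v) if isinstance(v, dict) else v) for k, v in DEFAULT_CONFIG.items()}
    for section, value in (user or {}).items():
        if isinstance(value, Mapping) and isinstance(cfg.get(section), dict):
            cfg[section].update(value)
        else:
            cfg[section] = value
    return cfg


def load_config(path: PathLike) -> dict[str, Any]:
    with open(path, encoding="utf-8") as fh:
        return _merge_config(yaml.safe_load(fh) or {})


def run_full_assessment(
    config: Optional[Union[PathLike, Mapping[str, Any]]] = None,
    seed: Optional[int] = None,
) -> TieredReport:
    """Execute S → I → C (and optionally the Monte Carlo refinement) in order.

    ``config`` is a YAML path or mapping with sections
    ``{registry, exposure, tiers, monte_carlo, output}``; defaults reproduce
    the published settings (worst-case 9% excretion fraction, n=10,000
    iterations, residual attributed to tau-fluvalinate, reference substance
    lambda-cyhalothrin).  Deterministic given the seed.
    """
    if config is None or isinstance(config, Mapping):
        cfg = _merge_config(config)
    else:
        cfg = load_config(config)
    if seed is None:
        seed = int(cfg.get("monte_carlo", {}).get("seed", 0))

    notes: list[str] = []
    errors: list[str] = []
    registry = load_registry(**{k: v for k, v in cfg["registry"].items() if v})
    exposure_path = cfg["exposure"].get("path")
    summaries = (
        read_exposure_table(exposure_path) if exposure_path else load_default_exposure()
    )
    if not summaries:
        notes.append("exposure table is empty; nothing to assess")

    populations = sorted({s.population_id for s in summaries})
    tier_s: list[RcrResult] = []
    tier_i: list[RcrResult] = []
    tier_c: list[CombinedAssessment] = []
    sums: dict[str, float] = {}

    for population_id in populations:
        pop_summaries = [s for s in summaries if s.population_id == population_id]
        scr = screening_values(registry, population_id, adopted=True)
        for biomarker, gv in scr.items():
            log.info(
                "screening value %s/%s = %.4g µg/L (raw %.4g, basis %s, fue %.2g)",
                biomarker, population_id, gv.value, gv.raw_value,
                gv.basis_substance_id, gv.fue_used,
            )
        s_results = run_tier_s(pop_summaries, scr)
        tier_s.extend(s_results)
        concern_studies = sorted({r.study_id for r in s_results if r.concern})
        if not concern_studies:
            notes.append(
                f"population {population_id!r}: no screening concern; "
                "assessment complete after Tier S"
            )
            continue

        gvs = tier_i_guidance(registry, population_id)
        if any(k[1] == "cyfluthrin" for k in gvs):
            notes.append(
                f"population {population_id!r}: cyfluthrin compared against the "
                "conservative 4-FPBA screening value (single-volunteer "
                "toxicokinetic basis)"
            )
        i_results = run_tier_i(pop_summaries, gvs)
        tier_i.extend(i_results)
        try:
            sums.update(sum_rcrs(i_results, cfg["tiers"]["allocation"]))
        except HbmError as exc:
            errors.append(f"sum of RCRs ({population_id}): {exc}")

        for study_id in concern_studies:
            assessment = _tier_c_for_study(
                study_id, population_id, pop_summaries, s_results, i_results,
                registry, cfg["tiers"], notes,
            )
            if assessment is not None:
                tier_c.append(assessment)
            else:
                notes.append(
                    f"study {study_id!r} ({population_id}): screening concern "
                    "not refined (no usable common-metabolite percentile)"
                )

    probabilistic: list[dict[str, Any]] = []
    if cfg["monte_carlo"].get("enabled"):
        settings = McSettings(
            n_iterations=int(cfg["monte_carlo"].get("n_iterations", 10_000)),
            seed=seed,
            scenario=cfg["monte_carlo"].get("scenario", "single_most_toxic"),
        )
        result = mc_exceedance(
            loglogistic(**BELGIAN_EXPOSURE_LOGLOGISTIC),
            weibull(**FUE_WEIBULL),
            registry,
            settings,
        )
        probabilistic.append(
            {
                "scenario": settings.scenario,
                "n_iterations": settings.n_iterations,
                "seed": settings.seed,
                "exceedance_probability": result.exceedance_probability,
                "sample_quantiles": result.sample_quantiles,
                "diagnostics": result.diagnostics,
            }
        )

    metadata: dict[str, Any] = {
        "package_version": __version__,
        "seed": seed,
        "populations": populations,
        "n_summaries": len(summaries),
    }
    if cfg["output"].get("timestamp"):
        metadata["timestamp"] = _dt.datetime.now(_dt.timezone.utc).isoformat()

    return TieredReport(
        metadata=metadata,
        tier_s=tier_s,
        tier_i=tier_i,
        tier_c=tier_c,
        sum_of_rcrs=sums,
        probabilistic=probabilistic,
        notes=notes,
        errors=errors,
    )


def _tier_c_for_study(
    study_id: str,
    population_id: str,
    summaries: list[ExposureSummary],
    s_results: list[RcrResult],
    i_results: list[RcrResult],
    registry: Registry,
    tiers_cfg: Mapping[str, Any],
    notes: list[str],
) -> Optional[CombinedAssessment]:
    s_row = next(
        (
            r
            for r in s_results
            if r.study_id == study_id and r.biomarker_id == "3-PBA" and r.rcr is not None
        ),
        None,
    )
    if s_row is None:
        return None
    contributions: dict[str, float] = {}
    for substance, biomarker in tiers_cfg["contributing_substances"].items():
        row = next(
            (
                r
                for r in i_results
                if r.study_id == study_id
                and r.substance_id == substance
                and r.biomarker_id == biomarker
            ),
            None,
        )
        if row is None or row.rcr is None:
            notes.append(
                f"study {study_id!r}: no {biomarker} result for {substance}; "
                "its contribution is treated as part of the residual"
            )
            continue
        contributions[substance] = contribution_to_3pba(
            substance, row.rcr, population_id, registry
        )
    measured = s_row.exposure_p95
    total = sum(contributions.values())
    if total > measured:
        notes.append(
            f"study {study_id!r}: selective-metabolite contributions "
            f"({total:.3g}) exceed the measured common-metabolite level "
            f"({measured:.3g}); contributions rescaled is NOT applied — "
            "study left unrefined"
        )
        return None
    return refined_combined_rcr(
        screening_rcr=s_row.rcr,
        measured_3pba=measured,
        contributions=contributions,
        residual_substance_id=tiers_cfg["residual_substance"],
        registry=registry,
        reference_substance_id=tiers_cfg["reference_substance"],
        study_id=study_id,
        population_id=population_id,
        note=f"residual attributed to {tiers_cfg['residual_substance']}",
    )


# ---------------------------------------------------------------------------
# serialisation


def write_report(report: TieredReport, path: PathLike, format: str = "json") -> Path:
    """Write a report as ``json`` (lossless round trip), ``csv-bundle``
    (one file per tier in a directory) or ``markdown``."""
    path = Path(path)
    if format == "json":
        path.write_text(report.model_dump_json(indent=2), encoding="utf-8")
        return path
    if format == "csv-bundle":
        path.mkdir(parents=True, exist_ok=True)
        pd.DataFrame([r.model_dump() for r in report.tier_s]).to_csv(
            path / "tier_s.csv", index=False
        )
        pd.DataFrame([r.model_dump() for r in report.tier_i]).to_csv(
            path / "tier_i.csv", index=False
        )
        pd.DataFrame([r.model_dump() for r in report.tier_c]).to_csv(
            path / "tier_c.csv", index=False
        )
        return path
    if format == "markdown":
        path.write_text(render_markdown(report), encoding="utf-8")
        return path
    raise ValueError(f"unknown report format {format!r}")


def read_report(path: PathLike) -> TieredReport:
    return TieredReport.model_validate_json(Path(path).read_text(encoding="utf-8"))


def _fmt(rcr: Optional[float]) -> str:
    return "NR" if rcr is None else f"{rcr:.3g}"


def render_markdown(report: TieredReport) -> str:
    """Human-readable report with a published-style Tier-I matrix."""
    lines = ["# Tiered pyrethroid biomonitoring risk assessment", ""]
    lines.append(f"Package version {report.metadata.get('package_version')}, "
                 f"seed {report.metadata.get('seed')}.")
    lines.append("")
    lines.append("## Tier S — screening")
    lines.append("")
    lines.append("| study | population | biomarker | p95 (µg/L) | screening value | RCR | concern |")
    lines.append("|---|---|---|---|---|---|---|")
    for r in report.tier_s:
        p95 = "NR" if r.exposure_p95 is None else f"{r.exposure_p95:g}"
        lines.append(
            f"| {r.study_id} | {r.population_id} | {r.biomarker_id} | {p95} "
            f"| {r.gv:g} | {_fmt(r.rcr)} | {'yes' if r.concern else 'no'} |"
        )
    if report.tier_i:
        lines += ["", "## Tier I — substance-specific RCRs", ""]
        pairs = sorted(
            {(r.biomarker_id, r.substance_id) for r in report.tier_i},
            key=lambda t: (t[0], t[1]),
        )
        header = " | ".join(f"{b} as {s}" for b, s in pairs)
        lines.append(f"| study | population | {header} |")
        lines.append("|---" * (2 + len(pairs)) + "|")
        studies = sorted({(r.study_id, r.population_id) for r in report.tier_i})
        by_key = {
            (r.study_id, r.biomarker_id, r.substance_id): r for r in report.tier_i
        }
        for study_id, population_id in studies:
            cells = []
            for b, s in pairs:
                row = by_key.get((study_id, b, s))
                cells.append("-" if row is None else _fmt(row.rcr))
            lines.append(f"| {study_id} | {population_id} | " + " | ".join(cells) + " |")
    if report.sum_of_rcrs:
        lines += ["", "## Sum of selective-metabolite RCRs", ""]
        for study_id, total in sorted(report.sum_of_rcrs.items()):
            lines.append(f"- {study_id}: {total:.2f}")
    if report.tier_c:
        lines += ["", "## Tier C — combined refinement", ""]
        for c in report.tier_c:
            lines.append(
                f"- {c.study_id} ({c.population_id}): screening RCR "
                f"{c.screening_rcr:.3f} → refined RCR {c.refined_rcr:.3f} "
                f"(residual {c.residual_amount:.2f} µg/L to {c.residual_substance_id})"
            )
    if report.probabilistic:
        lines += ["", "## Probabilistic refinement", ""]
        for p in report.probabilistic:
            lines.append(
                f"- scenario {p['scenario']}: exceedance probability "
                f"{p['exceedance_probability']:.4f} "
                f"(joint {p['diagnostics'].get('joint_exceedance', float('nan')):.4f})"
            )
    if report.notes:
        lines += ["", "## Notes", ""] + [f"- {n}" for n in report.notes]
    if report.errors:
        lines += ["", "## Errors", ""] + [f"- {e}" for e in report.errors]
    return "\n".join(lines) + "\n"
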