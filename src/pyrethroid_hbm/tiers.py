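"""Tiered risk characterisation engine.

Tier S compares the 95th percentile of a common metabolite (3-PBA, 4-FPBA or
their reported sum) with the conservative screening value; Tier I compares
each selective metabolite with the substance-specific guidance value; Tier C
refines a Tier-S concern by attributing the common-metabolite level to
individual substances and weighting each share by its relative potency
(ratio of the reference substance's ADI to its own).

The Risk Characterisation Ratio (RCR) is the exposure percentile divided by
the guidance value; RCR > 1 flags a potential concern requiring refinement.
"""

from __future__ import annotations

import itertools
from decimal import ROUND_HALF_UP, Decimal
from enum import Enum
from typing import Iterable, Mapping, Optional, Sequence

from pydantic import BaseModel, ConfigDict, model_validator

from .errors import AllocationError, ConsistencyError, DomainError
from .exposure import ExposureSummary
from .guidance import GuidanceValue, derive_hbm_gv, screening_values
from .registry import Registry

#: Worst-case molar excretion fraction of 3-PBA used throughout the combined
#: (Tier C) refinement.
SCREENING_FUE_3PBA = 0.09

#: Default attribution of shared selective biomarkers when summing Tier-I
#: ratios across substances (one substance per biomarker to avoid double
#: counting).
DEFAULT_ALLOCATION: dict[str, str] = {
    "ClF3CA": "lambda-cyhalothrin",
    "DCCA": "cypermethrin",
    "DBCA": "deltamethrin",
}

#: Biomarker → substance comparisons of the substance-specific assessment.
DEFAULT_TIER_I_PAIRS: tuple[tuple[str, str], ...] = (
    ("ClF3CA", "lambda-cyhalothrin"),
    ("ClF3CA", "bifenthrin"),
    ("DBCA", "deltamethrin"),
    ("DCCA", "cypermethrin"),
    ("DCCA", "permethrin"),
    ("4-FPBA", "cyfluthrin"),
)


class Tier(str, Enum):
    S = "S"
    I = "I"
    C = "C"


class RcrResult(BaseModel):
    model_config = ConfigDict(frozen=True)

    study_id: str
    country: str = ""
    population_id: str
    biomarker_id: str
    substance_id: Optional[str] = None
    exposure_p95: Optional[float] = None
    gv: float
    rcr: Optional[float] = None
    tier: Tier
    concern: bool = False
    note: str = ""

    @model_validator(mode="after")
    def _check(self) -> "RcrResult":
        if self.rcr is not None:
            expected = self.exposure_p95 / self.gv
            if abs(self.rcr - expected) > 1e-12 * max(1.0, abs(expected)):
                raise ValueError("rcr must equal exposure_p95 / gv to full precision")
            if self.concern != (self.rcr > 1):
                raise ValueError("concern flag must mirror rcr > 1")
        return self


class CombinedAssessment(BaseModel):
    model_config = ConfigDict(frozen=True)

    study_id: str
    population_id: str
    screening_rcr: float
    measured_3pba: float
    contributions: dict[str, float]
    residual_substance_id: str
    residual_amount: float
    potencies: dict[str, float]
    reference_substance_id: str
    refined_rcr: float
    note: str = ""

    @model_validator(mode="after")
    def _check(self) -> "CombinedAssessment":
        if any(v < 0 for v in self.contributions.values()) or self.residual_amount < 0:
            raise ValueError("contributions and residual must be non-negative")
        total = sum(self.contributions.values()) + self.residual_amount
        if abs(total - self.measured_3pba) > 1e-9 * max(1.0, self.measured_3pba):
            raise ValueError(
                "contributions plus residual must equal the measured common-"
                f"metabolite level ({total} vs {self.measured_3pba})"
            )
        ref_potency = self.potencies.get(self.reference_substance_id)
        if ref_potency is not None and abs(ref_potency - 1.0) > 1e-12:
            raise ValueError("the reference substance must have potency 1")
        return self


def compute_rcr(exposure_p95: float, gv: float) -> float:
    """Exact quotient of the exposure percentile and the guidance value."""
    if not gv > 0:
        raise DomainError(f"guidance value must be positive, got {gv}")
    if not exposure_p95 > 0:
        raise DomainError(f"exposure percentile must be positive, got {exposure_p95}")
    return exposure_p95 / gv


def round_printed(value: float, decimals: int) -> float:
    """Half-up rounding used when comparing against published tables."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# Tier S


def run_tier_s(
    summaries: Sequence[ExposureSummary],
    screening_gvs: Mapping[str, GuidanceValue],
) -> list[RcrResult]:
    """Screening ratios for every (study, common-metabolite) with a 95th percentile.

    A reported sum of common metabolites (``"3-PBA+4-FPBA"``) is compared
    against the 3-PBA screening value, which is valid for the sum because the
    second component's screening value is higher.  Populations with a missing
    p95 are skipped with a note-carrying result.
    """
    results: list[RcrResult] = []
    for s in summaries:
        gv_entry = screening_gvs.get(s.biomarker_id)
        if gv_entry is None and s.is_sum:
            first = s.biomarker_id.split("+")[0]
            gv_entry = screening_gvs.get(first)
        if gv_entry is None:
            continue
        if s.p95 is None:
            results.append(
                RcrResult(
                    study_id=s.study_id, country=s.country,
                    population_id=s.population_id, biomarker_id=s.biomarker_id,
                    gv=gv_entry.value, tier=Tier.S,
                    note="p95 not reported; excluded from screening",
                )
            )
            continue
        rcr = compute_rcr(s.p95, gv_entry.value)
        results.append(
            RcrResult(
                study_id=s.study_id, country=s.country,
                population_id=s.population_id, biomarker_id=s.biomarker_id,
                exposure_p95=s.p95, gv=gv_entry.value, rcr=rcr, tier=Tier.S,
                concern=rcr > 1,
            )
        )
    return results


# ---------------------------------------------------------------------------
# Tier I


def tier_i_guidance(
    registry: Registry, population_id: str
) -> dict[tuple[str, str], GuidanceValue]:
    """Guidance values backing the substance-specific comparisons.

    Cyfluthrin is compared against the conservative 4-FPBA *screening* value
    rather than its adopted guidance value (the toxicokinetic basis is a
    single volunteer, so the screening value is used as the conservative
    yardstick); every other substance uses its own proposed/adopted value.
    """
    from .guidance import substance_specific_gv

    out: dict[tuple[str, str], GuidanceValue] = {}
    scr = screening_values(registry, population_id, adopted=True)
    for biomarker, substance in DEFAULT_TIER_I_PAIRS:
        if substance == "cyfluthrin":
            out[(biomarker, substance)] = scr["4-FPBA"]
        else:
            out[(biomarker, substance)] = substance_specific_gv(
                substance, population_id, registry
            )
    return out


def run_tier_i(
    summaries: Sequence[ExposureSummary],
    gvs: Mapping[tuple[str, str], GuidanceValue],
    pairs: Iterable[tuple[str, str]] = DEFAULT_TIER_I_PAIRS,
) -> list[RcrResult]:
    """Substance-specific ratios for every (study, biomarker, substance) pair.

    A summary whose p95 is missing yields a result row marked not-reported
    (``rcr=None``) so the published table layout is preserved.
    """
    results: list[RcrResult] = []
    by_key = {
        (s.study_id, s.population_id, s.biomarker_id): s
        for s in summaries
        if not s.is_sum
    }
    study_pops = sorted(
        {(s.study_id, s.population_id, s.country) for s in summaries},
        key=lambda t: (t[1], t[0]),
    )
    for study_id, population_id, country in study_pops:
        for biomarker, substance in pairs:
            summary = by_key.get((study_id, population_id, biomarker))
            if summary is None:
                continue
            gv_entry = gvs.get((biomarker, substance))
            if gv_entry is None or gv_entry.population_id != population_id:
                continue
            if summary.p95 is None:
                results.append(
                    RcrResult(
                        study_id=study_id, country=country,
                        population_id=population_id, biomarker_id=biomarker,
                        substance_id=substance, gv=gv_entry.value, tier=Tier.I,
                        note="NR",
                    )
                )
                continue
            rcr = compute_rcr(summary.p95, gv_entry.value)
            results.append(
                RcrResult(
                    study_id=study_id, country=country,
                    population_id=population_id, biomarker_id=biomarker,
                    substance_id=substance, exposure_p95=summary.p95,
                    gv=gv_entry.value, rcr=rcr, tier=Tier.I, concern=rcr > 1,
                )
            )
    return results


def sum_rcrs(
    tier_i_results: Sequence[RcrResult],
    allocation: Mapping[str, str] = DEFAULT_ALLOCATION,
) -> dict[str, float]:
    """Per-study sum of selective-metabolite RCRs under a single-substance
    allocation of each shared biomarker (avoids double counting DCCA/ClF3CA).

    Not-reported biomarker terms are omitted; an allocation naming a
    substance with no Tier-I result for a biomarker that was assessed raises
    :class:`AllocationError`.  Keys are ``"study_id/population_id"`` (one
    study acronym can cover both a children and an adult population).
    """
    sums: dict[str, float] = {}
    keyfn = lambda r: (r.study_id, r.population_id)
    by_study = itertools.groupby(sorted(tier_i_results, key=keyfn), key=keyfn)
    for (study_id, population_id), group_iter in by_study:
        group = list(group_iter)
        total = 0.0
        seen_any = False
        for biomarker, substance in allocation.items():
            rows = [r for r in group if r.biomarker_id == biomarker]
            if not rows:
                continue
            chosen = [r for r in rows if r.substance_id == substance]
            if not chosen:
                raise AllocationError(
                    f"allocation maps {biomarker!r} to {substance!r} but study "
                    f"{study_id!r} has no Tier-I result for that substance"
                )
            if chosen[0].rcr is None:
                continue  # NR term omitted
            total += chosen[0].rcr
            seen_any = True
        if seen_any:
            sums[f"{study_id}/{population_id}"] = total
    return sums


# ---------------------------------------------------------------------------
# Tier C (combined refinement)


def gv_3pba_basis(substance_id: str, population_id: str, registry: Registry) -> float:
    """3-PBA-expressed guidance value of one substance at the worst-case 9%
    excretion fraction, using the substance's own ADI and molar mass (µg/L)."""
    sub = registry.require_assessable(substance_id)
    met = registry.metabolite("3-PBA")
    pop = registry.population(population_id)
    return derive_hbm_gv(
        sub.adi, sub.mw_parent, met.mw_metabolite, SCREENING_FUE_3PBA, pop.urine_volume
    )


def contribution_to_3pba(
    substance_id: str,
    tier_i_rcr: float,
    population_id: str,
    registry: Registry,
) -> float:
    """Maximum possible 3-PBA level (µg/L) attributable to one substance.

    The selective-metabolite RCR bounds the fraction of the substance's
    guidance-level exposure actually experienced; multiplying it by the
    substance's 3-PBA-expressed guidance value converts that bound into µg of
    3-PBA per litre.
    """
    if tier_i_rcr < 0:
        raise DomainError(f"RCR cannot be negative, got {tier_i_rcr}")
    return gv_3pba_basis(substance_id, population_id, registry) * tier_i_rcr


def relative_potencies(
    substance_ids: Iterable[str],
    registry: Registry,
    reference_substance_id: str = "lambda-cyhalothrin",
) -> dict[str, float]:
    """ADI-ratio potencies: potency_i = ADI_reference / ADI_i (reference = 1)."""
    ref = registry.substance(reference_substance_id)
    return {
        sid: ref.adi / registry.substance(sid).adi
        for sid in set(substance_ids) | {reference_substance_id}
    }


def refined_combined_rcr(
    screening_rcr: float,
    measured_3pba: float,
    contributions: Mapping[str, float],
    residual_substance_id: str,
    registry: Registry,
    reference_substance_id: str = "lambda-cyhalothrin",
    study_id: str = "",
    population_id: str = "children",
    note: str = "",
) -> CombinedAssessment:
    """Potency-weighted refinement of a screening RCR (Tier C).

    The measured common-metabolite level is split into per-substance
    contributions (from the selective biomarkers) plus a residual attributed
    to ``residual_substance_id``; the screening RCR is rescaled by the
    potency-weighted share of each part:

        refined = screening_rcr * Σ_i (amount_i / measured) * (ADI_ref / ADI_i)
    """
    if not measured_3pba > 0:
        raise DomainError("measured common-metabolite level must be positive")
    total_contrib = sum(contributions.values())
    if total_contrib > measured_3pba * (1 + 1e-12):
        raise ConsistencyError(
            f"contributions ({total_contrib:.4g} µg/L) exceed the measured "
            f"level ({measured_3pba:.4g} µg/L); they are maximum possible shares"
        )
    ref = registry.substance(reference_substance_id)
    min_adi = min(s.adi for s in registry.assessable_substances())
    if ref.adi > min_adi:
        raise DomainError(
            f"reference substance {reference_substance_id!r} must carry the "
            "minimum ADI among assessable substances"
        )
    residual = measured_3pba - total_contrib
    potencies = relative_potencies(
        list(contributions) + [residual_substance_id], registry, reference_substance_id
    )
    weighted = sum(
        amount / measured_3pba * potencies[sid] for sid, amount in contributions.items()
    )
    weighted += residual / measured_3pba * potencies[residual_substance_id]
    return CombinedAssessment(
        study_id=study_id,
        population_id=population_id,
        screening_rcr=screening_rcr,
        measured_3pba=measured_3pba,
        contributions=dict(contributions),
        residual_substance_id=residual_substance_id,
        residual_amount=residual,
        potencies=potencies,
        reference_substance_id=reference_substance_id,
        refined_rcr=screening_rcr * weighted,
        note=note,
    )


def required_contribution_fraction(gv: float, exposure: float) -> float:
    """Minimum fraction of the measured common metabolite that must stem from
    one substance for its guidance value to be exceeded (gv / exposure);
    values > 1 mean exceedance is impossible."""
    if not gv > 0 or not exposure > 0:
        raise DomainError("gv and exposure must be positive")
    return gv / exposure


def residual_attribution_sweep(
    screening_rcr: float,
    measured_3pba: float,
    contributions: Mapping[str, float],
    registry: Registry,
    residual_candidates: Sequence[str] = ("tau-fluvalinate", "lambda-cyhalothrin"),
    reference_substance_id: str = "lambda-cyhalothrin",
) -> dict[str, float]:
    """Refined RCR under each candidate attribution of the unexplained share."""
    return {
        candidate: refined_combined_rcr(
            screening_rcr, measured_3pba, contributions, candidate, registry,
            reference_substance_id,
        ).refined_rcr
        for candidate in residual_candidates
    }


def dcca_permethrin_share_sweep(
    screening_rcr: float,
    measured_3pba: float,
    dcca_p95: float,
    other_contributions: Mapping[str, float],
    registry: Registry,
    population_id: str = "children",
    shares: Sequence[float] = tuple(i / 10 for i in range(11)),
    residual_substance_id: str = "tau-fluvalinate",
    gv_dcca_cypermethrin: float = None,
    gv_dcca_permethrin: float = None,
) -> list[tuple[float, float]]:
    """Refined RCR as a function of the permethrin share of the DCCA level.

    A share ``s`` of the measured DCCA p95 is treated as permethrin-derived
    (lower potency) and the rest as cypermethrin-derived; returns
    ``[(share, refined_rcr), ...]`` without asserting any break-even point.
    """
    from .guidance import substance_specific_gv

    if gv_dcca_cypermethrin is None:
        gv_dcca_cypermethrin = substance_specific_gv(
            "cypermethrin", population_id, registry
        ).value
    if gv_dcca_permethrin is None:
        gv_dcca_permethrin = substance_specific_gv(
            "permethrin", population_id, registry
        ).value
    out = []
    for share in shares:
        contributions = dict(other_contributions)
        contributions["cypermethrin"] = contribution_to_3pba(
            "cypermethrin", dcca_p95 * (1 - share) / gv_dcca_cypermethrin,
            population_id, registry,
        )
        contributions["permethrin"] = contribution_to_3pba(
            "permethrin", dcca_p95 * share / gv_dcca_permethrin,
            population_id, registry,
        )
        out.append(
            (
                share,
                refined_combined_rcr(
                    screening_rcr, measured_3pba, contributions,
                    residual_substance_id, registry,
                    population_id=population_id,
                ).refined_rcr,
            )
        )
    return out
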