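"""Synthetic individual-level urinary biomarker data.

The assessment itself only ever sees aggregated percentile tables, but a
generator of individual-level concentrations with the assumed statistical
structure lets every pipeline stage be exercised end to end: generate a
cohort from known distributions, aggregate it to a percentile table with
bootstrap confidence intervals, and feed that table through the tiers.

Dependence between the common metabolite (3-PBA) and the selective
metabolites is modelled with a Gaussian copula on ranks — a shared latent
normal couples the columns at a chosen rank correlation while preserving the
requested marginals.  Within-individual mass-balance coupling (a person's
3-PBA being at least the sum of the attributable parts) is deliberately not
enforced: the aggregated pipeline never uses it.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator
from scipy import stats

from .errors import DomainError
from .exposure import ExposureSummary
from .probabilistic import DistributionSpec, quantile

#: Aggregation refuses below this cohort size: empirical tail percentiles of
#: a handful of observations are not meaningful.
MIN_AGGREGATION_N = 20

COMMON_BIOMARKER = "3-PBA"


class SyntheticCohortSpec(BaseModel):
    model_config = ConfigDict(frozen=True)

    n_individuals: int = Field(ge=1)
    population_id: str = "children"
    biomarker_dists: dict[str, DistributionSpec]
    correlation: Optional[float] = None
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "SyntheticCohortSpec":
        if not self.biomarker_dists:
            raise ValueError("at least one biomarker distribution is required")
        if self.correlation is not None and not (0 <= self.correlation < 1):
            raise ValueError("correlation must lie in [0, 1)")
        return self


def generate_cohort(spec: SyntheticCohortSpec) -> pd.DataFrame:
    """One row per individual, one column per biomarker, µg/L.

    Marginals follow the requested distributions; when ``correlation`` is
    set, a shared latent normal couples the common metabolite with every
    other column at that rank correlation (Gaussian copula).
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_individuals
    biomarkers = list(spec.biomarker_dists)
    r = spec.correlation
    columns: dict[str, np.ndarray] = {}
    if r is None or COMMON_BIOMARKER not in biomarkers:
        for b in biomarkers:
            u = rng.uniform(size=n)
            columns[b] = np.asarray(quantile(spec.biomarker_dists[b], _open_unit(u)))
    else:
        latent = rng.standard_normal(n)
        for b in biomarkers:
            if b == COMMON_BIOMARKER:
                z = latent
            else:
                z = r * latent + math.sqrt(1 - r * r) * rng.standard_normal(n)
            u = _open_unit(stats.norm.cdf(z))
            columns[b] = np.asarray(quantile(spec.biomarker_dists[b], u))
    return pd.DataFrame(columns, columns=biomarkers)


def _open_unit(u: np.ndarray) -> np.ndarray:
    eps = 1e-12
    return np.clip(u, eps, 1 - eps)


def aggregate_percentiles(
    cohort: pd.DataFrame,
    percentiles: Sequence[float] = (0.05, 0.5, 0.95),
    bootstrap_reps: int = 0,
    seed: Optional[int] = None,
    study_id: str = "synthetic",
    country: str = "synthetic",
    population_id: str = "children",
) -> list[ExposureSummary]:
    """Empirical percentiles per biomarker, optionally with bootstrap 95% CIs.

    Percentiles use linear interpolation of order statistics (the "type 7"
    convention).  With ``bootstrap_reps > 0`` a percentile bootstrap over
    individuals yields 95% confidence intervals for the 95th percentile.
    The output plugs directly into the tier engine.
    """
    n = len(cohort)
    if n < MIN_AGGREGATION_N:
        raise DomainError(
            f"refusing to aggregate {n} individuals; need at least {MIN_AGGREGATION_N}"
        )
    ps = np.asarray(percentiles, dtype=float)
    if np.any((ps <= 0) | (ps >= 1)):
        raise DomainError("percentiles must lie strictly inside (0, 1)")
    rng = np.random.default_rng(seed)
    out: list[ExposureSummary] = []
    for biomarker in cohort.columns:
        values = cohort[biomarker].to_numpy(dtype=float)
        keys = [f"p{int(round(100 * p)):02d}" for p in ps]
        pct = {k: float(np.quantile(values, p)) for k, p in zip(keys, ps)}
        ci95: dict[str, tuple[float, float]] = {}
        if bootstrap_reps > 0 and "p95" in pct:
            idx = rng.integers(0, n, size=(bootstrap_reps, n))
            boot = np.quantile(values[idx], 0.95, axis=1)
            lo, hi = np.quantile(boot, [0.025, 0.975])
            ci95["p95"] = (min(float(lo), pct["p95"]), max(float(hi), pct["p95"]))
        out.append(
            ExposureSummary(
                study_id=study_id,
                country=country,
                population_id=population_id,
                biomarker_id=str(biomarker),
                n=n,
                percentiles=pct,
                ci95=ci95,
                note="synthetic cohort aggregate",
            )
        )
    return out
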