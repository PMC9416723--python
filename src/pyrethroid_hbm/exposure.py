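"""Aggregated exposure summaries: percentile tables per study population.

The assessment consumes aggregated biomonitoring results — percentiles of the
urinary concentration of each biomarker (µg/L, not creatinine-adjusted) in
each study population — rather than individual-level data.  This module
reads, validates, writes and combines such tables.

File dialect (CSV): columns
``study_id,country,population,biomarker,n,p05,p50,p95,p95_lcl,p95_ucl,note``;
missing cells are empty or ``NR`` (not reported, e.g. the 95th percentile
could not be estimated due to low detection frequency).  ``NR`` becomes a
missing value, never zero.
"""

from __future__ import annotations

import math
import re
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd
from pydantic import BaseModel, ConfigDict, model_validator

from .errors import ExposureValidationError, PercentileSumError

PathLike = Union[str, Path]

_PCT_KEY = re.compile(r"^p(\d{2})$")


class ExposureSummary(BaseModel):
    """Percentiles of one biomarker's urinary concentration in one population."""

    model_config = ConfigDict(frozen=True)

    study_id: str
    country: str = ""
    population_id: str
    biomarker_id: str
    n: Optional[int] = None
    percentiles: dict[str, float] = {}
    ci95: dict[str, tuple[float, float]] = {}
    sampling_period: str = ""
    below_lod_flag: Optional[bool] = None
    note: str = ""
    is_sum: bool = False

    @model_validator(mode="after")
    def _check(self) -> "ExposureSummary":
        keyed = []
        for key, value in self.percentiles.items():
            m = _PCT_KEY.match(key)
            if not m:
                raise ValueError(f"percentile key {key!r} must look like 'p95'")
            if value < 0 or not math.isfinite(value):
                raise ValueError(f"{key} concentration must be finite and >= 0")
            keyed.append((int(m.group(1)), value))
        keyed.sort()
        for (pa, va), (pb, vb) in zip(keyed, keyed[1:]):
            if vb < va:
                raise ValueError(
                    f"percentiles must be non-decreasing: p{pa:02d}={va} > p{pb:02d}={vb}"
                )
        for key, (lo, hi) in self.ci95.items():
            if key not in self.percentiles:
                raise ValueError(f"ci95 given for missing percentile {key!r}")
            point = self.percentiles[key]
            if not (lo <= point <= hi):
                raise ValueError(
                    f"ci95 for {key} [{lo}, {hi}] does not bracket the estimate {point}"
                )
        return self

    def percentile(self, key: str) -> Optional[float]:
        return self.percentiles.get(key)

    @property
    def p95(self) -> Optional[float]:
        return self.percentiles.get("p95")


_COLUMNS = [
    "study_id", "country", "population", "biomarker", "n",
    "p05", "p50", "p95", "p95_lcl", "p95_ucl", "note",
]


def _cell(row, name) -> Optional[float]:
    value = row.get(name)
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    return float(value)


def read_exposure_table(path: PathLike) -> list[ExposureSummary]:
    """Read and validate an exposure CSV; ``NR``/empty cells become missing.

    Raises :class:`ExposureValidationError` with row-level diagnostics when
    any row has an unparseable or non-monotone percentile set.
    """
    try:
        df = pd.read_csv(
            path,
            dtype=str,
            keep_default_na=False,
        )
    except (OSError, pd.errors.ParserError) as exc:
        raise ExposureValidationError(f"{path}: {exc}") from exc
    missing_cols = [c for c in ("study_id", "population", "biomarker") if c not in df.columns]
    if missing_cols:
        raise ExposureValidationError(f"{path}: missing columns {missing_cols}")

    summaries: list[ExposureSummary] = []
    problems: list[str] = []
    for i, row in df.iterrows():
        rownum = i + 2  # header is line 1
        raw = {k: (row[k].strip() if k in df.columns else "") for k in _COLUMNS}
        numeric: dict[str, Optional[float]] = {}
        for field in ("n", "p05", "p50", "p95", "p95_lcl", "p95_ucl"):
            cell = raw[field]
            if cell == "" or cell.upper() == "NR":
                numeric[field] = None
                continue
            try:
                numeric[field] = float(cell)
            except ValueError:
                problems.append(f"row {rownum}: field {field!r} unparseable: {cell!r}")
                numeric[field] = None
        percentiles = {
            k: v for k, v in numeric.items() if k.startswith("p") and "_" not in k and v is not None
        }
        ci95 = {}
        if numeric["p95_lcl"] is not None and numeric["p95_ucl"] is not None and "p95" in percentiles:
            ci95["p95"] = (numeric["p95_lcl"], numeric["p95_ucl"])
        try:
            summaries.append(
                ExposureSummary(
                    study_id=raw["study_id"],
                    country=raw["country"],
                    population_id=raw["population"],
                    biomarker_id=raw["biomarker"],
                    n=int(numeric["n"]) if numeric["n"] is not None else None,
                    percentiles=percentiles,
                    ci95=ci95,
                    note=raw["note"],
                    is_sum="+" in raw["biomarker"],
                )
            )
        except ValueError as exc:
            problems.append(f"row {rownum}: {exc}")
    if problems:
        raise ExposureValidationError(
            f"{path}: {len(problems)} invalid row(s):\n  " + "\n  ".join(problems)
        )
    return summaries


def write_exposure_table(summaries: Sequence[ExposureSummary], path: PathLike) -> Path:
    """Write summaries in the standard dialect; missing percentiles become ``NR``."""
    records = []
    for s in summaries:
        rec = {
            "study_id": s.study_id,
            "country": s.country,
            "population": s.population_id,
            "biomarker": s.biomarker_id,
            "n": "" if s.n is None else s.n,
            "note": s.note,
        }
        for key in ("p05", "p50", "p95"):
            value = s.percentiles.get(key)
            rec[key] = "NR" if value is None else repr(value)
        lo_hi = s.ci95.get("p95")
        rec["p95_lcl"] = "NR" if lo_hi is None else repr(lo_hi[0])
        rec["p95_ucl"] = "NR" if lo_hi is None else repr(lo_hi[1])
        records.append(rec)
    df = pd.DataFrame.from_records(records, columns=_COLUMNS)
    path = Path(path)
    df.to_csv(path, index=False)
    return path


def load_default_exposure() -> list[ExposureSummary]:
    """The packaged aligned-studies fixture (2014–2021 children and adult studies)."""
    return read_exposure_table(
        str(resources.files("pyrethroid_hbm").joinpath("data", "exposure_hbm4eu.csv"))
    )


def sum_biomarker_summary(
    a: ExposureSummary,
    b: ExposureSummary,
    reported: Optional[ExposureSummary] = None,
) -> ExposureSummary:
    """Summary for the sum of two biomarkers (e.g. Σ(3-PBA + 4-FPBA)).

    Percentiles of sums are not sums of percentiles, so a reported sum
    percentile set must be supplied (``reported``) and is passed through
    verbatim.  The only additive shortcut taken is the exact identity: when
    one component is reported as zero at every percentile, the other
    component's percentiles are the sum's.
    """
    if a.study_id != b.study_id or a.population_id != b.population_id:
        raise PercentileSumError(
            "summaries belong to different study populations: "
            f"{a.study_id}/{a.population_id} vs {b.study_id}/{b.population_id}"
        )
    sum_id = f"{a.biomarker_id}+{b.biomarker_id}"
    if reported is not None:
        if reported.study_id != a.study_id or reported.population_id != a.population_id:
            raise PercentileSumError("reported sum belongs to a different study population")
        return reported.model_copy(update={"biomarker_id": sum_id, "is_sum": True})
    for component, other in ((a, b), (b, a)):
        if component.percentiles and all(v == 0.0 for v in component.percentiles.values()):
            return other.model_copy(update={"biomarker_id": sum_id, "is_sum": True})
    raise PercentileSumError(
        f"cannot form {sum_id} for {a.study_id}: percentiles of a sum are not "
        "sums of percentiles; supply the reported sum percentile row instead"
    )
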