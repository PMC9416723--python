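"""Typed store of substances, urinary biomarkers, excretion fractions and populations.

The registry holds everything the mass-balance derivation needs:

* ``SubstanceRecord`` — one pyrethroid active substance with its Acceptable
  Daily Intake (ADI, mg per kg body weight per day) and molar mass;
* ``MetaboliteRecord`` — one urinary biomarker with its molar mass and the
  parent substances it can originate from;
* ``ExcretionFraction`` — the molar fraction Fue of an ingested parent dose
  excreted in urine as a given metabolite, with a provenance basis;
* ``PopulationGroup`` — body-weight-adjusted daily urine volume (L/kg bw/day).

Molecular weights are not tabulated in regulatory summaries consistently, so
they ship here as named constants recomputed from the molecular formulas with
average atomic masses (see the packaged ``substances.csv``/``metabolites.csv``).
"""

from __future__ import annotations

import csv
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Union

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .errors import IntegrityError, PolicyError, RegistryLoadError, RegistryLookupError

PathLike = Union[str, Path]

#: Molar urinary excretion scenarios for the common metabolite 3-PBA:
#: worst case (lowest reported fraction), 5th percentile, geometric mean of
#: averaged study values, and geometric mean including cis/trans resolved data.
FUE_SCENARIOS: dict[str, float] = {
    "worst_case": 0.09,
    "p5": 0.11,
    "geomean": 0.21,
    "geomean_cis_trans": 0.31,
}


class FueBasis(str, Enum):
    measured_human = "measured_human"
    inferred = "inferred"
    worst_case = "worst_case"


class SubstanceRecord(BaseModel):
    model_config = ConfigDict(frozen=True)

    id: str
    adi: float = Field(gt=0, description="ADI, mg per kg bw per day")
    mw_parent: float = Field(gt=0, description="molar mass, g/mol")
    adi_source: str = ""
    approved_uses: tuple[str, ...] = ()
    assessable: bool = True


class MetaboliteRecord(BaseModel):
    model_config = ConfigDict(frozen=True)

    id: str
    mw_metabolite: float = Field(gt=0, description="molar mass, g/mol")
    parent_ids: tuple[str, ...] = ()
    isomer_note: str = ""


class ExcretionFraction(BaseModel):
    model_config = ConfigDict(frozen=True)

    substance_id: str
    metabolite_id: str
    fue: float = Field(gt=0, le=1, description="molar fraction in (0, 1]")
    basis: FueBasis
    source: str = ""


class PopulationGroup(BaseModel):
    model_config = ConfigDict(frozen=True)

    id: str
    urine_volume: float = Field(gt=0, description="L per kg bw per day")


class FueScenario(BaseModel):
    model_config = ConfigDict(frozen=True)

    id: str
    fue: float = Field(gt=0, le=1)


#: Preference order when several excretion fractions exist for one
#: substance–metabolite pair and no basis is requested explicitly.
_BASIS_PREFERENCE = (FueBasis.measured_human, FueBasis.inferred, FueBasis.worst_case)


class Registry(BaseModel):
    """Validated, cross-referenced store; construct via :func:`load_registry`."""

    model_config = ConfigDict(frozen=True)

    substances: dict[str, SubstanceRecord]
    metabolites: dict[str, MetaboliteRecord]
    fues: tuple[ExcretionFraction, ...]
    populations: dict[str, PopulationGroup]

    # -- lookups -----------------------------------------------------------
    def substance(self, substance_id: str) -> SubstanceRecord:
        try:
            return self.substances[substance_id]
        except KeyError:
            raise RegistryLookupError(f"unknown substance id: {substance_id!r}")

    def metabolite(self, metabolite_id: str) -> MetaboliteRecord:
        try:
            return self.metabolites[metabolite_id]
        except KeyError:
            raise RegistryLookupError(f"unknown metabolite id: {metabolite_id!r}")

    def population(self, population_id: str) -> PopulationGroup:
        try:
            return self.populations[population_id]
        except KeyError:
            raise RegistryLookupError(f"unknown population id: {population_id!r}")

    def fue(
        self,
        substance_id: str,
        metabolite_id: str,
        basis: Optional[FueBasis] = None,
    ) -> ExcretionFraction:
        """Excretion fraction for a substance→metabolite pair.

        With ``basis=None`` the most authoritative entry is returned
        (measured in humans, then inferred by read-across, then worst case).
        """
        candidates = [
            f
            for f in self.fues
            if f.substance_id == substance_id and f.metabolite_id == metabolite_id
        ]
        if basis is not None:
            candidates = [f for f in candidates if f.basis == basis]
        if not candidates:
            raise RegistryLookupError(
                f"no excretion fraction for pair ({substance_id!r}, {metabolite_id!r})"
                + (f" with basis {basis.value!r}" if basis else "")
            )
        candidates.sort(key=lambda f: _BASIS_PREFERENCE.index(f.basis))
        return candidates[0]

    def parents_with_adi(
        self, metabolite_id: str, include_non_assessable: bool = False
    ) -> list[SubstanceRecord]:
        """Parent substances of a biomarker that may enter a screening derivation.

        Substances flagged non-assessable (3-PBA is not considered a proper
        marker for etofenprox) are excluded unless explicitly requested.
        """
        met = self.metabolite(metabolite_id)
        parents = [self.substances[p] for p in met.parent_ids if p in self.substances]
        if not include_non_assessable:
            parents = [p for p in parents if p.assessable]
        return parents

    def assessable_substances(self) -> list[SubstanceRecord]:
        return [s for s in self.substances.values() if s.assessable]

    def require_assessable(self, substance_id: str) -> SubstanceRecord:
        sub = self.substance(substance_id)
        if not sub.assessable:
            raise PolicyError(
                f"{substance_id!r} is flagged non-assessable: no biomonitoring "
                "guidance derivation is defined for it"
            )
        return sub

    def mw_ratio(self, metabolite_id: str, substance_id: str) -> float:
        return mw_ratio(metabolite_id, substance_id, self)


def mw_ratio(metabolite_id: str, substance_id: str, registry: Registry) -> float:
    """Molar-mass ratio MW(metabolite) / MW(parent), dimensionless and > 0."""
    met = registry.metabolite(metabolite_id)
    sub = registry.substance(substance_id)
    return met.mw_metabolite / sub.mw_parent


# ---------------------------------------------------------------------------
# loading / writing


def _data_path(name: str) -> Path:
    return Path(str(resources.files("pyrethroid_hbm").joinpath("data", name)))


def _read_rows(path: Path) -> list[dict[str, str]]:
    try:
        with open(path, newline="", encoding="utf-8") as fh:
            return list(csv.DictReader(fh))
    except OSError as exc:
        raise RegistryLoadError(f"{path}: {exc}") from exc


def _parse_bool(value: str) -> bool:
    return value.strip().lower() in {"true", "1", "yes"}


def _build(model, row: dict, path: Path, rownum: int, **fields):
    try:
        return model(**fields)
    except ValidationError as exc:
        first = exc.errors()[0]
        field = ".".join(str(p) for p in first["loc"]) or "?"
        raise RegistryLoadError(
            f"{path}, row {rownum}, field {field!r}: {first['msg']}"
        ) from exc


def load_registry(
    substances: Optional[PathLike] = None,
    metabolites: Optional[PathLike] = None,
    fues: Optional[PathLike] = None,
    populations: Optional[PathLike] = None,
) -> Registry:
    """Load the registry from CSV/YAML files (packaged defaults when omitted).

    Raises
    ------
    RegistryLoadError
        On a schema violation, naming file, row and field.
    IntegrityError
        When a cross-reference (parent id, excretion-fraction pair) dangles.
    """
    sub_path = Path(substances) if substances else _data_path("substances.csv")
    met_path = Path(metabolites) if metabolites else _data_path("metabolites.csv")
    fue_path = Path(fues) if fues else _data_path("fues.csv")
    pop_path = Path(populations) if populations else _data_path("populations.yaml")

    subs: dict[str, SubstanceRecord] = {}
    for i, row in enumerate(_read_rows(sub_path), start=2):
        rec = _build(
            SubstanceRecord,
            row,
            sub_path,
            i,
            id=row.get("id", ""),
            adi=row.get("adi_mg_per_kg_bw_day", ""),
            mw_parent=row.get("mw_g_per_mol", ""),
            adi_source=row.get("adi_source", ""),
            approved_uses=tuple(
                u for u in (row.get("approved_uses") or "").split(";") if u
            ),
            assessable=_parse_bool(row.get("assessable", "true")),
        )
        if rec.id in subs:
            raise RegistryLoadError(
                f"{sub_path}, row {i}, field 'id': duplicate substance id {rec.id!r}"
            )
        subs[rec.id] = rec

    mets: dict[str, MetaboliteRecord] = {}
    for i, row in enumerate(_read_rows(met_path), start=2):
        rec = _build(
            MetaboliteRecord,
            row,
            met_path,
            i,
            id=row.get("id", ""),
            mw_metabolite=row.get("mw_g_per_mol", ""),
            parent_ids=tuple(p for p in (row.get("parents") or "").split(";") if p),
            isomer_note=row.get("isomer_note", ""),
        )
        if rec.id in mets:
            raise RegistryLoadError(
                f"{met_path}, row {i}, field 'id': duplicate metabolite id {rec.id!r}"
            )
        mets[rec.id] = rec

    fue_list: list[ExcretionFraction] = []
    for i, row in enumerate(_read_rows(fue_path), start=2):
        fue_list.append(
            _build(
                ExcretionFraction,
                row,
                fue_path,
                i,
                substance_id=row.get("substance_id", ""),
                metabolite_id=row.get("metabolite_id", ""),
                fue=row.get("fue", ""),
                basis=row.get("basis", ""),
                source=row.get("source", ""),
            )
        )

    try:
        with open(pop_path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
    except OSError as exc:
        raise RegistryLoadError(f"{pop_path}: {exc}") from exc
    pops = {}
    for pid, volume in raw.items():
        try:
            pops[pid] = PopulationGroup(id=pid, urine_volume=volume)
        except ValidationError as exc:
            raise RegistryLoadError(
                f"{pop_path}, key {pid!r}: {exc.errors()[0]['msg']}"
            ) from exc

    # cross-reference integrity
    for met in mets.values():
        for pid in met.parent_ids:
            if pid not in subs:
                raise IntegrityError(
                    f"metabolite {met.id!r} references unknown parent {pid!r}"
                )
    for f in fue_list:
        if f.substance_id not in subs:
            raise IntegrityError(
                f"excretion fraction references unknown substance {f.substance_id!r}"
            )
        if f.metabolite_id not in mets:
            raise IntegrityError(
                f"excretion fraction references unknown metabolite {f.metabolite_id!r}"
            )

    return Registry(
        substances=subs, metabolites=mets, fues=tuple(fue_list), populations=pops
    )


def write_registry(registry: Registry, directory: PathLike) -> dict[str, Path]:
    """Write a registry back to the on-disk layout; inverse of :func:`load_registry`."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "substances": directory / "substances.csv",
        "metabolites": directory / "metabolites.csv",
        "fues": directory / "fues.csv",
        "populations": directory / "populations.yaml",
    }
    with open(paths["substances"], "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(
            ["id", "adi_mg_per_kg_bw_day", "mw_g_per_mol", "adi_source",
             "approved_uses", "assessable"]
        )
        for s in registry.substances.values():
            w.writerow(
                [s.id, repr(s.adi), repr(s.mw_parent), s.adi_source,
                 ";".join(s.approved_uses), str(s.assessable).lower()]
            )
    with open(paths["metabolites"], "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["id", "mw_g_per_mol", "parents", "isomer_note"])
        for m in registry.metabolites.values():
            w.writerow([m.id, repr(m.mw_metabolite), ";".join(m.parent_ids), m.isomer_note])
    with open(paths["fues"], "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["substance_id", "metabolite_id", "fue", "basis", "source"])
        for f in registry.fues:
            w.writerow([f.substance_id, f.metabolite_id, repr(f.fue), f.basis.value, f.source])
    with open(paths["populations"], "w", encoding="utf-8") as fh:
        yaml.safe_dump(
            {p.id: p.urine_volume for p in registry.populations.values()}, fh
        )
    return paths
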