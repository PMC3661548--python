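"""Specimen measurement tables: reading, writing and fixture validation.

The unit of analysis is one measured specimen: its species, sex, and two
lengths in millimetres — prosoma length (a proxy for overall body size) and
pedipalpal patella length (the putatively dimorphic trait).  Tables travel
as plain CSV with a fixed header; sex labels are normalised on read from the
abbreviations common in specimen lists (``m``, ``f``, ``juv.`` ...).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterator, Optional

import pandas as pd

__all__ = [
    "Sex",
    "SpecimenRecord",
    "MeasurementTable",
    "SpeciesFixture",
    "ReferenceFixtures",
    "ValidationReport",
    "FormatError",
    "read_measurements",
    "write_measurements",
    "validate_against_fixture",
    "POTIGUAR_FIXTURE",
    "UBAJARA_FIXTURE",
]

COLUMNS = [
    "specimen_id",
    "species",
    "sex",
    "locality",
    "prosoma_length_mm",
    "patella_length_mm",
]

_SEX_ALIASES = {
    "m": "male",
    "male": "male",
    "f": "female",
    "female": "female",
    "j": "juvenile",
    "juv": "juvenile",
    "juv.": "juvenile",
    "juvenile": "juvenile",
}


class Sex(str, Enum):
    MALE = "male"
    FEMALE = "female"
    JUVENILE = "juvenile"


class FormatError(ValueError):
    """Raised for malformed measurement CSVs (bad header, bad values)."""


@dataclass(frozen=True)
class SpecimenRecord:
    """One measured individual; lengths in mm, ``None`` when unmeasured."""

    specimen_id: str
    species: str
    sex: Sex
    locality: Optional[str] = None
    prosoma_length: Optional[float] = None
    patella_length: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("prosoma_length", "patella_length"):
            v = getattr(self, name)
            if v is not None and not v > 0:
                raise ValueError(f"{name} must be positive, got {v!r}")

    @property
    def usable(self) -> bool:
        """True when both trait values are present (analyzable record)."""
        return self.prosoma_length is not None and self.patella_length is not None


@dataclass
class MeasurementTable:
    """Ordered collection of specimen records; mm units throughout.

    ``truth`` optionally carries generating morph labels keyed by
    specimen_id when the table came from the synthetic generator.
    """

    records: list[SpecimenRecord] = field(default_factory=list)
    truth: Optional[dict[str, str]] = None

    def __post_init__(self) -> None:
        ids = [r.specimen_id for r in self.records]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate specimen_id values: {dupes}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SpecimenRecord]:
        return iter(self.records)

    def subset(self, *, species: Optional[str] = None, sex: Optional[Sex] = None,
               usable_only: bool = False) -> "MeasurementTable":
        recs = [
            r for r in self.records
            if (species is None or r.species == species)
            and (sex is None or r.sex == sex)
            and (not usable_only or r.usable)
        ]
        truth = None
        if self.truth is not None:
            truth = {r.specimen_id: self.truth[r.specimen_id]
                     for r in recs if r.specimen_id in self.truth}
        return MeasurementTable(recs, truth=truth)

    def adults(self) -> "MeasurementTable":
        """Drop juveniles — the standard filter before any analysis."""
        recs = [r for r in self.records if r.sex is not Sex.JUVENILE]
        truth = None
        if self.truth is not None:
            truth = {r.specimen_id: self.truth[r.specimen_id]
                     for r in recs if r.specimen_id in self.truth}
        return MeasurementTable(recs, truth=truth)

    def to_dataframe(self, include_truth: bool = False) -> pd.DataFrame:
        rows = []
        for r in self.records:
            row = {
                "specimen_id": r.specimen_id,
                "species": r.species,
                "sex": r.sex.value,
                "locality": r.locality if r.locality is not None else "",
                "prosoma_length_mm": r.prosoma_length,
                "patella_length_mm": r.patella_length,
            }
            if include_truth and self.truth is not None:
                row["true_morph"] = self.truth.get(r.specimen_id, "")
            rows.append(row)
        cols = COLUMNS + (["true_morph"] if include_truth and self.truth else [])
        return pd.DataFrame(rows, columns=cols)


@dataclass(frozen=True)
class SpeciesFixture:
    """Published per-sex sample sizes and trait ranges for one species."""

    species: str
    n_male: int
    n_female: int
    male_prosoma_range: tuple[float, float]
    male_patella_range: tuple[float, float]
    female_prosoma_range: tuple[float, float]
    female_patella_range: tuple[float, float]


# Printed sample sizes and trait ranges for the two cave schizomids.
POTIGUAR_FIXTURE = SpeciesFixture(
    species="Rowlandius potiguar",
    n_male=45, n_female=17,
    male_prosoma_range=(1.25, 1.73), male_patella_range=(0.53, 2.2),
    female_prosoma_range=(1.27, 1.83), female_patella_range=(0.52, 0.6),
)
UBAJARA_FIXTURE = SpeciesFixture(
    species="Rowlandius ubajara",
    n_male=2, n_female=3,
    male_prosoma_range=(1.27, 1.37), male_patella_range=(0.48, 0.6),
    female_prosoma_range=(1.26, 1.73), female_patella_range=(0.53, 0.66),
)


@dataclass(frozen=True)
class ReferenceFixtures:
    species: tuple[SpeciesFixture, ...] = (POTIGUAR_FIXTURE, UBAJARA_FIXTURE)

    def lookup(self, species: str) -> Optional[SpeciesFixture]:
        for fx in self.species:
            if fx.species == species:
                return fx
        return None


@dataclass
class ValidationCheck:
    species: str
    sex: str
    check: str          # "count" | "prosoma_range" | "patella_range"
    passed: bool
    detail: str

    def to_dict(self) -> dict:
        return {"species": self.species, "sex": self.sex,
                "check": self.check, "passed": self.passed, "detail": self.detail}


@dataclass
class ValidationReport:
    checks: list[ValidationCheck] = field(default_factory=list)
    unknown_species: list[str] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return all(c.passed for c in self.checks)

    def failures(self) -> list[ValidationCheck]:
        return [c for c in self.checks if not c.passed]

    def to_json(self, **kwargs) -> str:
        return json.dumps(
            {"passed": self.passed,
             "checks": [c.to_dict() for c in self.checks],
             "unknown_species": self.unknown_species},
            **kwargs,
        )


def _parse_sex(raw: str, line: int) -> Sex:
    key = raw.strip().lower()
    if key not in _SEX_ALIASES:
        raise FormatError(f"line {line}: unrecognized sex value {raw!r}")
    return Sex(_SEX_ALIASES[key])


def _parse_length(raw, column: str, line: int) -> Optional[float]:
    if raw is None or (isinstance(raw, float) and pd.isna(raw)) or str(raw).strip() == "":
        return None
    try:
        value = float(raw)
    except (TypeError, ValueError):
        raise FormatError(f"line {line}: non-numeric {column} value {raw!r}") from None
    if not value > 0:
        raise FormatError(f"line {line}: {column} must be positive, got {value}")
    return value


def read_measurements(path: str | Path) -> MeasurementTable:
    """Read a measurement CSV into a :class:`MeasurementTable`.

    The header must contain the six canonical columns; a trailing
    ``true_morph`` column (written by the synthetic generator) is picked up
    into the table's ``truth`` mapping.  Rows with empty length fields are
    kept but marked unusable.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"missing mandatory column(s): {', '.join(missing)}")

    records: list[SpecimenRecord] = []
    truth: dict[str, str] = {}
    has_truth = "true_morph" in df.columns
    for idx, row in enumerate(df.itertuples(index=False), start=2):  # line 1 = header
        d = dict(zip(df.columns, row))
        rec = SpecimenRecord(
            specimen_id=str(d["specimen_id"]).strip(),
            species=str(d["species"]).strip(),
            sex=_parse_sex(str(d["sex"]), idx),
            locality=(str(d["locality"]) or None),
            prosoma_length=_parse_length(d["prosoma_length_mm"], "prosoma_length_mm", idx),
            patella_length=_parse_length(d["patella_length_mm"], "patella_length_mm", idx),
        )
        records.append(rec)
        if has_truth and str(d["true_morph"]).strip():
            truth[rec.specimen_id] = str(d["true_morph"]).strip()
    return MeasurementTable(records, truth=truth or None)


def write_measurements(table: MeasurementTable, path: str | Path,
                       include_truth: bool = False) -> None:
    """Write a table as CSV; read(write(T)) == T field-for-field.

    Generating morph labels are dropped unless ``include_truth`` is set.
    """
    df = table.to_dataframe(include_truth=include_truth)
    df.to_csv(path, index=False)  # repr-precision floats: exact round trip


def validate_against_fixture(table: MeasurementTable,
                             fixtures: ReferenceFixtures | SpeciesFixture = ReferenceFixtures(),
                             ) -> ValidationReport:
    """Check per-(species, sex) counts and trait ranges against published values.

    Ranges are inclusive.  Species present in the table but absent from the
    fixture set are flagged in ``unknown_species``, not fatal.
    """
    if len(table) == 0:
        raise ValueError("cannot validate an empty table")
    if isinstance(fixtures, SpeciesFixture):
        fixtures = ReferenceFixtures(species=(fixtures,))

    report = ValidationReport()
    seen_species = sorted({r.species for r in table})
    for sp in seen_species:
        if fixtures.lookup(sp) is None:
            report.unknown_species.append(sp)

    for fx in fixtures.species:
        if all(r.species != fx.species for r in table):
            continue
        for sex, n_expected, pros_rng, pat_rng in (
            (Sex.MALE, fx.n_male, fx.male_prosoma_range, fx.male_patella_range),
            (Sex.FEMALE, fx.n_female, fx.female_prosoma_range, fx.female_patella_range),
        ):
            group = table.subset(species=fx.species, sex=sex)
            n = len(group)
            report.checks.append(ValidationCheck(
                fx.species, sex.value, "count", n == n_expected,
                f"observed {n}, expected {n_expected}"))
            for trait, rng in (("prosoma", pros_rng), ("patella", pat_rng)):
                values = [getattr(r, f"{trait}_length") for r in group
                          if getattr(r, f"{trait}_length") is not None]
                bad = [v for v in values if not (rng[0] <= v <= rng[1])]
                report.checks.append(ValidationCheck(
                    fx.species, sex.value, f"{trait}_range", not bad,
                    f"{len(bad)} of {len(values)} outside [{rng[0]}, {rng[1]}]"))
    return report
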