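"""Typed domain model for deidentified EHR cohort bundles, plus on-disk I/O.

A :class:`CohortBundle` gathers everything the progression workflow consumes
for one cohort: patient demographics and biomarkers, clinical notes and
radiology reports (free text with optional section spans), drug orders,
encounters, death dates, diagnosis codes, ECOG performance scores and PHQ-8
depression scores, together with the study observation window.

On disk a bundle is a directory of line-oriented JSONL tables (one file per
record type) plus a ``manifest.json`` carrying the study window and schema
version.  All dates are ISO-8601 calendar dates — the source data are
deidentified, so no time-of-day is modeled.  Writes are deterministic: rows
are sorted by (patient_id, date, id) and serialized with sorted keys, so two
writes of the same bundle are byte-identical and the format diffs cleanly.
"""

from __future__ import annotations

import datetime as dt
import json
import logging
from enum import Enum
from pathlib import Path
from typing import Optional

from pydantic import BaseModel, Field, field_validator, model_validator

logger = logging.getLogger("rwpfs")

SCHEMA_VERSION = 1


class Sex(str, Enum):
    female = "female"
    male = "male"
    other = "other"
    unknown = "unknown"


class ReceptorStatus(str, Enum):
    """Hormone-receptor / HER2 biomarker status."""

    positive = "positive"
    negative = "negative"
    unknown = "unknown"


class NoteType(str, Enum):
    clinical_document = "clinical_document"
    radiology_report = "radiology_report"


class CodeSystem(str, Enum):
    ICD9 = "ICD9"
    ICD10 = "ICD10"


def _lenient_enum(cls: type[Enum], value: object, field: str) -> object:
    """Map unrecognized enum strings to ``unknown`` with a warning.

    Only used for enumerations that have an ``unknown`` member; structural
    enumerations (note type, code system) reject bad values outright.
    """
    if isinstance(value, str) and value not in {m.value for m in cls}:
        logger.warning("unrecognized %s value %r coerced to 'unknown'", field, value)
        return "unknown"
    return value


class Patient(BaseModel):
    patient_id: str
    birth_year: int
    sex: Sex = Sex.unknown
    metastasis_date: Optional[dt.date] = None
    hr_status: ReceptorStatus = ReceptorStatus.unknown
    her2_status: ReceptorStatus = ReceptorStatus.unknown

    @field_validator("sex", mode="before")
    @classmethod
    def _sex(cls, v: object) -> object:
        return _lenient_enum(Sex, v, "sex")

    @field_validator("hr_status", "her2_status", mode="before")
    @classmethod
    def _receptor(cls, v: object) -> object:
        return _lenient_enum(ReceptorStatus, v, "receptor status")


class Section(BaseModel):
    """A half-open character span ``[start, end)`` labeled with its header."""

    header: str
    start: int = Field(ge=0)
    end: int = Field(ge=0)


class ClinicalNote(BaseModel):
    note_id: str
    patient_id: str
    note_date: dt.date
    note_type: NoteType = NoteType.clinical_document
    text: str = ""
    sections: list[Section] = Field(default_factory=list)

    @model_validator(mode="after")
    def _check_sections(self) -> "ClinicalNote":
        prev_end = 0
        for sec in self.sections:
            if sec.start < prev_end:
                raise ValueError(
                    f"note {self.note_id}: section spans overlap or are unordered"
                )
            if not (sec.start <= sec.end <= len(self.text)):
                raise ValueError(f"note {self.note_id}: section span out of bounds")
            prev_end = sec.end
        return self


class DrugOrder(BaseModel):
    patient_id: str
    drug_name: str = Field(min_length=1)
    order_date: dt.date

    @field_validator("drug_name")
    @classmethod
    def _canonical(cls, v: str) -> str:
        return v.strip().lower()


class EncounterRecord(BaseModel):
    patient_id: str
    encounter_date: dt.date


class DeathRecord(BaseModel):
    patient_id: str
    death_date: dt.date


class DiagnosisRecord(BaseModel):
    patient_id: str
    code: str = Field(min_length=1)
    code_system: CodeSystem
    diagnosis_date: dt.date


class EcogRecord(BaseModel):
    patient_id: str
    score: int = Field(ge=0, le=5)
    record_date: dt.date


class Phq8Record(BaseModel):
    patient_id: str
    score: int = Field(ge=0, le=24)
    record_date: dt.date


class CohortBundle(BaseModel):
    """All structured and unstructured records for a set of patients.

    Construction validates referential integrity (every record refers to a
    known patient, at most one death per patient) and normalizes collection
    order, so two bundles with the same content compare equal regardless of
    input ordering.
    """

    patients: list[Patient] = Field(default_factory=list)
    notes: list[ClinicalNote] = Field(default_factory=list)
    drug_orders: list[DrugOrder] = Field(default_factory=list)
    encounters: list[EncounterRecord] = Field(default_factory=list)
    deaths: list[DeathRecord] = Field(default_factory=list)
    diagnoses: list[DiagnosisRecord] = Field(default_factory=list)
    ecog_records: list[EcogRecord] = Field(default_factory=list)
    phq8_records: list[Phq8Record] = Field(default_factory=list)
    study_start: dt.date
    study_end: dt.date

    @model_validator(mode="after")
    def _validate(self) -> "CohortBundle":
        if not self.study_start < self.study_end:
            raise ValueError("study_start must precede study_end")
        ids = [p.patient_id for p in self.patients]
        known = set(ids)
        if len(ids) != len(known):
            raise ValueError("duplicate patient_id in bundle")
        for name in ("notes", "drug_orders", "encounters", "deaths", "diagnoses",
                     "ecog_records", "phq8_records"):
            for rec in getattr(self, name):
                if rec.patient_id not in known:
                    raise ValueError(
                        f"{name} record references unknown patient_id "
                        f"{rec.patient_id!r}"
                    )
        dead = [d.patient_id for d in self.deaths]
        if len(dead) != len(set(dead)):
            raise ValueError("more than one death record for a patient")
        self._sort_in_place()
        return self

    def _sort_in_place(self) -> None:
        self.patients.sort(key=lambda p: p.patient_id)
        self.notes.sort(key=lambda n: (n.patient_id, n.note_date, n.note_id))
        self.drug_orders.sort(key=lambda o: (o.patient_id, o.order_date, o.drug_name))
        self.encounters.sort(key=lambda e: (e.patient_id, e.encounter_date))
        self.deaths.sort(key=lambda d: d.patient_id)
        self.diagnoses.sort(key=lambda d: (d.patient_id, d.diagnosis_date, d.code))
        self.ecog_records.sort(key=lambda r: (r.patient_id, r.record_date, r.score))
        self.phq8_records.sort(key=lambda r: (r.patient_id, r.record_date, r.score))


class BundleError(Exception):
    """Base class for bundle I/O failures."""


class MissingTableError(BundleError):
    def __init__(self, table: str, path: Path):
        self.table = table
        super().__init__(f"bundle at {path} is missing required table {table!r}")


class BundleReadError(BundleError):
    def __init__(self, locator: str, reason: str):
        self.locator = locator
        super().__init__(f"{locator}: {reason}")


_TABLES: list[tuple[str, type[BaseModel], str]] = [
    ("patients.jsonl", Patient, "patients"),
    ("notes.jsonl", ClinicalNote, "notes"),
    ("drug_orders.jsonl", DrugOrder, "drug_orders"),
    ("encounters.jsonl", EncounterRecord, "encounters"),
    ("deaths.jsonl", DeathRecord, "deaths"),
    ("diagnoses.jsonl", DiagnosisRecord, "diagnoses"),
    ("ecog.jsonl", EcogRecord, "ecog_records"),
    ("phq8.jsonl", Phq8Record, "phq8_records"),
]


def write_bundle(bundle: CohortBundle, path: str | Path) -> None:
    """Write ``bundle`` to ``path`` as JSONL tables plus a manifest.

    Deterministic: row order is the bundle's normalized order and JSON keys
    are sorted, so repeated writes of equal bundles are byte-identical.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for fname, _model, attr in _TABLES:
        rows = getattr(bundle, attr)
        with open(path / fname, "w", encoding="utf-8") as fh:
            for rec in rows:
                fh.write(json.dumps(rec.model_dump(mode="json"), sort_keys=True))
                fh.write("\n")
    manifest = {
        "schema_version": SCHEMA_VERSION,
        "study_start": bundle.study_start.isoformat(),
        "study_end": bundle.study_end.isoformat(),
    }
    with open(path / "manifest.json", "w", encoding="utf-8") as fh:
        fh.write(json.dumps(manifest, sort_keys=True, indent=2))
        fh.write("\n")


def read_bundle(path: str | Path) -> CohortBundle:
    """Read a bundle directory written by :func:`write_bundle`.

    Raises :class:`MissingTableError` when a table file or the manifest is
    absent and :class:`BundleReadError` (with a ``file:line`` locator) when a
    row is malformed.  Referential-integrity violations surface as pydantic
    validation errors from :class:`CohortBundle`.
    """
    path = Path(path)
    manifest_path = path / "manifest.json"
    if not manifest_path.exists():
        raise MissingTableError("manifest.json", path)
    try:
        manifest = json.loads(manifest_path.read_text(encoding="utf-8"))
        study_start = dt.date.fromisoformat(manifest["study_start"])
        study_end = dt.date.fromisoformat(manifest["study_end"])
    except (ValueError, KeyError, TypeError) as exc:
        raise BundleReadError(str(manifest_path), f"malformed manifest: {exc}") from exc

    data: dict[str, list[BaseModel]] = {}
    for fname, model, attr in _TABLES:
        fpath = path / fname
        if not fpath.exists():
            raise MissingTableError(fname, path)
        rows: list[BaseModel] = []
        with open(fpath, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                try:
                    rows.append(model.model_validate_json(line))
                except Exception as exc:
                    raise BundleReadError(
                        f"{fpath}:{lineno}", f"malformed row: {exc}"
                    ) from exc
        data[attr] = rows
    return CohortBundle(study_start=study_start, study_end=study_end, **data)
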