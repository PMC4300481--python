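"""Person records, cohorts and their CSV/JSON readers and writers.

A cohort is a list of :class:`PersonRecord`. Each record bundles identification
data, medical/family/smoking history, physical examinations, dated screening
test results and a log of visits with the tests requested at each — the four
registries a screening clinic keeps for one individual.

Validation is *total*: constructing a record never enforces cross-field
invariants; :func:`validate_record` returns findings as data, and only the
loaders/savers raise (so that a whole file's problems can be reported at once).

File formats
------------
``json``  — one nested document, a list of person objects (dates ISO-8601).
``csv``   — a directory of four normalized files keyed by ``person_id``:
            ``persons.csv``, ``exams.csv``, ``results.csv``, ``visits.csv``.
            Nested history lists are JSON-encoded in their ``persons.csv`` cell.
Schemas are documented in ``docs/file_formats.md``.
"""

from __future__ import annotations

import json
from datetime import date
from enum import Enum
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from .errors import CohortValidationError, FormatError


class Sex(str, Enum):
    male = "male"
    female = "female"


class MaritalStatus(str, Enum):
    single = "single"
    married = "married"
    divorced = "divorced"
    widowed = "widowed"
    unknown = "unknown"


class SmokingStatus(str, Enum):
    never = "never"
    former = "former"
    current = "current"


class TestCode(str, Enum):
    """The screening tests the default guideline set covers."""

    FPG = "FPG"
    LIPID_PROFILE = "LIPID_PROFILE"
    FOBT = "FOBT"
    SIGMOIDOSCOPY_COLONOSCOPY = "SIGMOIDOSCOPY_COLONOSCOPY"
    PAP_SMEAR = "PAP_SMEAR"
    MAMMOGRAPHY = "MAMMOGRAPHY"
    PSA = "PSA"
    SKIN_EXAM = "SKIN_EXAM"


class Relation(str, Enum):
    mother = "mother"
    father = "father"
    sister = "sister"
    brother = "brother"
    daughter = "daughter"
    son = "son"
    grandmother = "grandmother"
    grandfather = "grandfather"
    aunt = "aunt"
    uncle = "uncle"
    cousin = "cousin"


FIRST_DEGREE: frozenset[Relation] = frozenset(
    {Relation.mother, Relation.father, Relation.sister, Relation.brother,
     Relation.daughter, Relation.son}
)


class Contact(BaseModel):
    model_config = ConfigDict(extra="forbid")
    email: Optional[str] = None
    phone: Optional[str] = None


class CancerHistoryItem(BaseModel):
    model_config = ConfigDict(extra="forbid")
    site: str
    year: int


class FamilyHistoryItem(BaseModel):
    model_config = ConfigDict(extra="forbid")
    relation: Relation
    condition: str
    onset_age: Optional[int] = None

    @property
    def first_degree(self) -> bool:
        return self.relation in FIRST_DEGREE


class MedicalHistory(BaseModel):
    model_config = ConfigDict(extra="forbid")
    known_diseases: list[str] = Field(default_factory=list)
    cancer_history: list[CancerHistoryItem] = Field(default_factory=list)
    family_history: list[FamilyHistoryItem] = Field(default_factory=list)
    smoking: SmokingStatus = SmokingStatus.never
    pack_years: Optional[float] = None
    medications: list[str] = Field(default_factory=list)
    on_antihypertensives: bool = False


class PhysicalExam(BaseModel):
    model_config = ConfigDict(extra="forbid")
    date: date
    systolic: float
    diastolic: float
    height: float  # cm
    weight: float  # kg
    waist: float  # cm
    other_findings: list[str] = Field(default_factory=list)


class TestResult(BaseModel):
    """One dated screening-test result.

    Quantitative tests carry ``numeric_value`` (and ``units``); panel tests such
    as the lipid profile carry per-analyte ``components``; report-style tests
    (Pap smear, mammography, colonoscopy) carry ``text_report``.
    """

    model_config = ConfigDict(extra="forbid")
    test_code: TestCode
    date: date
    numeric_value: Optional[float] = None
    units: Optional[str] = None
    components: Optional[dict[str, float]] = None
    text_report: Optional[str] = None


class VisitEvent(BaseModel):
    """One clinic visit and the screening tests requested at it."""

    model_config = ConfigDict(extra="forbid")
    date: date
    tests_requested: list[TestCode] = Field(default_factory=list)


class PersonRecord(BaseModel):
    model_config = ConfigDict(extra="forbid")
    person_id: str
    name: str = ""
    birth_date: date
    sex: Sex
    marital_status: MaritalStatus = MaritalStatus.unknown
    contact: Contact = Field(default_factory=Contact)
    history: MedicalHistory = Field(default_factory=MedicalHistory)
    exams: list[PhysicalExam] = Field(default_factory=list)
    results: list[TestResult] = Field(default_factory=list)
    visits: list[VisitEvent] = Field(default_factory=list)

    def age_on(self, as_of: date) -> int:
        """Age in completed years on ``as_of``."""
        had_birthday = (as_of.month, as_of.day) >= (self.birth_date.month, self.birth_date.day)
        return as_of.year - self.birth_date.year - (0 if had_birthday else 1)

    def latest_exam(self, as_of: Optional[date] = None) -> Optional[PhysicalExam]:
        exams = [e for e in self.exams if as_of is None or e.date <= as_of]
        return max(exams, key=lambda e: e.date, default=None)

    def latest_result(self, test_code: TestCode, as_of: Optional[date] = None) -> Optional[TestResult]:
        rs = [r for r in self.results
              if r.test_code == test_code and (as_of is None or r.date <= as_of)]
        return max(rs, key=lambda r: r.date, default=None)


class ValidationFinding(BaseModel):
    """One invariant breach, reported as data rather than raised."""

    model_config = ConfigDict(extra="forbid")
    person_id: str
    field: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.person_id}/{self.field}: {self.message}"


def validate_record(record: PersonRecord) -> list[ValidationFinding]:
    """Check every cross-field invariant of one record; never raises."""
    out: list[ValidationFinding] = []

    def add(field: str, message: str) -> None:
        out.append(ValidationFinding(person_id=record.person_id or "<missing>",
                                     field=field, message=message))

    if not record.person_id:
        add("person_id", "person_id must be non-empty")
    for i, exam in enumerate(record.exams):
        if exam.date <= record.birth_date:
            add(f"exams[{i}].date", f"exam dated {exam.date} not after birth_date {record.birth_date}")
        if not (exam.systolic > exam.diastolic > 0):
            add(f"exams[{i}]", f"blood pressure {exam.systolic}/{exam.diastolic} violates systolic > diastolic > 0")
        for comp in ("height", "weight", "waist"):
            if getattr(exam, comp) <= 0:
                add(f"exams[{i}].{comp}", f"{comp} must be > 0")
    for i, res in enumerate(record.results):
        if res.date <= record.birth_date:
            add(f"results[{i}].date", f"result dated {res.date} not after birth_date {record.birth_date}")
        if res.numeric_value is None and res.text_report is None and not res.components:
            add(f"results[{i}]", "result needs numeric_value, components or text_report")
    visit_dates = [v.date for v in record.visits]
    for i, v in enumerate(record.visits):
        if v.date <= record.birth_date:
            add(f"visits[{i}].date", f"visit dated {v.date} not after birth_date {record.birth_date}")
    if len(set(visit_dates)) != len(visit_dates):
        add("visits", "visit dates must be distinct (strictly ordered when sorted)")
    if record.history.pack_years is not None and record.history.pack_years < 0:
        add("history.pack_years", "pack_years must be >= 0 when present")
    return out


def validate_cohort(cohort: Iterable[PersonRecord]) -> list[ValidationFinding]:
    """All per-record findings plus cohort-level uniqueness of person_id."""
    cohort = list(cohort)
    findings: list[ValidationFinding] = []
    seen: set[str] = set()
    for rec in cohort:
        findings.extend(validate_record(rec))
        if rec.person_id in seen:
            findings.append(ValidationFinding(
                person_id=rec.person_id, field="person_id",
                message=f"duplicated person_id {rec.person_id!r}"))
        seen.add(rec.person_id)
    return findings


# ---------------------------------------------------------------------------
# JSON I/O

def _cohort_to_obj(cohort: list[PersonRecord]) -> list[dict]:
    return [json.loads(rec.model_dump_json(exclude_none=True)) for rec in cohort]


def _cohort_from_obj(obj, path: str) -> list[PersonRecord]:
    if not isinstance(obj, list):
        raise FormatError("JSON cohort must be a top-level array of person objects", path=path)
    records = []
    for i, item in enumerate(obj):
        try:
            records.append(PersonRecord.model_validate(item))
        except Exception as exc:
            raise FormatError(f"cannot parse person object: {exc}", path=path, record=i) from exc
    return records


# ---------------------------------------------------------------------------
# CSV I/O (directory of four normalized files)

_CSV_FILES = ("persons.csv", "exams.csv", "results.csv", "visits.csv")

_PERSON_SCALARS = ["person_id", "name", "birth_date", "sex", "marital_status",
                   "email", "phone", "smoking", "pack_years", "on_antihypertensives"]
_PERSON_JSON = ["known_diseases", "cancer_history", "family_history", "medications"]


def _persons_frame(cohort: list[PersonRecord]) -> pd.DataFrame:
    rows = []
    for r in cohort:
        h = r.history
        rows.append({
            "person_id": r.person_id, "name": r.name, "birth_date": r.birth_date.isoformat(),
            "sex": r.sex.value, "marital_status": r.marital_status.value,
            "email": r.contact.email, "phone": r.contact.phone,
            "smoking": h.smoking.value, "pack_years": h.pack_years,
            "on_antihypertensives": h.on_antihypertensives,
            "known_diseases": json.dumps(h.known_diseases),
            "cancer_history": json.dumps([c.model_dump() for c in h.cancer_history]),
            "family_history": json.dumps([f.model_dump(exclude_none=True) for f in h.family_history]),
            "medications": json.dumps(h.medications),
        })
    return pd.DataFrame(rows, columns=_PERSON_SCALARS + _PERSON_JSON)


def _entity_frames(cohort: list[PersonRecord]):
    exams, results, visits = [], [], []
    for r in cohort:
        for e in r.exams:
            exams.append({"person_id": r.person_id, "date": e.date.isoformat(),
                          "systolic": e.systolic, "diastolic": e.diastolic,
                          "height": e.height, "weight": e.weight, "waist": e.waist,
                          "other_findings": json.dumps(e.other_findings)})
        for t in r.results:
            results.append({"person_id": r.person_id, "test_code": t.test_code.value,
                            "date": t.date.isoformat(), "numeric_value": t.numeric_value,
                            "units": t.units,
                            "components": json.dumps(t.components) if t.components else None,
                            "text_report": t.text_report})
        for v in r.visits:
            visits.append({"person_id": r.person_id, "date": v.date.isoformat(),
                           "tests_requested": json.dumps([c.value for c in v.tests_requested])})
    return (
        pd.DataFrame(exams, columns=["person_id", "date", "systolic", "diastolic",
                                     "height", "weight", "waist", "other_findings"]),
        pd.DataFrame(results, columns=["person_id", "test_code", "date", "numeric_value",
                                       "units", "components", "text_report"]),
        pd.DataFrame(visits, columns=["person_id", "date", "tests_requested"]),
    )


def _none_if_na(x):
    return None if pd.isna(x) else x


def _load_csv_dir(path: Path) -> list[PersonRecord]:
    frames = {}
    for name in _CSV_FILES:
        f = path / name
        if not f.exists():
            raise FormatError(f"missing {name} in CSV cohort directory", path=str(path))
        try:
            frames[name] = pd.read_csv(f, dtype={"person_id": str})
        except Exception as exc:
            raise FormatError(f"cannot parse {name}: {exc}", path=str(f)) from exc

    by_person: dict[str, dict] = {}
    order: list[str] = []
    for i, row in frames["persons.csv"].iterrows():
        try:
            pid = str(row["person_id"])
            by_person[pid] = {
                "person_id": pid,
                "name": _none_if_na(row.get("name")) or "",
                "birth_date": row["birth_date"],
                "sex": row["sex"],
                "marital_status": _none_if_na(row.get("marital_status")) or "unknown",
                "contact": {"email": _none_if_na(row.get("email")),
                            "phone": _none_if_na(row.get("phone"))},
                "history": {
                    "smoking": _none_if_na(row.get("smoking")) or "never",
                    "pack_years": _none_if_na(row.get("pack_years")),
                    "on_antihypertensives": bool(row.get("on_antihypertensives", False)),
                    "known_diseases": json.loads(row.get("known_diseases") or "[]"),
                    "cancer_history": json.loads(row.get("cancer_history") or "[]"),
                    "family_history": json.loads(row.get("family_history") or "[]"),
                    "medications": json.loads(row.get("medications") or "[]"),
                },
                "exams": [], "results": [], "visits": [],
            }
            order.append(pid)
        except FormatError:
            raise
        except Exception as exc:
            raise FormatError(f"bad persons.csv row: {exc}", path=str(path / "persons.csv"),
                              record=int(i) + 2) from exc

    def rows_for(name: str):
        for i, row in frames[name].iterrows():
            pid = str(row["person_id"])
            if pid not in by_person:
                raise FormatError(f"unknown person_id {pid!r}", path=str(path / name),
                                  record=int(i) + 2)
            yield i, pid, row

    for i, pid, row in rows_for("exams.csv"):
        by_person[pid]["exams"].append({
            "date": row["date"], "systolic": row["systolic"], "diastolic": row["diastolic"],
            "height": row["height"], "weight": row["weight"], "waist": row["waist"],
            "other_findings": json.loads(_none_if_na(row.get("other_findings")) or "[]")})
    for i, pid, row in rows_for("results.csv"):
        comp = _none_if_na(row.get("components"))
        by_person[pid]["results"].append({
            "test_code": row["test_code"], "date": row["date"],
            "numeric_value": _none_if_na(row.get("numeric_value")),
            "units": _none_if_na(row.get("units")),
            "components": json.loads(comp) if comp else None,
            "text_report": _none_if_na(row.get("text_report"))})
    for i, pid, row in rows_for("visits.csv"):
        by_person[pid]["visits"].append({
            "date": row["date"],
            "tests_requested": json.loads(_none_if_na(row.get("tests_requested")) or "[]")})

    records = []
    for pid in order:
        try:
            records.append(PersonRecord.model_validate(by_person[pid]))
        except Exception as exc:
            raise FormatError(f"cannot build record: {exc}", path=str(path), record=pid) from exc
    return records


# ---------------------------------------------------------------------------
# Public loaders / savers

def load_cohort(path: str | Path, format: str = "json") -> list[PersonRecord]:
    """Load and validate a cohort.

    ``format='json'`` expects one nested document; ``format='csv'`` expects a
    directory with the four normalized CSV files. Raises :class:`FormatError`
    on parse failure and :class:`CohortValidationError` (listing field and
    person_id per finding) on invariant breaches, including duplicated ids.
    """
    path = Path(path)
    if format == "json":
        if not path.exists():
            raise FormatError("file does not exist", path=str(path))
        try:
            obj = json.loads(path.read_text())
        except json.JSONDecodeError as exc:
            raise FormatError(f"invalid JSON at line {exc.lineno}: {exc.msg}", path=str(path)) from exc
        records = _cohort_from_obj(obj, str(path))
    elif format == "csv":
        if not path.is_dir():
            raise FormatError("CSV cohort path must be a directory", path=str(path))
        records = _load_csv_dir(path)
    else:
        raise ValueError(f"unknown format {format!r}")

    findings = validate_cohort(records)
    if findings:
        raise CohortValidationError(findings)
    return records


def save_cohort(cohort: list[PersonRecord], path: str | Path, format: str = "json") -> None:
    """Write a validated cohort so that :func:`load_cohort` round-trips it."""
    findings = validate_cohort(cohort)
    if findings:
        raise CohortValidationError(findings)
    path = Path(path)
    if format == "json":
        path.write_text(json.dumps(_cohort_to_obj(list(cohort)), indent=1) + "\n")
    elif format == "csv":
        path.mkdir(parents=True, exist_ok=True)
        persons = _persons_frame(list(cohort))
        exams, results, visits = _entity_frames(list(cohort))
        persons.to_csv(path / "persons.csv", index=False)
        exams.to_csv(path / "exams.csv", index=False)
        results.to_csv(path / "results.csv", index=False)
        visits.to_csv(path / "visits.csv", index=False)
    else:
        raise ValueError(f"unknown format {format!r}")
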