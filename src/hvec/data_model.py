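"""Domain types for longitudinal claims cohorts.

The unit of analysis is a :class:`ClinicalRecord` — one dated inpatient or
outpatient visit carrying coded diagnoses/procedures/medications/tests/other,
care-site attributes, per-category costs and counts, and a hospital-stay
duration.  Records are grouped into :class:`Person` sequences (sorted by date,
ties broken on record id) and persons into a :class:`Cohort`.

Dates are plain integer day indices relative to a cohort epoch; all 30-day
windows downstream are computed in integer-day arithmetic.

A cohort round-trips through a flat two-table CSV interchange format
(``persons.csv`` + ``records.csv``) via :func:`write_cohort` /
:func:`read_cohort`.
"""

from __future__ import annotations

import csv
import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

__all__ = [
    "CATEGORIES",
    "DEFAULT_CA_CODES",
    "N_CARE_SITE_TYPE",
    "N_CARE_SITE_SPECIALIZATION",
    "N_CARE_SITE_RANK",
    "MedicalCode",
    "ClinicalRecord",
    "Person",
    "Cohort",
    "CohortFormatError",
    "IntegrityError",
    "flag_ca",
    "read_cohort",
    "write_cohort",
]

#: The five code categories of a claims record, in canonical order.
CATEGORIES = ("diagnosis", "procedure", "medication", "test", "other")

#: ICD-9 procedure codes flagging an in-hospital cardiac arrest record:
#: 99.60 (cardiopulmonary resuscitation, not otherwise specified) and
#: 99.63 (closed-chest cardiac massage).
DEFAULT_CA_CODES = frozenset({"99.60", "99.63"})

# Cardinalities of the opaque care-site categoricals.
N_CARE_SITE_TYPE = 21
N_CARE_SITE_SPECIALIZATION = 5
N_CARE_SITE_RANK = 17

CLAIM_TYPES = ("inpatient", "outpatient")
GENDERS = ("male", "female")


class CohortFormatError(ValueError):
    """A cohort file is malformed (bad row, unknown token, missing column)."""


class IntegrityError(ValueError):
    """A cohort violates a structural invariant (duplicate ids, bad counts)."""


@dataclass(frozen=True)
class MedicalCode:
    """A single coded clinical concept (ICD-9-style token) with its category."""

    category: str
    code: str

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown code category: {self.category!r}")
        if not self.code:
            raise ValueError("code must be a non-empty token")


def flag_ca(record: "ClinicalRecord", ca_codes: Iterable[str] = DEFAULT_CA_CODES) -> bool:
    """True iff the record carries a *procedure* code in ``ca_codes``.

    Monotone in ``ca_codes``: enlarging the set can only turn False into True.
    """
    ca = set(ca_codes)
    if not ca:
        raise ValueError("ca_codes must be non-empty")
    return any(c.category == "procedure" and c.code in ca for c in record.codes)


@dataclass
class ClinicalRecord:
    """One clinical visit; the unit of analysis.

    ``costs`` and ``counts`` are aligned with :data:`CATEGORIES`; ``counts``
    must tally the codes by category.  Outpatient records have zero
    ``hospital_stay``.  ``is_ca`` is derived from the procedure codes.
    """

    record_id: str
    person_id: str
    date: int
    claim_type: str
    codes: list[MedicalCode]
    care_site_type: int
    care_site_specialization: int
    care_site_rank: int
    hospital_stay: int
    costs: list[float]
    counts: list[int]
    discharge_dead_or_critical: bool
    is_ca: bool = field(default=False)

    def validate(self, ca_codes: Iterable[str] = DEFAULT_CA_CODES) -> None:
        if self.date < 0:
            raise IntegrityError(f"record {self.record_id}: negative date {self.date}")
        if self.claim_type not in CLAIM_TYPES:
            raise IntegrityError(
                f"record {self.record_id}: unknown claim_type {self.claim_type!r}"
            )
        if self.claim_type == "outpatient" and self.hospital_stay != 0:
            raise IntegrityError(
                f"record {self.record_id}: outpatient record with hospital_stay "
                f"{self.hospital_stay}"
            )
        if self.hospital_stay < 0:
            raise IntegrityError(f"record {self.record_id}: negative hospital_stay")
        if len(self.costs) != 5 or len(self.counts) != 5:
            raise IntegrityError(f"record {self.record_id}: costs/counts must have 5 entries")
        if any(c < 0 for c in self.costs) or any(n < 0 for n in self.counts):
            raise IntegrityError(f"record {self.record_id}: negative cost or count")
        tallies = [sum(1 for c in self.codes if c.category == cat) for cat in CATEGORIES]
        if tallies != list(self.counts):
            raise IntegrityError(
                f"record {self.record_id}: counts {list(self.counts)} do not match "
                f"code tallies {tallies}"
            )
        if not (0 <= self.care_site_type < N_CARE_SITE_TYPE):
            raise IntegrityError(f"record {self.record_id}: care_site_type out of range")
        if not (0 <= self.care_site_specialization < N_CARE_SITE_SPECIALIZATION):
            raise IntegrityError(
                f"record {self.record_id}: care_site_specialization out of range"
            )
        if not (0 <= self.care_site_rank < N_CARE_SITE_RANK):
            raise IntegrityError(f"record {self.record_id}: care_site_rank out of range")
        if self.is_ca != flag_ca(self, ca_codes):
            raise IntegrityError(
                f"record {self.record_id}: is_ca flag inconsistent with procedure codes"
            )


@dataclass
class Person:
    """A patient: demographics plus a date-sorted record sequence."""

    person_id: str
    gender: str
    birth_year: int
    records: list[ClinicalRecord]

    def __post_init__(self) -> None:
        self.sort_records()

    def sort_records(self) -> None:
        # Total, stable order: date then record_id — required for reproducible
        # recurrent processing of same-day records.
        self.records.sort(key=lambda r: (r.date, r.record_id))

    def validate(self) -> None:
        if self.gender not in GENDERS:
            raise IntegrityError(f"person {self.person_id}: unknown gender {self.gender!r}")
        if not self.records:
            raise IntegrityError(f"person {self.person_id}: empty record list")
        for r in self.records:
            if r.person_id != self.person_id:
                raise IntegrityError(
                    f"record {r.record_id} carries person_id {r.person_id!r}, "
                    f"expected {self.person_id!r}"
                )
            r.validate()
        keys = [(r.date, r.record_id) for r in self.records]
        if keys != sorted(keys):
            raise IntegrityError(f"person {self.person_id}: records out of order")


@dataclass
class Cohort:
    """A set of persons sharing an epoch year (day 0 = Jan 1 of epoch_year)."""

    persons: list[Person]
    epoch_year: int = 2000

    def validate(self) -> None:
        seen: set[str] = set()
        for p in self.persons:
            if p.person_id in seen:
                raise IntegrityError(f"duplicate person_id {p.person_id!r}")
            seen.add(p.person_id)
            p.validate()

    @property
    def n_records(self) -> int:
        return sum(len(p.records) for p in self.persons)

    def iter_records(self):
        for p in self.persons:
            for r in p.records:
                yield p, r


# ---------------------------------------------------------------------------
# Interchange format

_RECORD_COLUMNS = [
    "record_id", "person_id", "date", "claim_type", "codes",
    "care_site_type", "care_site_specialization", "care_site_rank",
    "hospital_stay",
    "cost_dx", "cost_px", "cost_med", "cost_test", "cost_other",
    "count_dx", "count_px", "count_med", "count_test", "count_other",
    "discharge_dead_or_critical",
]
_PERSON_COLUMNS = ["person_id", "gender", "birth_year"]


def _serialize_codes(codes: Sequence[MedicalCode]) -> str:
    return "|".join(f"{c.category}:{c.code}" for c in codes)


def _parse_codes(text: str, where: str) -> list[MedicalCode]:
    if not text:
        return []
    out = []
    for tok in text.split("|"):
        cat, sep, code = tok.partition(":")
        if not sep or cat not in CATEGORIES or not code:
            raise CohortFormatError(f"{where}: malformed code token {tok!r}")
        out.append(MedicalCode(cat, code))
    return out


def write_cohort(cohort: Cohort, path: str) -> None:
    """Write ``persons.csv``, ``records.csv`` and ``meta.csv`` under ``path``."""
    os.makedirs(path, exist_ok=True)
    with open(os.path.join(path, "persons.csv"), "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(_PERSON_COLUMNS)
        for p in cohort.persons:
            w.writerow([p.person_id, p.gender, p.birth_year])
    with open(os.path.join(path, "records.csv"), "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(_RECORD_COLUMNS)
        for p in cohort.persons:
            for r in p.records:
                w.writerow(
                    [r.record_id, r.person_id, r.date, r.claim_type,
                     _serialize_codes(r.codes),
                     r.care_site_type, r.care_site_specialization, r.care_site_rank,
                     r.hospital_stay,
                     *(repr(float(c)) for c in r.costs),
                     *(int(n) for n in r.counts),
                     int(r.discharge_dead_or_critical)]
                )
    with open(os.path.join(path, "meta.csv"), "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["epoch_year"])
        w.writerow([cohort.epoch_year])


def read_cohort(path: str, ca_codes: Iterable[str] = DEFAULT_CA_CODES) -> Cohort:
    """Read a cohort written by :func:`write_cohort`; validates all invariants.

    Raises :class:`CohortFormatError` (naming the offending line) on malformed
    rows and :class:`IntegrityError` on duplicate person ids or invariant
    violations.
    """
    epoch_year = 2000
    meta_path = os.path.join(path, "meta.csv")
    if os.path.exists(meta_path):
        with open(meta_path, newline="", encoding="utf-8") as fh:
            rows = list(csv.reader(fh))
        try:
            epoch_year = int(rows[1][0])
        except (IndexError, ValueError) as exc:
            raise CohortFormatError(f"meta.csv: malformed epoch row") from exc

    persons: dict[str, Person] = {}
    with open(os.path.join(path, "persons.csv"), newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames != _PERSON_COLUMNS:
            raise CohortFormatError(f"persons.csv: unexpected header {reader.fieldnames}")
        for lineno, row in enumerate(reader, start=2):
            where = f"persons.csv line {lineno}"
            pid = row["person_id"]
            if not pid:
                raise CohortFormatError(f"{where}: empty person_id")
            if pid in persons:
                raise IntegrityError(f"{where}: duplicate person_id {pid!r}")
            try:
                birth_year = int(row["birth_year"])
            except ValueError as exc:
                raise CohortFormatError(f"{where}: bad birth_year") from exc
            persons[pid] = Person(pid, row["gender"], birth_year, [])

    with open(os.path.join(path, "records.csv"), newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames != _RECORD_COLUMNS:
            raise CohortFormatError(f"records.csv: unexpected header {reader.fieldnames}")
        for lineno, row in enumerate(reader, start=2):
            where = f"records.csv line {lineno}"
            try:
                codes = _parse_codes(row["codes"], where)
                rec = ClinicalRecord(
                    record_id=row["record_id"],
                    person_id=row["person_id"],
                    date=int(row["date"]),
                    claim_type=row["claim_type"],
                    codes=codes,
                    care_site_type=int(row["care_site_type"]),
                    care_site_specialization=int(row["care_site_specialization"]),
                    care_site_rank=int(row["care_site_rank"]),
                    hospital_stay=int(row["hospital_stay"]),
                    costs=[float(row[c]) for c in
                           ("cost_dx", "cost_px", "cost_med", "cost_test", "cost_other")],
                    counts=[int(row[c]) for c in
                            ("count_dx", "count_px", "count_med", "count_test", "count_other")],
                    discharge_dead_or_critical=bool(int(row["discharge_dead_or_critical"])),
                )
            except CohortFormatError:
                raise
            except (ValueError, KeyError, TypeError) as exc:
                raise CohortFormatError(f"{where}: malformed row ({exc})") from exc
            rec.is_ca = flag_ca(rec, ca_codes)
            if rec.person_id not in persons:
                raise IntegrityError(f"{where}: unknown person_id {rec.person_id!r}")
            persons[rec.person_id].records.append(rec)

    cohort = Cohort(list(persons.values()), epoch_year=epoch_year)
    for p in cohort.persons:
        p.sort_records()
    cohort.validate()
    return cohort
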