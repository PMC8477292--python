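"""Per-record 30-day outcome labels and task subsets.

Two binary targets are attached to each clinical record:

* ``mortality_30d`` — the person has a mortality event (a record flagged
  ``discharge_dead_or_critical``) 1-30 days *after* this record.  The
  mortality record itself is labeled negative (anti-leakage: terminal-record
  features trivially indicate death, and a model relying on them is useless
  for intervention), optionally dropped entirely via
  ``drop_mortality_records``.
* ``readmission_30d`` — for inpatient records only: a later inpatient
  admission starts 1-30 days after this record's discharge day
  (``date + hospital_stay``).  Outpatient records have no discharge day and
  get ``None`` (excluded from readmission losses and metrics).

All windows are inclusive integer-day windows [1, 30].

Four task subsets are derived: ALL-mortality (every labeled record),
CA-mortality (records carrying a cardiac-arrest procedure code),
ALL-readmission (readmission-eligible records) and CA-readmission
(readmission-eligible CA records).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

from .data_model import Cohort, IntegrityError, Person

__all__ = [
    "LabelSet",
    "TASK_NAMES",
    "label_mortality",
    "label_readmission",
    "build_labels",
    "build_task_masks",
]

logger = logging.getLogger(__name__)

TASK_NAMES = ("ALL-mortality", "CA-mortality", "ALL-readmission", "CA-readmission")

WINDOW_DAYS = 30


@dataclass(frozen=True)
class LabelSet:
    """Targets for one record; ``readmission_30d`` is None when ineligible."""

    record_id: str
    mortality_30d: int
    readmission_30d: Optional[int]
    is_ca: bool


def _mortality_day(person: Person) -> Optional[int]:
    days = [r.date for r in person.records if r.discharge_dead_or_critical]
    if len(days) > 1:
        raise IntegrityError(
            f"person {person.person_id}: {len(days)} mortality records (at most one allowed)"
        )
    return days[0] if days else None


def label_mortality(person: Person) -> list[int]:
    """Binary 30-day mortality label per record (sorted order).

    Positive iff the mortality event day d_m satisfies 1 <= d_m - date <= 30.
    The mortality record itself (gap 0) is always negative.
    """
    d_m = _mortality_day(person)
    out = []
    for r in person.records:
        if d_m is None or r.discharge_dead_or_critical:
            out.append(0)
        else:
            gap = d_m - r.date
            out.append(1 if 1 <= gap <= WINDOW_DAYS else 0)
    return out


def label_readmission(person: Person) -> list[Optional[int]]:
    """30-day readmission label per record; None for outpatient records.

    An inpatient record is positive iff a later inpatient record starts
    1-30 days after its discharge day.  Overlapping stays (non-positive
    computed gap) contribute a 0, with a logged warning.
    """
    recs = person.records
    out: list[Optional[int]] = []
    for i, r in enumerate(recs):
        if r.claim_type != "inpatient":
            out.append(None)
            continue
        discharge = r.date + r.hospital_stay
        label = 0
        for later in recs[i + 1:]:
            if later.claim_type != "inpatient":
                continue
            gap = later.date - discharge
            if gap <= 0:
                logger.warning(
                    "person %s: inpatient record %s starts before discharge of %s "
                    "(gap %d); counted as non-readmission",
                    person.person_id, later.record_id, r.record_id, gap,
                )
                continue
            if gap <= WINDOW_DAYS:
                label = 1
                break
        out.append(label)
    return out


def build_labels(cohort: Cohort, drop_mortality_records: bool = False) -> list[LabelSet]:
    """LabelSets for every record of the cohort, in cohort iteration order.

    With ``drop_mortality_records`` the records flagged
    ``discharge_dead_or_critical`` are omitted (the stricter exclusion
    reading) instead of kept as negatives.
    """
    out: list[LabelSet] = []
    for person in cohort.persons:
        mort = label_mortality(person)
        readm = label_readmission(person)
        for r, m, d in zip(person.records, mort, readm):
            if drop_mortality_records and r.discharge_dead_or_critical:
                continue
            out.append(LabelSet(r.record_id, m, d, r.is_ca))
    return out


def build_task_masks(labels: list[LabelSet]) -> dict[str, tuple[list[str], list[int]]]:
    """Map each task name to its (record_ids, labels) pair.

    CA tasks restrict to CA records; readmission tasks restrict to
    readmission-eligible records.  CA sets may be empty.
    """
    masks: dict[str, tuple[list[str], list[int]]] = {}
    masks["ALL-mortality"] = (
        [l.record_id for l in labels],
        [l.mortality_30d for l in labels],
    )
    masks["CA-mortality"] = (
        [l.record_id for l in labels if l.is_ca],
        [l.mortality_30d for l in labels if l.is_ca],
    )
    elig = [l for l in labels if l.readmission_30d is not None]
    masks["ALL-readmission"] = (
        [l.record_id for l in elig],
        [int(l.readmission_30d) for l in elig],
    )
    masks["CA-readmission"] = (
        [l.record_id for l in elig if l.is_ca],
        [int(l.readmission_30d) for l in elig if l.is_ca],
    )
    return masks
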