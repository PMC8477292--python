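"""Record featurization: the 707-dimensional clinical record vector.

Each record maps to a fixed concatenation of named spans:

==============================  ====
span                            dims
==============================  ====
diagnosis code-embedding sum     128
procedure code-embedding sum     128
medication code-embedding sum    128
test code-embedding sum          128
other code-embedding sum         128
claim type (one-hot)               2
age at record (scaled)             1
gender (one-hot)                   2
care-site type (one-hot)          21
care-site specialization          5
care-site rank (one-hot)          17
hospital stay (scaled)             1
total cost per category (5)        5
total count per category (5)       5
past hospitalization duration      4
past admission count               4
==============================  ====

for a total of exactly 707 dimensions.  Codes within a category are summed
in embedding space (multiset sum: a duplicated code counts twice), so the
span is a zero vector when the category is empty and the result is
order-independent.

Code embeddings are deterministic hashed random unit-variance vectors keyed
by (category, code) and a seed; they preserve code identity (which is where
the synthetic severity signal lives) without any claim of semantic
similarity structure.

Scalar features (age, stay, costs, counts, history) are z-scored with
statistics fitted on the training split only; costs are log1p-transformed
first.  The scaler freezes after fitting — transforming validation or test
data can never update its statistics.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .data_model import (
    CATEGORIES,
    ClinicalRecord,
    Cohort,
    N_CARE_SITE_RANK,
    N_CARE_SITE_SPECIALIZATION,
    N_CARE_SITE_TYPE,
    Person,
)

__all__ = [
    "LAYOUT",
    "SPAN_SLICES",
    "TOTAL_DIM",
    "GROUP_SLICES",
    "HISTORY_WINDOWS_DAYS",
    "CodeEmbeddingTable",
    "RecordVector",
    "FeatureScaler",
    "make_embedding_table",
    "embed_category",
    "history_features",
    "build_record_vector",
    "raw_record_vector",
    "featurize_cohort_raw",
]

CODE_EMBED_DIM = 128

LAYOUT: tuple[tuple[str, int], ...] = (
    ("diagnosis", CODE_EMBED_DIM),
    ("procedures", CODE_EMBED_DIM),
    ("meds", CODE_EMBED_DIM),
    ("tests", CODE_EMBED_DIM),
    ("other", CODE_EMBED_DIM),
    ("claim_type", 2),
    ("age", 1),
    ("gender", 2),
    ("care_site_type", N_CARE_SITE_TYPE),
    ("care_site_specialization", N_CARE_SITE_SPECIALIZATION),
    ("care_site_rank", N_CARE_SITE_RANK),
    ("hospital_stay", 1),
    ("total_cost", 5),
    ("total_count", 5),
    ("past_hospitalization_duration", 4),
    ("past_admission_count", 4),
)


def _span_slices() -> dict[str, slice]:
    out, off = {}, 0
    for name, length in LAYOUT:
        out[name] = slice(off, off + length)
        off += length
    return out


SPAN_SLICES = _span_slices()
TOTAL_DIM = sum(length for _, length in LAYOUT)  # 707

#: Natural groupings of the input used as autoencoder reconstruction targets:
#: the five code-embedding spans, the demographic/care-site context, and the
#: record statistics + history scalars.
GROUP_SLICES = {
    "codes": slice(0, 5 * CODE_EMBED_DIM),                      # 640
    "context": slice(5 * CODE_EMBED_DIM, SPAN_SLICES["care_site_rank"].stop),  # 48
    "stats": slice(SPAN_SLICES["hospital_stay"].start, TOTAL_DIM),             # 19
}

#: Look-back windows (days) for the historical features: 3/6/12/24 months.
HISTORY_WINDOWS_DAYS = (90, 180, 365, 730)

# Scalar (z-scored) columns: age, hospital_stay, costs, counts, history.
_SCALAR_SPANS = ("age", "hospital_stay", "total_cost", "total_count",
                 "past_hospitalization_duration", "past_admission_count")
SCALAR_COLUMNS = np.concatenate(
    [np.arange(SPAN_SLICES[s].start, SPAN_SLICES[s].stop) for s in _SCALAR_SPANS]
)
COST_COLUMNS = np.arange(SPAN_SLICES["total_cost"].start, SPAN_SLICES["total_cost"].stop)


# ---------------------------------------------------------------------------
# Code embeddings

class CodeEmbeddingTable:
    """Deterministic (category, code) -> vector lookup.

    Vectors are standard-normal with the configured dimension, derived from a
    stable 64-bit hash of (seed, category, code): the same inputs give the
    same vector on any machine or run.  Unknown codes raise a
    :class:`KeyError` naming the code unless an ``unknown_vector`` was
    configured.
    """

    def __init__(self, dimension: int = CODE_EMBED_DIM,
                 vectors: Optional[dict] = None, seed: int = 0,
                 unknown_vector: Optional[np.ndarray] = None):
        if dimension < 1:
            raise ValueError("dimension must be >= 1")
        self.dimension = dimension
        self.seed = seed
        self.vectors: dict[tuple[str, str], np.ndarray] = dict(vectors or {})
        for v in self.vectors.values():
            if v.shape != (dimension,):
                raise ValueError("all embedding vectors must have the table dimension")
        self.unknown_vector = unknown_vector

    @staticmethod
    def _hash_vector(category: str, code: str, dimension: int, seed: int) -> np.ndarray:
        digest = hashlib.blake2b(
            f"{seed}|{category}|{code}".encode(), digest_size=8
        ).digest()
        sub = np.random.default_rng(int.from_bytes(digest, "little"))
        return sub.standard_normal(dimension)

    def lookup(self, category: str, code: str) -> np.ndarray:
        key = (category, code)
        v = self.vectors.get(key)
        if v is None:
            if self.unknown_vector is not None:
                return self.unknown_vector
            raise KeyError(f"no embedding for code {code!r} in category {category!r}")
        return v

    def add(self, category: str, code: str) -> np.ndarray:
        """Materialize (deterministically) and cache the vector for a code."""
        key = (category, code)
        if key not in self.vectors:
            self.vectors[key] = self._hash_vector(category, code, self.dimension, self.seed)
        return self.vectors[key]


def make_embedding_table(vocab: Sequence[tuple[str, str]], dimension: int = CODE_EMBED_DIM,
                         seed: int = 0,
                         unknown_vector: Optional[np.ndarray] = None) -> CodeEmbeddingTable:
    """Build a table of deterministic hashed random vectors for a vocabulary."""
    table = CodeEmbeddingTable(dimension=dimension, seed=seed, unknown_vector=unknown_vector)
    for category, code in vocab:
        table.add(category, code)
    return table


def make_table_for_cohort(cohort: Cohort, dimension: int = CODE_EMBED_DIM,
                          seed: int = 0) -> CodeEmbeddingTable:
    vocab = sorted({(c.category, c.code)
                    for _, r in cohort.iter_records() for c in r.codes})
    return make_embedding_table(vocab, dimension=dimension, seed=seed)


def embed_category(record: ClinicalRecord, category: str,
                   table: CodeEmbeddingTable) -> np.ndarray:
    """Multiset sum of the embeddings of the record's codes in one category.

    Codes are summed in sorted order so the result is exactly (not just up
    to rounding) invariant under permutations of the code list.
    """
    out = np.zeros(table.dimension)
    tokens = sorted(c.code for c in record.codes if c.category == category)
    for code in tokens:
        out += table.lookup(category, code)
    return out


# ---------------------------------------------------------------------------
# History features

def history_features(person: Person, record: ClinicalRecord) -> np.ndarray:
    """Inpatient-stay days and admission counts in the 90/180/365/730-day
    windows strictly before the record's date: 4 durations then 4 counts."""
    durations = np.zeros(4)
    counts = np.zeros(4)
    for prior in person.records:
        gap = record.date - prior.date
        if gap <= 0:
            continue
        if prior.claim_type != "inpatient":
            continue
        for k, w in enumerate(HISTORY_WINDOWS_DAYS):
            if gap <= w:
                durations[k] += prior.hospital_stay
                counts[k] += 1
    return np.concatenate([durations, counts])


# ---------------------------------------------------------------------------
# Scaling

class FeatureScaler:
    """Z-scores the scalar columns of raw record vectors (costs log1p first).

    Fit on training rows only; freezes afterwards.  ``transform`` never
    mutates the fitted statistics.
    """

    def __init__(self) -> None:
        self.mean_: Optional[np.ndarray] = None
        self.std_: Optional[np.ndarray] = None
        self.fitted = False

    def fit(self, raw_matrix: np.ndarray) -> "FeatureScaler":
        if self.fitted:
            raise RuntimeError("FeatureScaler is frozen after fitting")
        x = raw_matrix[:, SCALAR_COLUMNS].astype(float).copy()
        cost_local = np.searchsorted(SCALAR_COLUMNS, COST_COLUMNS)
        x[:, cost_local] = np.log1p(x[:, cost_local])
        self.mean_ = x.mean(axis=0)
        std = x.std(axis=0, ddof=0)
        std[std == 0.0] = 1.0
        self.std_ = std
        self.fitted = True
        return self

    def transform(self, raw_matrix: np.ndarray) -> np.ndarray:
        if not self.fitted:
            raise RuntimeError("FeatureScaler.transform called before fit")
        out = np.array(raw_matrix, dtype=float, copy=True)
        cost_local = np.searchsorted(SCALAR_COLUMNS, COST_COLUMNS)
        scal = out[:, SCALAR_COLUMNS]
        scal[:, cost_local] = np.log1p(scal[:, cost_local])
        out[:, SCALAR_COLUMNS] = (scal - self.mean_) / self.std_
        return out

    def state(self) -> dict:
        return {"mean": None if self.mean_ is None else self.mean_.copy(),
                "std": None if self.std_ is None else self.std_.copy()}


# ---------------------------------------------------------------------------
# Record vectors

@dataclass
class RecordVector:
    """A 707-dim feature vector with named-span access."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (TOTAL_DIM,):
            raise ValueError(f"record vector must have length {TOTAL_DIM}")

    def span(self, name: str) -> np.ndarray:
        return self.values[SPAN_SLICES[name]]


def _one_hot(index: int, size: int, what: str) -> np.ndarray:
    if not 0 <= index < size:
        raise ValueError(f"{what} level {index} out of range [0, {size})")
    v = np.zeros(size)
    v[index] = 1.0
    return v


def raw_record_vector(person: Person, record: ClinicalRecord,
                      table: CodeEmbeddingTable, epoch_year: int = 2000) -> np.ndarray:
    """The unscaled 707-dim vector (scalar spans in natural units)."""
    parts = [embed_category(record, cat, table) for cat in CATEGORIES]
    parts.append(_one_hot(0 if record.claim_type == "inpatient" else 1, 2, "claim_type"))
    age_years = (epoch_year + record.date // 365) - person.birth_year
    parts.append(np.array([float(age_years)]))
    parts.append(_one_hot(0 if person.gender == "male" else 1, 2, "gender"))
    parts.append(_one_hot(record.care_site_type, N_CARE_SITE_TYPE, "care_site_type"))
    parts.append(_one_hot(record.care_site_specialization, N_CARE_SITE_SPECIALIZATION,
                          "care_site_specialization"))
    parts.append(_one_hot(record.care_site_rank, N_CARE_SITE_RANK, "care_site_rank"))
    parts.append(np.array([float(record.hospital_stay)]))
    parts.append(np.asarray(record.costs, dtype=float))
    parts.append(np.asarray(record.counts, dtype=float))
    parts.append(history_features(person, record))
    return np.concatenate(parts)


def build_record_vector(person: Person, record: ClinicalRecord,
                        table: CodeEmbeddingTable, scaler: FeatureScaler,
                        epoch_year: int = 2000) -> RecordVector:
    """The final (scaled) 707-dim record vector."""
    raw = raw_record_vector(person, record, table, epoch_year=epoch_year)
    return RecordVector(scaler.transform(raw[None, :])[0])


def featurize_cohort_raw(cohort: Cohort, table: CodeEmbeddingTable) -> dict[str, np.ndarray]:
    """Unscaled (T_p, 707) feature matrix per person id.

    Scaling is a cheap affine pass, so raw features can be shared across
    training runs that use different train/validation/test splits.
    """
    out = {}
    for person in cohort.persons:
        rows = [raw_record_vector(person, r, table, epoch_year=cohort.epoch_year)
                for r in person.records]
        out[person.person_id] = np.stack(rows)
    return out
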