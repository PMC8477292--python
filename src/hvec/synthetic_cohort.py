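"""Synthetic claims-cohort generator.

Emulates the statistical structure a claims-based cardiac-arrest outcome
model has to cope with: persons with a geometric-like number of visits
(mean ~9.3), rare cardiac-arrest (CA) index records flagged by resuscitation
procedure codes, outcome rates tunable down to the ~0.5% regime of
CA-mortality, and a planted severity signal linking code identity to
outcomes so that learning is detectable.

The generative model
--------------------
Each person carries a scalar latent severity ``s ~ Normal(0, 1)`` that
drives everything observable:

* codes — each drawn code comes from a "severe" sub-vocabulary with
  probability ``sigmoid(s - 1)``, otherwise from the common part;
* CA events — inpatient records carry a resuscitation procedure code with a
  severity-tilted probability calibrated so the marginal per-record CA rate
  equals ``ca_rate_per_record``;
* mortality — after each record the person dies with a per-record hazard
  ``sigmoid(c + severity_effect * s)``; the intercept ``c`` is calibrated
  (Gauss-Hermite quadrature) so the marginal hazard equals
  ``base_mortality_rate`` for non-CA records and ``ca_mortality_target_rate``
  for CA records.  A death appends a terminal record flagged
  ``discharge_dead_or_critical`` 1-30 days after discharge and ends the
  sequence;
* readmission — after each inpatient record, the next visit is an inpatient
  admission within 1-30 days of discharge with probability
  ``sigmoid(c_r + severity_effect * s)`` (marginal calibrated to
  ``base_readmission_rate``); otherwise the next visit starts 31-120 days
  after discharge, so accidental readmissions cannot occur;
* costs — lognormal with log-mean increasing in severity and code count.

Because death truncates sequences, the nominal geometric visit-count
parameter is calibrated (closed-form expectation under the geometric/hazard
competition, averaged over severity by quadrature) so that the *realized*
mean records per person matches ``mean_records_per_person``.

Generation is a pure function of the config, including its seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numpy.polynomial.hermite_e import hermegauss
from scipy.optimize import brentq
from scipy.special import expit, logit

from .data_model import (
    CATEGORIES,
    ClinicalRecord,
    Cohort,
    MedicalCode,
    N_CARE_SITE_RANK,
    N_CARE_SITE_SPECIALIZATION,
    N_CARE_SITE_TYPE,
    Person,
    flag_ca,
)

__all__ = ["GeneratorConfig", "generate_cohort", "cohort_summary"]

# Fixed structural constants of the generator (not per-study dials).
INPATIENT_FRACTION = 0.3
SEVERE_VOCAB_FRACTION = 0.2
CODES_PER_CATEGORY_MEAN = (2.0, 1.0, 2.0, 1.5, 0.5)  # aligned with CATEGORIES
CODE_PREFIX = ("D", "P", "M", "T", "O")
CA_SEVERITY_GAIN = 0.5      # severity tilt of the CA-event probability
MEAN_STAY_EXTRA = 3.0       # inpatient stay = 1 + Poisson(MEAN_STAY_EXTRA)
LOG_COST_BASE = 6.0
LOG_COST_SD = 0.5
MALE_FRACTION = 0.379       # study-population demographics
AGE_MEAN, AGE_SD = 68.66, 18.96


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for one synthetic cohort."""

    n_persons: int
    mean_records_per_person: float = 9.3
    code_vocab_size_per_category: int = 200
    ca_rate_per_record: float = 0.11
    severity_effect: float = 1.5
    base_mortality_rate: float = 0.02
    base_readmission_rate: float = 0.30
    ca_mortality_target_rate: float = 0.0053
    seed: int = 0

    def validate(self) -> None:
        if self.n_persons < 1:
            raise ValueError("n_persons must be >= 1")
        if self.mean_records_per_person < 1:
            raise ValueError("mean_records_per_person must be >= 1")
        if self.code_vocab_size_per_category < 1:
            raise ValueError("code_vocab_size_per_category must be >= 1")
        for name in ("ca_rate_per_record", "base_mortality_rate",
                     "base_readmission_rate", "ca_mortality_target_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability, got {v}")
        if self.severity_effect < 0:
            raise ValueError("severity_effect must be non-negative")
        if self.ca_rate_per_record > INPATIENT_FRACTION:
            raise ValueError(
                "ca_rate_per_record cannot exceed the inpatient record fraction "
                f"({INPATIENT_FRACTION}): CA events occur on inpatient records only"
            )


# ---------------------------------------------------------------------------
# Calibration helpers (deterministic, quadrature-based)

_GH_NODES, _GH_WEIGHTS = hermegauss(80)
_GH_WEIGHTS = _GH_WEIGHTS / math.sqrt(2.0 * math.pi)  # E[f(s)], s ~ N(0,1)


def _normal_mean(f) -> float:
    return float(np.sum(_GH_WEIGHTS * f(_GH_NODES)))


def _calibrate_intercept(target: float, slope: float) -> float:
    """Intercept c with E_s[sigmoid(c + slope*s)] = target, s ~ N(0,1)."""
    if target <= 0.0:
        return -np.inf
    if target >= 1.0:
        return np.inf
    if slope == 0.0:
        return float(logit(target))
    g = lambda c: _normal_mean(lambda s: expit(c + slope * s)) - target
    return float(brentq(g, -60.0, 60.0, xtol=1e-12))


@dataclass(frozen=True)
class _Calibration:
    c_ca: float          # CA probability intercept (among inpatient records)
    c_mort: float        # non-CA per-record death-hazard intercept
    c_mort_ca: float     # CA-record death-hazard intercept
    c_readmit: float     # inpatient 30-day readmission intercept
    geom_p: float        # nominal geometric visit-count parameter


def _marginal_hazard(cal_c_ca: float, c_mort: float, c_mort_ca: float,
                     effect: float, s: np.ndarray) -> np.ndarray:
    p_ca = INPATIENT_FRACTION * expit(cal_c_ca + CA_SEVERITY_GAIN * s)
    q0 = expit(c_mort + effect * s)
    qca = expit(c_mort_ca + effect * s)
    return (1.0 - p_ca) * q0 + p_ca * qca


def _calibrate(config: GeneratorConfig) -> _Calibration:
    c_ca = _calibrate_intercept(
        config.ca_rate_per_record / INPATIENT_FRACTION, CA_SEVERITY_GAIN
    )
    c_mort = _calibrate_intercept(config.base_mortality_rate, config.severity_effect)
    # CA-record hazard is calibrated against the severity distribution of CA
    # records (tilted towards high s when CA_SEVERITY_GAIN > 0).
    if config.ca_mortality_target_rate <= 0.0:
        c_mort_ca = -np.inf
    elif config.ca_rate_per_record <= 0.0:
        c_mort_ca = _calibrate_intercept(
            config.ca_mortality_target_rate, config.severity_effect
        )
    else:
        w_ca = expit(c_ca + CA_SEVERITY_GAIN * _GH_NODES)
        w_ca = w_ca / np.sum(_GH_WEIGHTS * w_ca)

        def gap(c):
            rate = np.sum(
                _GH_WEIGHTS * w_ca * expit(c + config.severity_effect * _GH_NODES)
            )
            return rate - config.ca_mortality_target_rate

        c_mort_ca = float(brentq(gap, -60.0, 60.0, xtol=1e-12))
    c_readmit = _calibrate_intercept(config.base_readmission_rate, config.severity_effect)

    # Realized-mean calibration: under a nominal Geometric(p) visit count
    # (support 1, 2, ...) competing with a per-record death hazard q(s), the
    # expected number of kept clinical records is K = 1 / (1 - (1-p)(1-q)) and
    # a death record is appended with probability q*K, so
    # E[total records | s] = K(s) * (1 + q(s)).
    q_s = _marginal_hazard(c_ca, c_mort, c_mort_ca, config.severity_effect, _GH_NODES)
    q_s = np.clip(q_s, 0.0, 1.0)

    def realized_mean(p: float) -> float:
        K = 1.0 / (1.0 - (1.0 - p) * (1.0 - q_s))
        return float(np.sum(_GH_WEIGHTS * K * (1.0 + q_s)))

    target = config.mean_records_per_person
    lo, hi = 1e-9, 1.0 - 1e-12
    if realized_mean(hi) >= target:
        geom_p = hi  # target at/below the 1-visit floor; use shortest sequences
    elif realized_mean(lo) <= target:
        raise ValueError(
            "mean_records_per_person unreachable: death hazard truncates "
            "sequences below the requested mean"
        )
    else:
        geom_p = float(brentq(lambda p: realized_mean(p) - target, lo, hi, xtol=1e-12))
    return _Calibration(c_ca, c_mort, c_mort_ca, c_readmit, geom_p)


# ---------------------------------------------------------------------------
# Generation

def _draw_codes(rng: np.random.Generator, s: float, vocab_size: int) -> list[MedicalCode]:
    n_severe = max(1, int(SEVERE_VOCAB_FRACTION * vocab_size))
    p_severe = expit(s - 1.0)
    codes: list[MedicalCode] = []
    for cat, lam, prefix in zip(CATEGORIES, CODES_PER_CATEGORY_MEAN, CODE_PREFIX):
        for _ in range(int(rng.poisson(lam))):
            if rng.random() < p_severe:
                idx = int(rng.integers(0, n_severe))
            else:
                idx = int(rng.integers(n_severe, max(vocab_size, n_severe + 1)))
            codes.append(MedicalCode(cat, f"{prefix}{idx:04d}"))
    return codes


def _make_record(rng: np.random.Generator, person_id: str, seq: int, date: int,
                 inpatient: bool, s: float, vocab_size: int,
                 ca: bool, dead: bool) -> ClinicalRecord:
    codes = _draw_codes(rng, s, vocab_size)
    if ca:
        ca_code = "99.60" if rng.random() < 0.5 else "99.63"
        codes.append(MedicalCode("procedure", ca_code))
    counts = [sum(1 for c in codes if c.category == cat) for cat in CATEGORIES]
    stay = int(1 + rng.poisson(MEAN_STAY_EXTRA)) if inpatient else 0
    costs = []
    for k, n in enumerate(counts):
        if n > 0:
            mu = LOG_COST_BASE + 0.3 * s + 0.25 * n
            costs.append(float(np.exp(rng.normal(mu, LOG_COST_SD))))
        else:
            costs.append(0.0)
    rec = ClinicalRecord(
        record_id=f"{person_id}-r{seq:03d}",
        person_id=person_id,
        date=int(date),
        claim_type="inpatient" if inpatient else "outpatient",
        codes=codes,
        care_site_type=int(rng.integers(N_CARE_SITE_TYPE)),
        care_site_specialization=int(rng.integers(N_CARE_SITE_SPECIALIZATION)),
        care_site_rank=int(rng.integers(N_CARE_SITE_RANK)),
        hospital_stay=stay,
        costs=costs,
        counts=counts,
        discharge_dead_or_critical=dead,
    )
    rec.is_ca = flag_ca(rec)
    return rec


def generate_cohort(config: GeneratorConfig, return_severity: bool = False):
    """Generate a cohort; pure function of ``config`` (incl. its seed).

    With ``return_severity`` also returns the per-person latent severity
    (a diagnostic for signal-recovery checks; real cohorts have no such
    observable).
    """
    config.validate()
    cal = _calibrate(config)
    rng = np.random.default_rng(config.seed)
    epoch_year = 2000
    severities: dict[str, float] = {}
    persons: list[Person] = []
    for i in range(config.n_persons):
        pid = f"p{i:06d}"
        s = float(rng.normal())
        severities[pid] = s
        gender = "male" if rng.random() < MALE_FRACTION else "female"
        start = int(rng.integers(0, 731))
        age0 = float(np.clip(rng.normal(AGE_MEAN, AGE_SD), 0.0, 110.0))
        birth_year = epoch_year + start // 365 - int(age0)

        n_nominal = int(rng.geometric(cal.geom_p))
        records: list[ClinicalRecord] = []
        date = start
        # A 30-day readmission forces the next record to be inpatient, so the
        # free inpatient probability beta is set per person to keep the
        # stationary inpatient fraction at INPATIENT_FRACTION:
        # pi = pi*(r + (1-r)*beta) + (1-pi)*beta  =>  beta = pi(1-r)/(1-pi*r).
        r_s = float(expit(cal.c_readmit + config.severity_effect * s))
        pi = INPATIENT_FRACTION
        beta = pi * (1.0 - r_s) / (1.0 - pi * r_s)
        inpatient = bool(rng.random() < pi)
        for j in range(n_nominal):
            is_ca = inpatient and (
                rng.random() < expit(cal.c_ca + CA_SEVERITY_GAIN * s)
            )
            rec = _make_record(rng, pid, len(records), date, inpatient, s,
                               config.code_vocab_size_per_category,
                               ca=is_ca, dead=False)
            records.append(rec)
            discharge = date + rec.hospital_stay

            hazard_c = cal.c_mort_ca if is_ca else cal.c_mort
            q = expit(hazard_c + config.severity_effect * s)
            if rng.random() < q:
                death_gap = int(rng.integers(1, 31))
                death_inpat = bool(rng.random() < 0.5)
                records.append(
                    _make_record(rng, pid, len(records), discharge + death_gap,
                                 death_inpat, s,
                                 config.code_vocab_size_per_category,
                                 ca=False, dead=True)
                )
                break

            if j == n_nominal - 1:
                break
            if inpatient:
                if rng.random() < expit(cal.c_readmit + config.severity_effect * s):
                    gap = int(rng.integers(1, 31))
                    next_inpatient = True
                else:
                    gap = int(rng.integers(31, 121))
                    next_inpatient = bool(rng.random() < beta)
            else:
                gap = int(rng.integers(1, 91))
                next_inpatient = bool(rng.random() < beta)
            date = discharge + gap
            inpatient = next_inpatient

        persons.append(Person(pid, gender, birth_year, records))
    cohort = Cohort(persons, epoch_year=epoch_year)
    if return_severity:
        return cohort, severities
    return cohort


# ---------------------------------------------------------------------------
# Summary

def cohort_summary(cohort: Cohort) -> dict:
    """Headline cohort statistics and per-task positive rates.

    CA-task rates are ``nan`` (not 0) when the cohort has no CA records;
    readmission rates are computed over readmission-eligible (inpatient)
    records only.
    """
    from .labeling import build_labels  # deferred: labeling imports data_model only

    if not cohort.persons:
        raise ValueError("cohort_summary requires a non-empty cohort")
    counts = np.array([len(p.records) for p in cohort.persons], dtype=float)
    labels = build_labels(cohort)
    mort = np.array([l.mortality_30d for l in labels], dtype=float)
    readm = np.array(
        [np.nan if l.readmission_30d is None else float(l.readmission_30d) for l in labels]
    )
    ca = np.array([l.is_ca for l in labels], dtype=bool)

    def _rate(values: np.ndarray) -> float:
        values = values[~np.isnan(values)]
        return float(values.mean()) if values.size else float("nan")

    return {
        "n_persons": len(cohort.persons),
        "n_records": int(counts.sum()),
        "mean_records_per_person": float(counts.mean()),
        "sd_records_per_person": float(counts.std(ddof=0)),
        "ca_record_fraction": float(ca.mean()),
        "rate_all_mortality": _rate(mort),
        "rate_ca_mortality": _rate(mort[ca]) if ca.any() else float("nan"),
        "rate_all_readmission": _rate(readm),
        "rate_ca_readmission": _rate(readm[ca]) if ca.any() else float("nan"),
    }
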