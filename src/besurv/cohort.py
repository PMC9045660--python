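"""Surveillance-cohort data model, CSV I/O, validation and descriptive epidemiology.

A cohort couples three tables keyed by patient id:

* baseline — age at index endoscopy and gender;
* visits — repeated endoscopies with dichotomized biomarker calls
  (LGD histology, p53 and SOX2 immunohistochemistry) and the time-varying
  covariates esophagitis and Barrett-segment length (long = >=3 cm);
* outcomes — time of HGD/EAC detection or censoring, with delayed entry
  (a six-month run-in excludes prevalent neoplasia; person-time starts at
  0.5 years).

Biomarker codes are normalized to {0, 1, NaN}: "indefinite for dysplasia"
histology is treated as a missing LGD value, and p53/SOX2 are "aberrant"
(overexpression or loss for p53, loss for SOX2) versus "normal".
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PatientBaseline",
    "VisitRecord",
    "OutcomeRecord",
    "Cohort",
    "ExclusionReport",
    "CohortValidationError",
    "read_cohort",
    "write_cohort",
    "apply_eligibility_filters",
    "standardize_age",
    "compute_incidence",
]

#: Entry offset implementing the six-month run-in (left truncation), years.
DEFAULT_ENTRY_YEARS = 0.5

MARKERS = ("lgd", "p53", "sox2")

# Accepted textual dialects for the dichotomized calls.
_LGD_CODES = {"NDBE": 0.0, "LGD": 1.0, "IND": math.nan, "": math.nan}
_IHC_CODES = {"NORMAL": 0.0, "ABERRANT": 1.0, "": math.nan}


class CohortValidationError(ValueError):
    """Structural or contract violation in cohort inputs."""


@dataclass(frozen=True)
class PatientBaseline:
    patient_id: str
    age_years: float
    female: int

    def __post_init__(self):
        if not 18.0 < self.age_years < 110.0:
            raise CohortValidationError(
                f"patient {self.patient_id}: age {self.age_years} outside (18, 110)"
            )
        if self.female not in (0, 1):
            raise CohortValidationError(
                f"patient {self.patient_id}: female must be 0/1, got {self.female}"
            )


@dataclass(frozen=True)
class VisitRecord:
    patient_id: str
    time_years: float
    lgd: float  # 0, 1 or NaN
    p53: float
    sox2: float
    esophagitis: int
    long_segment: int

    def marker(self, name: str) -> float:
        return getattr(self, name)


@dataclass(frozen=True)
class OutcomeRecord:
    patient_id: str
    event_time_years: float
    event: int
    entry_time_years: float = 0.0


@dataclass
class Cohort:
    """Validated analysis dataset: one baseline and one outcome per patient,
    time-ordered visits."""

    baselines: list[PatientBaseline]
    visits: list[VisitRecord]
    outcomes: list[OutcomeRecord]
    age_scaler: tuple[float, float] | None = None

    @property
    def patient_ids(self) -> list[str]:
        return [b.patient_id for b in self.baselines]

    @property
    def n_patients(self) -> int:
        return len(self.baselines)

    def visits_of(self, patient_id: str) -> list[VisitRecord]:
        return [v for v in self.visits if v.patient_id == patient_id]

    def outcome_of(self, patient_id: str) -> OutcomeRecord:
        for o in self.outcomes:
            if o.patient_id == patient_id:
                return o
        raise KeyError(patient_id)

    def baseline_of(self, patient_id: str) -> PatientBaseline:
        for b in self.baselines:
            if b.patient_id == patient_id:
                return b
        raise KeyError(patient_id)

    def subset(self, patient_ids) -> "Cohort":
        keep = set(patient_ids)
        return Cohort(
            baselines=[b for b in self.baselines if b.patient_id in keep],
            visits=[v for v in self.visits if v.patient_id in keep],
            outcomes=[o for o in self.outcomes if o.patient_id in keep],
            age_scaler=self.age_scaler,
        )

    def resample(self, patient_ids: list[str], suffix_sep: str = "#") -> "Cohort":
        """Bootstrap helper: build a cohort from a with-replacement draw of
        patient ids, disambiguating repeats with ``id#k`` suffixes."""
        baselines, visits, outcomes = [], [], []
        for k, pid in enumerate(patient_ids):
            new_id = f"{pid}{suffix_sep}{k}"
            baselines.append(replace(self.baseline_of(pid), patient_id=new_id))
            visits.extend(
                replace(v, patient_id=new_id) for v in self.visits_of(pid)
            )
            outcomes.append(replace(self.outcome_of(pid), patient_id=new_id))
        return Cohort(baselines, visits, outcomes, age_scaler=self.age_scaler)


@dataclass(frozen=True)
class ExclusionReport:
    n_eligible: int
    n_excluded_no_marker_data: int
    n_excluded_short_followup: int
    n_included: int

    def __post_init__(self):
        total_excluded = self.n_excluded_no_marker_data + self.n_excluded_short_followup
        if self.n_included != self.n_eligible - total_excluded:
            raise CohortValidationError("exclusion report counts are inconsistent")
        if min(self.n_eligible, self.n_excluded_no_marker_data,
               self.n_excluded_short_followup, self.n_included) < 0:
            raise CohortValidationError("exclusion counts must be nonnegative")


def _norm_marker(raw, codes: dict, col: str, pid: str) -> float:
    if raw is None or (isinstance(raw, float) and math.isnan(raw)):
        return math.nan
    s = str(raw).strip()
    if s.upper() in codes:
        return codes[s.upper()]
    try:
        val = float(s)
    except ValueError:
        raise CohortValidationError(
            f"patient {pid}: unrecognized {col} code {raw!r}"
        ) from None
    if val in (0.0, 1.0):
        return val
    raise CohortValidationError(f"patient {pid}: {col} must be 0/1, got {raw!r}")


def _validate(cohort: Cohort) -> Cohort:
    ids = [b.patient_id for b in cohort.baselines]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise CohortValidationError(f"duplicate patient_id in baseline: {dupes}")
    known = set(ids)

    out_ids = [o.patient_id for o in cohort.outcomes]
    if len(set(out_ids)) != len(out_ids):
        raise CohortValidationError("duplicate patient_id in outcomes")
    for o in cohort.outcomes:
        if o.patient_id not in known:
            raise CohortValidationError(f"outcome for unknown patient_id {o.patient_id!r}")
        if o.event not in (0, 1):
            raise CohortValidationError(f"patient {o.patient_id}: event must be 0/1")
        if o.event_time_years <= 0:
            raise CohortValidationError(
                f"patient {o.patient_id}: event_time_years must be positive"
            )
    missing_outcome = known - set(out_ids)
    if missing_outcome:
        raise CohortValidationError(
            f"patients without an outcome record: {sorted(missing_outcome)}"
        )

    outcome_time = {o.patient_id: o.event_time_years for o in cohort.outcomes}
    by_patient: dict[str, list[VisitRecord]] = {}
    for v in cohort.visits:
        if v.patient_id not in known:
            raise CohortValidationError(f"visit for unknown patient_id {v.patient_id!r}")
        if v.esophagitis not in (0, 1) or v.long_segment not in (0, 1):
            raise CohortValidationError(
                f"patient {v.patient_id}: esophagitis/long_segment must be 0/1"
            )
        if v.time_years > outcome_time[v.patient_id]:
            raise CohortValidationError(
                f"patient {v.patient_id}: visit at t={v.time_years} after "
                f"event/censor time {outcome_time[v.patient_id]}"
            )
        by_patient.setdefault(v.patient_id, []).append(v)

    visits_sorted: list[VisitRecord] = []
    for pid in ids:
        vs = sorted(by_patient.get(pid, []), key=lambda v: v.time_years)
        if not vs:
            raise CohortValidationError(f"patient {pid}: no visits")
        times = [v.time_years for v in vs]
        if len(set(times)) != len(times):
            raise CohortValidationError(f"patient {pid}: duplicate visit times")
        if vs[0].time_years != 0.0:
            raise CohortValidationError(f"patient {pid}: no index visit at t=0")
        visits_sorted.extend(vs)

    cohort.visits = visits_sorted
    return cohort


def read_cohort(baseline_path, visits_path, outcomes_path) -> Cohort:
    """Read and validate the three CSV tables into a :class:`Cohort`.

    LGD accepts {NDBE, LGD, IND, 0, 1, blank}; IND (indefinite for dysplasia)
    maps to missing. p53/SOX2 accept {normal, aberrant, 0, 1, blank}.
    Esophagitis and segment length missing at a follow-up visit are carried
    forward from the previous visit; missing at the index visit is an error.
    """
    base = pd.read_csv(baseline_path, dtype={"patient_id": str})
    vis = pd.read_csv(visits_path, dtype={"patient_id": str})
    out = pd.read_csv(outcomes_path, dtype={"patient_id": str})

    for df, cols, name in (
        (base, ["patient_id", "age_years", "female"], "baseline"),
        (vis, ["patient_id", "time_years", "lgd", "p53", "sox2",
               "esophagitis", "long_segment"], "visits"),
        (out, ["patient_id", "event_time_years", "event"], "outcomes"),
    ):
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise CohortValidationError(f"{name} table missing columns {missing}")

    baselines = [
        PatientBaseline(r.patient_id, float(r.age_years), int(r.female))
        for r in base.itertuples()
    ]

    visits = []
    vis = vis.sort_values(["patient_id", "time_years"], kind="stable")
    carry: dict[str, tuple[int, int]] = {}
    for r in vis.itertuples():
        pid = r.patient_id
        eso, seg = r.esophagitis, r.long_segment
        if pd.isna(eso) or pd.isna(seg):
            if pid not in carry:
                raise CohortValidationError(
                    f"patient {pid}: esophagitis/long_segment missing at index visit"
                )
            prev = carry[pid]
            eso = prev[0] if pd.isna(eso) else eso
            seg = prev[1] if pd.isna(seg) else seg
        eso, seg = int(eso), int(seg)
        carry[pid] = (eso, seg)
        visits.append(
            VisitRecord(
                patient_id=pid,
                time_years=float(r.time_years),
                lgd=_norm_marker(r.lgd, _LGD_CODES, "lgd", pid),
                p53=_norm_marker(r.p53, _IHC_CODES, "p53", pid),
                sox2=_norm_marker(r.sox2, _IHC_CODES, "sox2", pid),
                esophagitis=eso,
                long_segment=seg,
            )
        )

    has_entry = "entry_time_years" in out.columns
    outcomes = [
        OutcomeRecord(
            patient_id=r.patient_id,
            event_time_years=float(r.event_time_years),
            event=int(r.event),
            entry_time_years=float(r.entry_time_years) if has_entry else 0.0,
        )
        for r in out.itertuples()
    ]

    return _validate(Cohort(baselines, visits, outcomes))


def write_cohort(cohort: Cohort, baseline_path, visits_path, outcomes_path) -> None:
    """Write the three CSV tables (inverse of :func:`read_cohort`)."""
    pd.DataFrame(
        [(b.patient_id, b.age_years, b.female) for b in cohort.baselines],
        columns=["patient_id", "age_years", "female"],
    ).to_csv(baseline_path, index=False)
    pd.DataFrame(
        [
            (v.patient_id, v.time_years, v.lgd, v.p53, v.sox2,
             v.esophagitis, v.long_segment)
            for v in cohort.visits
        ],
        columns=["patient_id", "time_years", "lgd", "p53", "sox2",
                 "esophagitis", "long_segment"],
    ).to_csv(visits_path, index=False)
    pd.DataFrame(
        [
            (o.patient_id, o.event_time_years, o.event, o.entry_time_years)
            for o in cohort.outcomes
        ],
        columns=["patient_id", "event_time_years", "event", "entry_time_years"],
    ).to_csv(outcomes_path, index=False)


def apply_eligibility_filters(
    cohort: Cohort, min_followup_years: float = DEFAULT_ENTRY_YEARS
) -> tuple[Cohort, ExclusionReport]:
    """Apply the run-in and tissue-availability exclusions.

    Patients whose event or censoring falls inside the six-month run-in are
    removed (prevalent-neoplasia exclusion), as are patients with no
    non-missing biomarker call at any visit (no assessable material).
    Retained patients get ``entry_time_years = min_followup_years`` (left
    truncation); the operation is idempotent.
    """
    n_eligible = cohort.n_patients
    short, nomarker, keep = [], [], []
    for b in cohort.baselines:
        pid = b.patient_id
        o = cohort.outcome_of(pid)
        if o.event_time_years <= min_followup_years:
            short.append(pid)
            continue
        vs = cohort.visits_of(pid)
        if all(
            math.isnan(v.marker(m)) for v in vs for m in MARKERS
        ):
            nomarker.append(pid)
            continue
        keep.append(pid)

    if not keep:
        raise CohortValidationError("no patients remain after eligibility filtering")

    filtered = cohort.subset(keep)
    filtered.outcomes = [
        replace(o, entry_time_years=min_followup_years) for o in filtered.outcomes
    ]
    report = ExclusionReport(
        n_eligible=n_eligible,
        n_excluded_no_marker_data=len(nomarker),
        n_excluded_short_followup=len(short),
        n_included=len(keep),
    )
    return filtered, report


def standardize_age(cohort: Cohort) -> Cohort:
    """Freeze the cohort's age scaler (sample mean, sd with ddof=1).

    Downstream model matrices use (age - mean)/sd; the scaler is persisted
    with fitted models and reused verbatim when scoring new patients.
    """
    ages = np.array([b.age_years for b in cohort.baselines], dtype=float)
    if len(np.unique(ages)) < 2:
        raise CohortValidationError("age standardization requires >=2 distinct ages")
    mean, sd = float(ages.mean()), float(ages.std(ddof=1))
    if sd == 0.0:
        raise CohortValidationError("zero age variance")
    return Cohort(
        baselines=cohort.baselines,
        visits=cohort.visits,
        outcomes=cohort.outcomes,
        age_scaler=(mean, sd),
    )


def standardized_age(cohort: Cohort, age_years: float) -> float:
    if cohort.age_scaler is None:
        raise CohortValidationError("age scaler not set; call standardize_age first")
    mean, sd = cohort.age_scaler
    return (age_years - mean) / sd


def compute_incidence(cohort: Cohort) -> dict:
    """Incidence rate per 100 person-years with an exact Poisson 95% CI.

    Person-time per patient is follow-up minus the run-in (entry time), per
    the delayed-entry accounting.
    """
    py = sum(
        o.event_time_years - o.entry_time_years for o in cohort.outcomes
    )
    if py <= 0:
        raise CohortValidationError("zero person-years at risk")
    events = sum(o.event for o in cohort.outcomes)
    rate = 100.0 * events / py
    if events == 0:
        lo = 0.0
    else:
        lo = 100.0 * stats.chi2.ppf(0.025, 2 * events) / 2.0 / py
    hi = 100.0 * stats.chi2.ppf(0.975, 2 * events + 2) / 2.0 / py
    return {
        "events": int(events),
        "person_years": float(py),
        "rate_per_100py": float(rate),
        "ci95": (float(lo), float(hi)),
    }
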