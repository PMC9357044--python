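"""Cohort data model and delimited-table I/O.

An active-surveillance cohort is represented as one static table (one row
per patient), one long-format longitudinal table (one row per visit, wide
across co-measured variables), and an optional outcomes table.  Times are
integer days since diagnosis; day 0 is the diagnosis day.  Empty cells are
missing values.
"""

from __future__ import annotations

import copy
import logging
import math
from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

logger = logging.getLogger(__name__)

MRI_STAGES = ("T1", "T2", "T3")

STATIC_COLUMNS = [
    "patient_id", "age", "family_history", "ethnicity", "grade_group",
    "mri_stage", "likert", "psa", "volume", "psa_density", "core_positivity",
]
LONG_COLUMNS = [
    "patient_id", "day", "psa", "psa_density", "volume", "precise",
    "biopsy_grade_group", "cores_total", "cores_positive", "mri_stage",
]
OUTCOME_COLUMNS = ["patient_id", "event", "time_days", "cause_scenario", "censor_reason"]


@dataclass
class StaticProfile:
    """Diagnostic baseline covariates at active-surveillance entry."""

    age_at_entry: float
    family_history: bool
    ethnicity: str  # {"white", "other"}
    grade_group: int  # 1-5; entry criterion restricts to {1, 2}
    mri_stage: str  # {"T1", "T2", "T3"}
    likert: Optional[int] = None  # 1-5
    psa_baseline: float = 0.0  # ng/mL
    prostate_volume: Optional[float] = None  # mL
    psa_density: Optional[float] = None  # ng/mL/mL
    core_positivity: Optional[float] = None  # fraction of positive cores
    entry_cpg: Optional[int] = None  # derived, 1 or 2


@dataclass
class Observation:
    """One follow-up visit; only the measured fields are non-null."""

    t: int  # days since diagnosis
    psa: Optional[float] = None
    psa_density: Optional[float] = None
    prostate_volume: Optional[float] = None
    precise: Optional[int] = None
    biopsy_grade_group: Optional[int] = None
    cores_total: Optional[int] = None
    cores_positive: Optional[int] = None
    mri_stage: Optional[str] = None


@dataclass
class Outcome:
    """Composite-endpoint outcome: event indicator + time, with provenance."""

    event: bool
    time: int  # days since diagnosis
    cause_scenario: str = "none"  # {"i","ii","iii","iv","none"}
    censor_reason: str = "none"  # {"treatment","death","last_investigation","none"}


@dataclass
class ClinicalPathway:
    """One patient: static profile, time-ordered observations, outcome."""

    patient_id: str
    static: StaticProfile
    observations: list[Observation] = field(default_factory=list)
    outcome: Optional[Outcome] = None


@dataclass
class Cohort:
    pathways: list[ClinicalPathway] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.pathways)

    def __iter__(self):
        return iter(self.pathways)

    def by_id(self, patient_id: str) -> ClinicalPathway:
        for p in self.pathways:
            if p.patient_id == patient_id:
                return p
        raise KeyError(patient_id)


@dataclass
class Finding:
    patient_id: str
    message: str


@dataclass
class ValidationReport:
    findings: list[Finding] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.findings


# ---------------------------------------------------------------------------
# reading

def _opt_float(v) -> Optional[float]:
    if v is None or (isinstance(v, float) and math.isnan(v)) or v == "":
        return None
    return float(v)


def _opt_int(v) -> Optional[int]:
    f = _opt_float(v)
    return None if f is None else int(round(f))


def _opt_bool(v) -> Optional[bool]:
    if v is None or (isinstance(v, float) and math.isnan(v)) or v == "":
        return None
    if isinstance(v, str):
        return v.strip().lower() in ("true", "1", "yes")
    return bool(v)


def _opt_str(v) -> Optional[str]:
    if v is None or (isinstance(v, float) and math.isnan(v)) or v == "":
        return None
    return str(v)


_STATIC_NUMERIC = ["age", "grade_group", "likert", "psa", "volume",
                   "psa_density", "core_positivity"]
_LONG_NUMERIC = ["day", "psa", "psa_density", "volume", "precise",
                 "biopsy_grade_group", "cores_total", "cores_positive"]


def _check_numeric(df: pd.DataFrame, cols: list[str], table: str) -> None:
    for col in cols:
        if col not in df.columns:
            continue
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df[col].notna() & (df[col].astype(str).str.strip() != "") & coerced.isna()
        if bad.any():
            row = int(bad.idxmax()) + 2  # header + 1-based
            raise ValueError(
                f"non-numeric value {df[col][bad].iloc[0]!r} in column "
                f"{col!r} of {table} table (file row {row})"
            )
        df[col] = coerced


def read_cohort(static_path, longitudinal_path, outcomes_path=None) -> Cohort:
    """Read a cohort from its delimited-table representation.

    Observations are returned sorted by day within each patient.  Unknown
    columns are ignored with a logged warning.  Outcomes are attached when
    ``outcomes_path`` is given, else every pathway's outcome is None.
    """
    static = pd.read_csv(static_path, dtype={"patient_id": str})
    long = pd.read_csv(longitudinal_path, dtype={"patient_id": str})

    for df, known, name in ((static, STATIC_COLUMNS, "static"),
                            (long, LONG_COLUMNS, "longitudinal")):
        extra = [c for c in df.columns if c not in known]
        if extra:
            logger.warning("ignoring unknown %s columns: %s", name, extra)

    _check_numeric(static, _STATIC_NUMERIC, "static")
    _check_numeric(long, _LONG_NUMERIC, "longitudinal")

    dup = static["patient_id"][static["patient_id"].duplicated()]
    if len(dup):
        raise ValueError(f"duplicate patient_id in static table: {sorted(set(dup))}")

    known_ids = set(static["patient_id"])
    unknown = sorted(set(long["patient_id"]) - known_ids)
    if unknown:
        raise ValueError(f"longitudinal rows reference unknown patient_ids: {unknown}")

    outcomes: dict[str, Outcome] = {}
    if outcomes_path is not None:
        odf = pd.read_csv(outcomes_path, dtype={"patient_id": str})
        for _, r in odf.iterrows():
            outcomes[r["patient_id"]] = Outcome(
                event=bool(_opt_bool(r["event"])),
                time=int(r["time_days"]),
                cause_scenario=_opt_str(r.get("cause_scenario")) or "none",
                censor_reason=_opt_str(r.get("censor_reason")) or "none",
            )

    pathways = []
    grouped = dict(tuple(long.groupby("patient_id", sort=False)))
    for _, r in static.iterrows():
        pid = r["patient_id"]
        prof = StaticProfile(
            age_at_entry=float(r["age"]),
            family_history=bool(_opt_bool(r["family_history"])),
            ethnicity=_opt_str(r.get("ethnicity")) or "white",
            grade_group=int(r["grade_group"]),
            mri_stage=str(r["mri_stage"]),
            likert=_opt_int(r.get("likert")),
            psa_baseline=float(r["psa"]),
            prostate_volume=_opt_float(r.get("volume")),
            psa_density=_opt_float(r.get("psa_density")),
            core_positivity=_opt_float(r.get("core_positivity")),
        )
        obs = []
        if pid in grouped:
            sub = grouped[pid].sort_values("day", kind="stable")
            for _, o in sub.iterrows():
                obs.append(Observation(
                    t=int(o["day"]),
                    psa=_opt_float(o.get("psa")),
                    psa_density=_opt_float(o.get("psa_density")),
                    prostate_volume=_opt_float(o.get("volume")),
                    precise=_opt_int(o.get("precise")),
                    biopsy_grade_group=_opt_int(o.get("biopsy_grade_group")),
                    cores_total=_opt_int(o.get("cores_total")),
                    cores_positive=_opt_int(o.get("cores_positive")),
                    mri_stage=_opt_str(o.get("mri_stage")),
                ))
        pathways.append(ClinicalPathway(
            patient_id=pid, static=prof, observations=obs,
            outcome=outcomes.get(pid),
        ))
    return Cohort(pathways=pathways,
                  provenance={"static": str(static_path),
                              "longitudinal": str(longitudinal_path)})


# ---------------------------------------------------------------------------
# writing

def _cell(v):
    if v is None:
        return ""
    if isinstance(v, bool):
        return str(v)
    return v


def write_cohort(cohort: Cohort, static_path, longitudinal_path,
                 outcomes_path=None) -> None:
    """Write a cohort back to its three-table representation.

    Nulls become empty cells; ``read_cohort(write_cohort(c))`` reproduces
    ``c`` field for field.
    """
    srows, lrows, orows = [], [], []
    for p in cohort.pathways:
        s = p.static
        srows.append({
            "patient_id": p.patient_id, "age": s.age_at_entry,
            "family_history": s.family_history, "ethnicity": s.ethnicity,
            "grade_group": s.grade_group, "mri_stage": s.mri_stage,
            "likert": _cell(s.likert), "psa": s.psa_baseline,
            "volume": _cell(s.prostate_volume),
            "psa_density": _cell(s.psa_density),
            "core_positivity": _cell(s.core_positivity),
        })
        for o in p.observations:
            lrows.append({
                "patient_id": p.patient_id, "day": o.t,
                "psa": _cell(o.psa), "psa_density": _cell(o.psa_density),
                "volume": _cell(o.prostate_volume),
                "precise": _cell(o.precise),
                "biopsy_grade_group": _cell(o.biopsy_grade_group),
                "cores_total": _cell(o.cores_total),
                "cores_positive": _cell(o.cores_positive),
                "mri_stage": _cell(o.mri_stage),
            })
        if p.outcome is not None:
            orows.append({
                "patient_id": p.patient_id, "event": p.outcome.event,
                "time_days": p.outcome.time,
                "cause_scenario": p.outcome.cause_scenario,
                "censor_reason": p.outcome.censor_reason,
            })
    pd.DataFrame(srows, columns=STATIC_COLUMNS).to_csv(static_path, index=False)
    pd.DataFrame(lrows, columns=LONG_COLUMNS).to_csv(longitudinal_path, index=False)
    if outcomes_path is not None:
        pd.DataFrame(orows, columns=OUTCOME_COLUMNS).to_csv(outcomes_path, index=False)


# ---------------------------------------------------------------------------
# validation

def validate_cohort(cohort: Cohort) -> ValidationReport:
    """Report type-invariant violations without mutating the cohort."""
    findings: list[Finding] = []
    seen: set[str] = set()
    for p in cohort.pathways:
        if p.patient_id in seen:
            findings.append(Finding(p.patient_id, "duplicate patient_id"))
        seen.add(p.patient_id)
        s = p.static
        if s.grade_group not in (1, 2):
            findings.append(Finding(p.patient_id, "entry criterion violated: grade_group > 2"))
        if s.mri_stage not in MRI_STAGES:
            findings.append(Finding(p.patient_id, f"unknown mri_stage {s.mri_stage!r}"))
        if (s.psa_density is not None and s.prostate_volume is not None
                and s.prostate_volume > 0 and s.psa_baseline is not None):
            expect = s.psa_baseline / s.prostate_volume
            if expect > 0 and abs(s.psa_density - expect) > 1e-6 * max(expect, 1e-12):
                findings.append(Finding(p.patient_id, "psa_density inconsistent with psa/volume"))
        prev_t = -1
        for o in p.observations:
            if o.t <= prev_t:
                findings.append(Finding(p.patient_id, f"non-increasing time at day {o.t}"))
            prev_t = o.t
            if (o.cores_positive is not None and o.cores_total is not None
                    and o.cores_positive > o.cores_total):
                findings.append(Finding(p.patient_id, f"cores_positive > cores_total at day {o.t}"))
            if all(getattr(o, f) is None for f in (
                    "psa", "psa_density", "prostate_volume", "precise",
                    "biopsy_grade_group", "cores_total", "cores_positive", "mri_stage")):
                findings.append(Finding(p.patient_id, f"empty observation at day {o.t}"))
        if p.outcome is not None:
            oc = p.outcome
            if oc.event != (oc.cause_scenario != "none"):
                findings.append(Finding(p.patient_id, "event flag inconsistent with cause_scenario"))
            if (not oc.event) != (oc.censor_reason != "none"):
                findings.append(Finding(p.patient_id, "event flag inconsistent with censor_reason"))
    return ValidationReport(findings=findings)


def copy_cohort(cohort: Cohort) -> Cohort:
    return copy.deepcopy(cohort)
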