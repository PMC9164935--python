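"""Liver-injury event detection in longitudinal laboratory data.

A qualifying liver-injury event is the first study day on which
ALT or AST reaches 3x the upper limit of normal (ULN), or ALP or total
bilirubin reaches 2x ULN (thresholds inclusive).  At that onset day the
three phenotype parameters are derived:

* latency  = onset study day (first dose = day 1 by convention),
* R-value  = (ALT in xULN) / (ALP in xULN) from same-day values,
* AST/ALT  = the de Ritis ratio from same-day raw values.

Bilirubin-only events are detected but flagged, since the phenotype
parameters describe enzyme patterns; missing same-day ALP (or ALT)
leaves the R-value (or ratio) undefined rather than silently zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "ANALYTES",
    "LabObservation",
    "PatientCourse",
    "InjuryEvent",
    "DetectionThresholds",
    "detect_event",
    "detect_events",
    "compute_r",
    "compute_ratio",
]

ANALYTES = ("ALT", "AST", "ALP", "TBIL")

#: Trigger priority when several analytes qualify on the same day.
_TRIGGER_PRIORITY = {"ALT": 0, "AST": 1, "ALP": 2, "TBIL": 3}


@dataclass(frozen=True)
class LabObservation:
    """One analyte measurement on one study day."""

    patient_id: str
    arm: str
    study_day: int
    analyte: str
    value: float
    uln: float

    def __post_init__(self) -> None:
        if self.analyte not in ANALYTES:
            raise ValueError(f"unknown analyte {self.analyte!r}; expected one of {ANALYTES}")
        if self.study_day < 1:
            raise ValueError(f"study_day must be >= 1 (first dose = day 1), got {self.study_day}")
        if not self.value >= 0:
            raise ValueError(f"lab value must be non-negative, got {self.value}")
        if not self.uln > 0:
            raise ValueError(
                f"missing or non-positive ULN for patient {self.patient_id!r} "
                f"day {self.study_day} analyte {self.analyte}"
            )

    @property
    def xuln(self) -> float:
        return self.value / self.uln


@dataclass
class PatientCourse:
    """A patient's longitudinal liver panel, grouped by study day."""

    patient_id: str
    arm: str
    observations: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.observations = sorted(self.observations, key=lambda o: (o.study_day, _TRIGGER_PRIORITY[o.analyte]))
        seen = set()
        for o in self.observations:
            key = (o.study_day, o.analyte)
            if key in seen:
                raise ValueError(
                    f"patient {self.patient_id!r}: duplicate {o.analyte} on day {o.study_day}"
                )
            seen.add(key)

    def days(self) -> list[int]:
        return sorted({o.study_day for o in self.observations})

    def on_day(self, day: int) -> dict[str, LabObservation]:
        return {o.analyte: o for o in self.observations if o.study_day == day}

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, patient_id: str) -> "PatientCourse":
        sub = df[df["patient_id"] == patient_id]
        if sub.empty:
            raise ValueError(f"no observations for patient {patient_id!r}")
        arms = sub["arm"].unique()
        if len(arms) != 1:
            raise ValueError(f"patient {patient_id!r} appears under multiple arms: {list(arms)}")
        obs = [
            LabObservation(
                patient_id=str(r.patient_id),
                arm=str(r.arm),
                study_day=int(r.study_day),
                analyte=str(r.analyte),
                value=float(r.value),
                uln=float(r.uln),
            )
            for r in sub.itertuples()
        ]
        return cls(patient_id=str(patient_id), arm=str(arms[0]), observations=obs)


@dataclass(frozen=True)
class InjuryEvent:
    """A detected liver-injury onset with its phenotype parameters."""

    patient_id: str
    arm: str
    onset_day: int
    trigger: str
    latency_days: int
    r_value: Optional[float]
    ast_alt_ratio: Optional[float]
    flags: tuple = ()


@dataclass(frozen=True)
class DetectionThresholds:
    """Event-qualification thresholds (multiples of ULN) and the latency
    day-numbering convention."""

    alt_xuln: float = 3.0
    ast_xuln: float = 3.0
    alp_xuln: float = 2.0
    tbil_xuln: float = 2.0
    #: Added to the onset study day to yield latency; 0 keeps the
    #: first-dose-equals-day-1 convention where latency = onset day.
    day_offset: int = 0

    def threshold(self, analyte: str) -> float:
        return {"ALT": self.alt_xuln, "AST": self.ast_xuln, "ALP": self.alp_xuln, "TBIL": self.tbil_xuln}[analyte]


def compute_r(alt_xuln: float, alp_xuln: Optional[float]) -> Optional[float]:
    """R-value: (ALT in xULN) / (ALP in xULN); ``None`` (undefined) when
    ALP is missing or non-positive, never a silent zero."""
    if alp_xuln is None or not alp_xuln > 0:
        warnings.warn("R-value undefined: ALP (xULN) missing or non-positive", stacklevel=2)
        return None
    return alt_xuln / alp_xuln


def compute_ratio(ast: float, alt: Optional[float]) -> Optional[float]:
    """De Ritis AST/ALT ratio from raw (same-unit) values; undefined
    when ALT is missing or zero."""
    if alt is None or alt == 0:
        warnings.warn("AST/ALT ratio undefined: ALT missing or zero", stacklevel=2)
        return None
    return ast / alt


def detect_event(
    course: PatientCourse,
    thresholds: DetectionThresholds = DetectionThresholds(),
) -> Optional[InjuryEvent]:
    """Find the first qualifying liver-injury day in a patient course.

    Returns ``None`` when no day qualifies (or the course is empty).
    The onset is minimal: no earlier day satisfies any threshold.  When
    several analytes qualify on the same day the trigger is recorded in
    the priority order ALT > AST > ALP > TBIL (the choice does not
    affect the phenotype parameters).
    """
    if not course.observations:
        return None
    for day in course.days():
        obs = course.on_day(day)
        qualifying = [
            a for a in ANALYTES if a in obs and obs[a].xuln >= thresholds.threshold(a)
        ]
        if not qualifying:
            continue
        trigger = min(qualifying, key=_TRIGGER_PRIORITY.get)
        flags = []
        if trigger == "TBIL" and len(qualifying) == 1:
            flags.append("bilirubin_only_trigger")

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r = (
                compute_r(obs["ALT"].xuln, obs["ALP"].xuln if "ALP" in obs else None)
                if "ALT" in obs
                else None
            )
            ratio = (
                compute_ratio(obs["AST"].value, obs["ALT"].value)
                if "AST" in obs and "ALT" in obs
                else None
            )
        if r is None:
            flags.append("r_value_undefined")
        if ratio is None:
            flags.append("ast_alt_ratio_undefined")
        return InjuryEvent(
            patient_id=course.patient_id,
            arm=course.arm,
            onset_day=day,
            trigger=trigger,
            latency_days=day + thresholds.day_offset,
            r_value=r,
            ast_alt_ratio=ratio,
            flags=tuple(flags),
        )
    return None


def detect_events(
    labs: pd.DataFrame,
    thresholds: DetectionThresholds = DetectionThresholds(),
) -> pd.DataFrame:
    """Run :func:`detect_event` over every patient in a long-format lab
    table and return the detected events as a data frame.

    Expected columns: patient_id, arm, study_day, analyte, value, uln.
    Patients are processed in first-appearance order; row order within a
    patient is irrelevant.
    """
    required = {"patient_id", "arm", "study_day", "analyte", "value", "uln"}
    missing = required - set(labs.columns)
    if missing:
        raise ValueError(f"lab table missing column(s) {sorted(missing)}")
    rows = []
    for pid in labs["patient_id"].drop_duplicates():
        course = PatientCourse.from_dataframe(labs, pid)
        ev = detect_event(course, thresholds)
        if ev is None:
            continue
        rows.append(
            {
                "patient_id": ev.patient_id,
                "arm": ev.arm,
                "latency_days": ev.latency_days,
                "r_value": np.nan if ev.r_value is None else ev.r_value,
                "ast_alt_ratio": np.nan if ev.ast_alt_ratio is None else ev.ast_alt_ratio,
                "trigger": ev.trigger,
                "flags": ";".join(ev.flags),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["patient_id", "arm", "latency_days", "r_value", "ast_alt_ratio", "trigger", "flags"],
    )
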