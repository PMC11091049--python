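"""Domain types for paired meal-test cohorts.

A cohort is a set of subjects, each with up to two arms: a plain meal test
(``MT``) and a meal test preceded by an inhaled insulin dose (``MT_I``).
Each arm carries sampled plasma glucose, insulin and C-peptide series on a
common time grid (minutes from the meal start).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import DomainError, ValidationError

ARM_MT = "MT"
ARM_MT_I = "MT_I"
ARMS = (ARM_MT, ARM_MT_I)

ANALYTES = ("glucose", "insulin", "cpeptide")

#: Sampling grid of the study design (minutes).
STUDY_TIME_GRID = (0.0, 7.0, 15.0, 30.0, 60.0, 120.0, 240.0, 300.0, 360.0)


@dataclass
class SubjectRecord:
    """Demographics and dosing information for one subject.

    ``category`` selects the population class for the C-peptide kinetic
    constants; only ``"normal"`` (healthy, non-obese) is implemented.
    """

    subject_id: str
    sex: str  # "male" | "female"
    age: float  # years
    weight: float  # kg
    bmi: float  # kg/m^2
    height: Optional[float] = None  # m, measured; derivable from weight and bmi
    dose_U: Optional[float] = None  # insulin units administered in the MT_I arm
    category: str = "normal"

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValidationError(f"sex must be 'male' or 'female', got {self.sex!r}")
        for name in ("age", "weight", "bmi"):
            if not getattr(self, name) > 0:
                raise DomainError(f"{name} must be positive for subject {self.subject_id}")
        if self.height is not None and not self.height > 0:
            raise DomainError(f"height must be positive for subject {self.subject_id}")
        if self.dose_U is not None and not self.dose_U > 0:
            raise DomainError(f"dose_U must be positive for subject {self.subject_id}")


def derive_height(subject: SubjectRecord) -> float:
    """Height in metres: the measured value if present, else ``sqrt(weight/bmi)``.

    A measured height wins even when it is inconsistent with weight/BMI.
    """
    if subject.height is not None:
        return subject.height
    if not (subject.weight > 0 and subject.bmi > 0):
        raise DomainError("weight and bmi must be positive to derive height")
    return math.sqrt(subject.weight / subject.bmi)


@dataclass
class AnalyteSeries:
    """One analyte sampled over time, stored in canonical units.

    Canonical units: glucose mg/dL, insulin and C-peptide pmol/L.
    """

    analyte: str
    times: np.ndarray  # min, strictly increasing, first == 0
    values: np.ndarray
    source_unit: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.analyte not in ANALYTES:
            raise ValidationError(f"unknown analyte {self.analyte!r}")
        if self.times.ndim != 1 or self.times.shape != self.values.shape:
            raise ValidationError("times and values must be 1-d arrays of equal length")
        if self.times.size == 0:
            raise ValidationError("series must contain at least one sample")
        if self.times[0] != 0:
            raise ValidationError(f"{self.analyte}: first sampling time must be 0 min")
        if np.any(np.diff(self.times) <= 0):
            raise ValidationError(f"{self.analyte}: sampling times must be strictly increasing")
        if np.any(self.values < 0):
            raise ValidationError(f"{self.analyte}: negative concentration encountered")

    def __len__(self) -> int:
        return self.times.size


@dataclass
class MealTestDataset:
    """One subject's sampled meal-test arm (glucose, insulin, C-peptide)."""

    subject: SubjectRecord
    arm: str  # "MT" | "MT_I"
    glucose: AnalyteSeries
    insulin: AnalyteSeries
    cpeptide: AnalyteSeries

    def __post_init__(self) -> None:
        if self.arm not in ARMS:
            raise ValidationError(f"arm must be one of {ARMS}, got {self.arm!r}")
        for series, name in ((self.glucose, "glucose"), (self.insulin, "insulin"), (self.cpeptide, "cpeptide")):
            if series.analyte != name:
                raise ValidationError(f"series in slot {name!r} is labelled {series.analyte!r}")
        # After per-analyte dropping of missing samples the three grids may
        # legitimately differ; a mismatch is reported, not rejected.
        grids = [self.glucose.times, self.insulin.times, self.cpeptide.times]
        if not all(len(g) == len(grids[0]) and np.array_equal(g, grids[0]) for g in grids[1:]):
            warnings.warn(
                f"subject {self.subject.subject_id} arm {self.arm}: analyte time grids differ "
                "(missing samples were dropped per analyte)",
                stacklevel=2,
            )

    @property
    def key(self) -> tuple:
        return (self.subject.subject_id, self.arm)
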