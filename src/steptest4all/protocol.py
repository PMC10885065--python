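"""Test individualization and conduct logic.

The step test is a continuous progressive protocol on a single step whose
height is individualized from five categorical ponderation factors (sex, age
class, physical fitness, BMI band, smoking status):

    step height (cm) = 4 x (sum of factor values) + 15,   bounded to [15, 40].

Cadence starts at 15 cycles/min (0.25 Hz) and rises by 2.5 cycles/min per
stage up to 37.5 cycles/min, within a 10-minute cap. The test stops at the
first heart-rate sample reaching the target — 80% of the age-predicted
maximum HRmax = 208 − 0.7·age — or earlier on an operator flag (discomfort,
cadence failure).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

from .errors import ValidationError

__all__ = [
    "Sex",
    "AgeClass",
    "FitnessClass",
    "ParticipantProfile",
    "CadenceSchedule",
    "StepConfig",
    "TerminationDecision",
    "ponderation_sum",
    "step_height",
    "age_predicted_hrmax",
    "target_hr",
    "cadence_schedule",
    "termination_check",
    "age_class_from_age",
    "fitness_class_from_pa_level",
    "build_step_config",
]


class Sex(str, Enum):
    WOMAN = "woman"
    MAN = "man"

    @property
    def code(self) -> int:
        """Numeric coding used by the prediction equation (women 0, men 1)."""
        return 0 if self is Sex.WOMAN else 1


class AgeClass(str, Enum):
    YOUNG = "young"
    ADULT = "adult"
    SENIOR = "senior"


class FitnessClass(str, Enum):
    INSUFFICIENTLY_ACTIVE = "insufficiently_active"
    MODERATELY_ACTIVE = "moderately_active"
    VIGOROUSLY_ACTIVE = "vigorously_active"


# Ponderation factor values; they feed the step-height formula only.
SEX_POINTS = {Sex.WOMAN: 0.5, Sex.MAN: 1.0}
AGE_POINTS = {AgeClass.SENIOR: 0.0, AgeClass.ADULT: 0.5, AgeClass.YOUNG: 1.0}
FITNESS_POINTS = {
    FitnessClass.INSUFFICIENTLY_ACTIVE: 0.0,
    FitnessClass.MODERATELY_ACTIVE: 0.5,
    FitnessClass.VIGOROUSLY_ACTIVE: 1.0,
}

DEFAULT_AGE_CUTOFFS = (35.0, 65.0)  # young < 35 <= adult < 65 <= senior


def bmi_points(bmi: float) -> float:
    """BMI ponderation band: <25 -> 0.5; 25-<30 -> 0; >=30 -> -0.5."""
    if bmi <= 0:
        raise ValidationError(f"bmi must be positive, got {bmi!r}")
    if bmi < 25:
        return 0.5
    if bmi < 30:
        return 0.0
    return -0.5


def smoking_points(smoker: bool) -> float:
    return 0.0 if smoker else 0.5


@dataclass
class ParticipantProfile:
    """Demographics and categorical factors feeding step height and prediction.

    ``age_class`` and ``bmi`` may be left unset when ``age`` respectively
    ``body_mass``/``height`` are available; they are then derived.
    """

    sex: Sex
    age: Optional[float] = None
    age_class: Optional[AgeClass] = None
    fitness_class: Optional[FitnessClass] = None
    bmi: Optional[float] = None
    smoker: bool = False
    body_mass: Optional[float] = None  # kg
    height: Optional[float] = None  # m

    def __post_init__(self):
        self.sex = Sex(self.sex)
        if self.age_class is not None:
            self.age_class = AgeClass(self.age_class)
        if self.fitness_class is not None:
            self.fitness_class = FitnessClass(self.fitness_class)
        if self.age is not None and self.age <= 0:
            raise ValidationError(f"age must be positive, got {self.age!r}")
        if self.age_class is None and self.age is not None:
            self.age_class = age_class_from_age(self.age)
        derived_bmi = None
        if self.body_mass is not None and self.height is not None:
            if self.height <= 0 or self.body_mass <= 0:
                raise ValidationError("body_mass and height must be positive")
            derived_bmi = self.body_mass / self.height**2
        if self.bmi is None:
            self.bmi = derived_bmi
        elif derived_bmi is not None and abs(self.bmi - derived_bmi) > 0.1:
            raise ValidationError(
                f"bmi={self.bmi:.2f} inconsistent with body_mass/height^2="
                f"{derived_bmi:.2f} (tolerance 0.1 kg/m^2)"
            )
        if self.bmi is not None and self.bmi <= 0:
            raise ValidationError(f"bmi must be positive, got {self.bmi!r}")


@dataclass(frozen=True)
class CadenceSchedule:
    """Ordered stage plan: (stage index, cadence in cycles/min, start time s)."""

    stage_duration: float  # s
    stages: tuple[tuple[int, float, float], ...]
    max_duration: float  # minutes

    @property
    def n_stages(self) -> int:
        return len(self.stages)

    def cadence_of(self, stage_index: int) -> float:
        for idx, cadence, _ in self.stages:
            if idx == stage_index:
                return cadence
        raise ValidationError(f"stage {stage_index} not in schedule")


@dataclass(frozen=True)
class StepConfig:
    """Fully individualized test plan for one participant."""

    step_height: float  # cm
    schedule: CadenceSchedule
    target_hr: float  # bpm


@dataclass(frozen=True)
class TerminationDecision:
    reason: str  # target_reached | discomfort | cadence_failure | completed
    time: Optional[float] = None  # s; None when completed
    hr: Optional[float] = None  # bpm at the triggering sample


def age_class_from_age(
    age: float, cutoffs: tuple[float, float] = DEFAULT_AGE_CUTOFFS
) -> AgeClass:
    """Map age in years onto the ponderation age class (young/adult/senior)."""
    if age <= 0:
        raise ValidationError(f"age must be positive, got {age!r}")
    young_below, senior_from = cutoffs
    if age < young_below:
        return AgeClass.YOUNG
    if age < senior_from:
        return AgeClass.ADULT
    return AgeClass.SENIOR


def fitness_class_from_pa_level(pa_level: int) -> FitnessClass:
    """Default mapping from IPAQ level: 1 -> insufficiently, 2 -> moderately,
    3 -> vigorously active. Overridable by setting the profile field directly."""
    mapping = {
        1: FitnessClass.INSUFFICIENTLY_ACTIVE,
        2: FitnessClass.MODERATELY_ACTIVE,
        3: FitnessClass.VIGOROUSLY_ACTIVE,
    }
    if pa_level not in mapping:
        raise ValidationError(f"pa_level must be 1, 2, or 3, got {pa_level!r}")
    return mapping[pa_level]


def ponderation_sum(profile: ParticipantProfile) -> float:
    """Sum of the five ponderation factor values, in [0, 4]."""
    if profile.age_class is None:
        raise ValidationError("age_class (or age) is required for ponderation")
    if profile.fitness_class is None:
        raise ValidationError("fitness_class is required for ponderation")
    if profile.bmi is None:
        raise ValidationError("bmi (or body_mass and height) is required")
    return (
        SEX_POINTS[profile.sex]
        + AGE_POINTS[profile.age_class]
        + FITNESS_POINTS[profile.fitness_class]
        + bmi_points(profile.bmi)
        + smoking_points(profile.smoker)
    )


def step_height(profile: ParticipantProfile) -> int:
    """Individualized step height in whole cm, 4 x ponderation + 15, in [15, 40]."""
    raw = 4.0 * ponderation_sum(profile) + 15.0
    return int(round(min(max(raw, 15.0), 40.0)))


def age_predicted_hrmax(age: float) -> float:
    """Age-predicted maximal heart rate, 208 − 0.7·age (bpm)."""
    if age <= 0:
        raise ValidationError(f"age must be positive, got {age!r}")
    return 208.0 - 0.7 * age


def target_hr(age: float, fraction: float = 0.8) -> float:
    """Termination target: ``fraction`` of age-predicted HRmax (default 80%)."""
    if not 0 < fraction <= 1:
        raise ValidationError(f"fraction must be in (0, 1], got {fraction!r}")
    return fraction * age_predicted_hrmax(age)


def cadence_schedule(
    max_duration: float = 10.0,
    stage_duration: float = 60.0,
    *,
    start_cadence: float = 15.0,
    increment: float = 2.5,
    max_cadence: float = 37.5,
) -> CadenceSchedule:
    """Stage plan from 15 cycles/min rising by 2.5/min, capped at 37.5.

    ``max_duration`` is in minutes, ``stage_duration`` in seconds. The default
    yields ten one-minute stages.
    """
    if max_duration <= 0 or stage_duration <= 0:
        raise ValidationError("max_duration and stage_duration must be positive")
    by_cadence = int(math.floor((max_cadence - start_cadence) / increment)) + 1
    by_time = int(math.floor(max_duration * 60.0 / stage_duration))
    n = min(by_cadence, by_time)
    if n < 1:
        raise ValidationError("schedule admits no stages under these settings")
    stages = tuple(
        (k + 1, start_cadence + k * increment, k * stage_duration) for k in range(n)
    )
    return CadenceSchedule(
        stage_duration=stage_duration, stages=stages, max_duration=max_duration
    )


def termination_check(
    times: Sequence[float],
    hrs: Sequence[float],
    target: float,
    flags: Sequence[tuple[float, str]] = (),
) -> TerminationDecision:
    """Scan a time-ordered HR stream for the stop condition.

    Returns ``target_reached`` at the first sample with hr >= target. Operator
    flags (``discomfort``/``cadence_failure``) stop the test at their own
    timestamp and take precedence on ties. If nothing fires, the schedule is
    ``completed``.
    """
    if len(times) == 0:
        raise ValidationError("empty heart-rate stream")
    if len(times) != len(hrs):
        raise ValidationError("times and hrs must have equal length")
    for flag_time, reason in flags:
        if reason not in ("discomfort", "cadence_failure"):
            raise ValidationError(f"unknown operator flag {reason!r}")
    events: list[tuple[float, int, str, Optional[float]]] = []
    for flag_time, reason in flags:
        events.append((flag_time, 0, reason, None))  # priority 0: flags win ties
    for t, hr in zip(times, hrs):
        if hr >= target:
            events.append((t, 1, "target_reached", hr))
            break
    if not events:
        return TerminationDecision("completed")
    t, _, reason, hr = min(events)
    return TerminationDecision(reason, time=t, hr=hr)


def build_step_config(
    profile: ParticipantProfile,
    *,
    fraction: float = 0.8,
    max_duration: float = 10.0,
    stage_duration: float = 60.0,
) -> StepConfig:
    """Convenience bundle: height, schedule, and HR target for one participant."""
    if profile.age is None:
        raise ValidationError("profile.age is required to compute the HR target")
    return StepConfig(
        step_height=step_height(profile),
        schedule=cadence_schedule(max_duration, stage_duration),
        target_hr=target_hr(profile.age, fraction),
    )
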