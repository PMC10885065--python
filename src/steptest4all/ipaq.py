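"""IPAQ short-form scoring.

Converts the six short-form items (days/week and minutes/day of walking,
moderate activity, and vigorous activity) into weekly MET-minutes and the
ordinal three-level physical-activity classification (1 = Low, 2 = Moderate,
3 = High) that serves as the ``PA_level`` covariate of the VO2max prediction
equation.

MET weights follow the official short-form scoring protocol: walking 3.3,
moderate 4.0, vigorous 8.0 MET. They are exposed as configuration because
different scoring revisions have circulated.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ValidationError

__all__ = [
    "METWeights",
    "IPAQResponse",
    "PALevel",
    "weekly_met_minutes",
    "classify_pa_level",
    "DEFAULT_MET_WEIGHTS",
]

PA_LABELS = {1: "Low", 2: "Moderate", 3: "High"}


@dataclass(frozen=True)
class METWeights:
    """Category MET intensities used for weekly volume scoring."""

    walking: float = 3.3
    moderate: float = 4.0
    vigorous: float = 8.0


DEFAULT_MET_WEIGHTS = METWeights()


@dataclass(frozen=True)
class IPAQResponse:
    """One respondent's short-form answers.

    ``*_days`` are days per week in [0, 7]; ``*_min`` are minutes per day
    of that activity on such a day (>= 0).
    """

    vigorous_days: int = 0
    vigorous_min: float = 0.0
    moderate_days: int = 0
    moderate_min: float = 0.0
    walking_days: int = 0
    walking_min: float = 0.0

    def __post_init__(self):
        for name in ("vigorous_days", "moderate_days", "walking_days"):
            d = getattr(self, name)
            if not 0 <= d <= 7:
                raise ValidationError(f"{name}={d!r} outside [0, 7]")
        for name in ("vigorous_min", "moderate_min", "walking_min"):
            m = getattr(self, name)
            if m < 0:
                raise ValidationError(f"{name}={m!r} must be >= 0")

    @property
    def total_days(self) -> int:
        """Day counts summed across the three categories (may exceed 7)."""
        return self.vigorous_days + self.moderate_days + self.walking_days


@dataclass(frozen=True)
class PALevel:
    """Ordinal physical-activity level with its canonical label."""

    level: int

    def __post_init__(self):
        if self.level not in PA_LABELS:
            raise ValidationError(f"PA level must be 1, 2, or 3, got {self.level!r}")

    @property
    def label(self) -> str:
        return PA_LABELS[self.level]


def _cleaned(response: IPAQResponse, clean: bool, cap_min: float) -> IPAQResponse:
    if not clean:
        return response
    return IPAQResponse(
        vigorous_days=response.vigorous_days,
        vigorous_min=min(response.vigorous_min, cap_min),
        moderate_days=response.moderate_days,
        moderate_min=min(response.moderate_min, cap_min),
        walking_days=response.walking_days,
        walking_min=min(response.walking_min, cap_min),
    )


def weekly_met_minutes(
    response: IPAQResponse,
    weights: METWeights = DEFAULT_MET_WEIGHTS,
    *,
    clean: bool = False,
    cap_min_per_day: float = 180.0,
) -> dict[str, float]:
    """Weekly MET-minutes per category and in total.

    Each category contributes ``days x minutes/day x MET weight``. With
    ``clean=True`` the official truncation rule caps minutes per day at
    ``cap_min_per_day`` (180 by default) before scoring; no cleaning is
    applied by default.
    """
    r = _cleaned(response, clean, cap_min_per_day)
    out = {
        "walking": r.walking_days * r.walking_min * weights.walking,
        "moderate": r.moderate_days * r.moderate_min * weights.moderate,
        "vigorous": r.vigorous_days * r.vigorous_min * weights.vigorous,
    }
    out["total"] = out["walking"] + out["moderate"] + out["vigorous"]
    return out


def classify_pa_level(
    response: IPAQResponse,
    weights: METWeights = DEFAULT_MET_WEIGHTS,
    *,
    clean: bool = False,
    cap_min_per_day: float = 180.0,
    require_all_categories_for_high: bool = False,
) -> PALevel:
    """Three-level classification from a short-form response.

    High (3) requires either (a) vigorous activity on >= 3 days with a weekly
    volume of >= 1500 MET-min, or (b) activity on >= 7 day-counts summed
    across categories with >= 3000 MET-min/week. Moderate (2) requires either
    (a) >= 3 vigorous days of >= 20 min, (b) >= 5 days of moderate activity
    and/or walking of >= 30 min, or (c) >= 5 summed day-counts with
    >= 600 MET-min/week. Everything else is Low (1).

    The 7-day High rule counts *any combination* of categories by default;
    ``require_all_categories_for_high=True`` additionally requires a nonzero
    day count in each of walking, moderate, and vigorous activity.
    """
    r = _cleaned(response, clean, cap_min_per_day)
    total = weekly_met_minutes(r, weights)["total"]

    seven_day_combination = r.total_days >= 7
    if require_all_categories_for_high:
        seven_day_combination = seven_day_combination and (
            r.walking_days > 0 and r.moderate_days > 0 and r.vigorous_days > 0
        )
    if (r.vigorous_days >= 3 and total >= 1500) or (
        seven_day_combination and total >= 3000
    ):
        return PALevel(3)

    mod_walk_days = (r.moderate_days if r.moderate_min >= 30 else 0) + (
        r.walking_days if r.walking_min >= 30 else 0
    )
    if (
        (r.vigorous_days >= 3 and r.vigorous_min >= 20)
        or mod_walk_days >= 5
        or (r.total_days >= 5 and total >= 600)
    ):
        return PALevel(2)

    return PALevel(1)
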