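"""Session reduction and submaximal VO2max estimation.

A test session is a phase-labelled time series of heart rate and oxygen
uptake covering rest, the incremental stages, and recovery. The reduction
follows fixed averaging windows:

* resting values: arithmetic mean over the final 60 s of the rest phase;
* stage endpoints: mean over the final 5 s of each stage;
* recovery: HRR60 = HR at test end minus the mean HR over the last 5 s of
  the first minute after exercise stops.

VO2max is estimated by fitting the individual ordinary-least-squares line
VO2 = a + b·HR through the rest point and >= 3 stage endpoints and
evaluating it at the age-predicted HRmax. Averaging windows are closed
intervals; samples exactly on a window edge are included. In-window samples
are averaged without time weighting, with a warning when fewer than three
samples fall in a 5-s window.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    DegenerateFitError,
    InsufficientDataError,
    ValidationError,
)
from .protocol import age_predicted_hrmax

__all__ = [
    "PhysioTimeSeries",
    "StagePoint",
    "SubmaximalFit",
    "RecoverySummary",
    "SessionReport",
    "resting_values",
    "stage_endpoints",
    "recovery_summary",
    "fit_hr_vo2",
    "estimate_vo2max",
    "analyze_session",
]

REST = "rest"
RECOVERY = "recovery"
_STAGE_RE = re.compile(r"^stage_(\d+)$")


def _phase_rank(phase: str) -> float:
    if phase == REST:
        return 0.0
    m = _STAGE_RE.match(phase)
    if m:
        return float(m.group(1))
    if phase == RECOVERY:
        return float("inf")
    raise ValidationError(f"unknown phase label {phase!r}")


@dataclass
class PhysioTimeSeries:
    """Validated, phase-ordered session samples.

    Wraps a DataFrame with columns ``time_s``, ``hr_bpm``, ``vo2_mlkgmin``,
    ``phase``. VO2 may be missing (NaN) during recovery only.
    """

    df: pd.DataFrame

    def __post_init__(self):
        required = {"time_s", "hr_bpm", "vo2_mlkgmin", "phase"}
        missing = required - set(self.df.columns)
        if missing:
            raise ValidationError(f"missing columns: {sorted(missing)}")
        df = self.df.reset_index(drop=True)
        t = df["time_s"].to_numpy(dtype=float)
        if len(t) == 0:
            raise ValidationError("empty time series")
        if not np.all(np.diff(t) > 0):
            bad = int(np.flatnonzero(np.diff(t) <= 0)[0]) + 1
            raise ValidationError(f"times not strictly increasing at row {bad}")
        hr = df["hr_bpm"].to_numpy(dtype=float)
        if np.any(~np.isfinite(hr)) or np.any(hr <= 0):
            raise ValidationError("hr_bpm must be finite and positive")
        ranks = df["phase"].map(_phase_rank).to_numpy(dtype=float)
        out_of_order = ranks[1:] < ranks[:-1]  # avoids inf - inf
        if np.any(out_of_order):
            bad = int(np.flatnonzero(out_of_order)[0]) + 1
            raise ValidationError(
                f"phases out of order (rest -> stages ascending -> recovery) at row {bad}"
            )
        vo2 = df["vo2_mlkgmin"].to_numpy(dtype=float)
        non_recovery = df["phase"] != RECOVERY
        if np.any(~np.isfinite(vo2[non_recovery.to_numpy()])):
            raise ValidationError("vo2_mlkgmin may be missing during recovery only")
        self.df = df

    @property
    def phases(self) -> list[str]:
        seen: list[str] = []
        for p in self.df["phase"]:
            if not seen or seen[-1] != p:
                seen.append(p)
        return seen

    def phase_rows(self, phase: str) -> pd.DataFrame:
        return self.df[self.df["phase"] == phase]

    def stage_indices(self) -> list[int]:
        out = []
        for p in self.phases:
            m = _STAGE_RE.match(p)
            if m:
                out.append(int(m.group(1)))
        return out


@dataclass(frozen=True)
class StagePoint:
    stage_index: int
    cadence: float  # cycles/min
    hr: float  # bpm
    vo2: float  # mL/kg/min


@dataclass(frozen=True)
class SubmaximalFit:
    """Individual HR->VO2 line used for extrapolation to HRmax."""

    slope: float  # mL/kg/min per bpm
    intercept: float  # mL/kg/min
    r2: float
    n_points: int


@dataclass(frozen=True)
class RecoverySummary:
    hr_end: float  # bpm at test termination
    hr_60: float  # bpm, last-5-s mean of the first recovery minute
    hrr60: float  # hr_end - hr_60
    flagged: bool = False  # True when hrr60 < 0 (physiologically implausible)


@dataclass(frozen=True)
class SessionReport:
    """Everything the session reduction produces for one participant."""

    hr_rest: float
    vo2_rest: float
    stage_points: tuple[StagePoint, ...]
    fit: SubmaximalFit
    hrmax: float
    vo2max: float
    recovery: RecoverySummary
    extrapolated: bool  # False if HRmax was inside the observed HR range


def _window_mean(rows: pd.DataFrame, start: float, cols: tuple[str, ...], min_samples: int = 1,
                 context: str = "") -> tuple[float, ...]:
    win = rows[rows["time_s"] >= start]
    if len(win) == 0:
        raise InsufficientDataError(f"no samples in averaging window {context}")
    if len(win) < min_samples:
        warnings.warn(
            f"only {len(win)} sample(s) in 5-s window {context}", stacklevel=3
        )
    return tuple(float(win[c].mean()) for c in cols)


def resting_values(ts: PhysioTimeSeries, window_s: float = 60.0) -> tuple[float, float]:
    """Mean HR and VO2 over the final ``window_s`` (60 s) of the rest phase."""
    rest = ts.phase_rows(REST)
    if len(rest) == 0:
        raise InsufficientDataError("no rest phase in series")
    span = rest["time_s"].iloc[-1] - rest["time_s"].iloc[0]
    if span < window_s:
        raise InsufficientDataError(
            f"rest phase spans {span:.1f} s < required {window_s:.0f} s"
        )
    end = rest["time_s"].iloc[-1]
    hr, vo2 = _window_mean(rest, end - window_s, ("hr_bpm", "vo2_mlkgmin"),
                           context="of rest phase")
    return hr, vo2


def stage_endpoints(
    ts: PhysioTimeSeries,
    window_s: float = 5.0,
    *,
    start_cadence: float = 15.0,
    cadence_increment: float = 2.5,
) -> list[StagePoint]:
    """Last-5-s mean HR/VO2 of each stage present in the series."""
    indices = ts.stage_indices()
    if not indices:
        raise InsufficientDataError("no completed stage in series")
    points = []
    for k in indices:
        rows = ts.phase_rows(f"stage_{k}")
        if len(rows) == 0:
            raise InsufficientDataError(f"stage {k} has no samples")
        end = rows["time_s"].iloc[-1]
        hr, vo2 = _window_mean(
            rows, end - window_s, ("hr_bpm", "vo2_mlkgmin"),
            min_samples=3, context=f"of stage {k}",
        )
        cadence = start_cadence + (k - 1) * cadence_increment
        points.append(StagePoint(stage_index=k, cadence=cadence, hr=hr, vo2=vo2))
    return points


def recovery_summary(
    ts: PhysioTimeSeries,
    *,
    hr_end_mode: str = "stage_avg",
    window_s: float = 5.0,
) -> RecoverySummary:
    """HRR60 from the recovery phase.

    ``hr_end`` is the last-5-s average of the final stage (``stage_avg``,
    default) or the instantaneous HR of the last pre-recovery sample
    (``instantaneous``). The recovery clock starts at the last exercise
    sample; ``hr_60`` averages HR over the closed window [55 s, 60 s] of
    that clock.
    """
    rec = ts.phase_rows(RECOVERY)
    if len(rec) == 0:
        raise InsufficientDataError("no recovery phase in series")
    pre = ts.df[ts.df["phase"] != RECOVERY]
    if len(pre) == 0:
        raise InsufficientDataError("recovery phase with no preceding exercise")
    t0 = pre["time_s"].iloc[-1]
    if rec["time_s"].iloc[-1] - t0 < 60.0:
        raise InsufficientDataError("recovery phase spans less than 60 s")

    if hr_end_mode == "instantaneous":
        hr_end = float(pre["hr_bpm"].iloc[-1])
    elif hr_end_mode == "stage_avg":
        indices = ts.stage_indices()
        if not indices:
            raise InsufficientDataError("no stage before recovery")
        rows = ts.phase_rows(f"stage_{indices[-1]}")
        end = rows["time_s"].iloc[-1]
        (hr_end,) = _window_mean(
            rows, end - window_s, ("hr_bpm",), min_samples=3,
            context=f"of final stage {indices[-1]}",
        )
    else:
        raise ValidationError(f"unknown hr_end_mode {hr_end_mode!r}")

    win = rec[(rec["time_s"] >= t0 + 60.0 - window_s) & (rec["time_s"] <= t0 + 60.0)]
    if len(win) == 0:
        raise InsufficientDataError("no samples in [55 s, 60 s] of recovery")
    if len(win) < 3:
        warnings.warn(f"only {len(win)} sample(s) in recovery 5-s window", stacklevel=2)
    hr_60 = float(win["hr_bpm"].mean())
    hrr60 = hr_end - hr_60
    return RecoverySummary(hr_end=hr_end, hr_60=hr_60, hrr60=hrr60, flagged=hrr60 < 0)


def fit_hr_vo2(
    rest_point: tuple[float, float],
    stage_points: list[StagePoint],
    *,
    include_rest: bool = True,
) -> SubmaximalFit:
    """OLS line VO2 = intercept + slope·HR through the rest point and stages."""
    if len(stage_points) < 3:
        raise InsufficientDataError(
            f"need >= 3 stage points for the HR-VO2 fit, got {len(stage_points)}"
        )
    hr = [p.hr for p in stage_points]
    vo2 = [p.vo2 for p in stage_points]
    if include_rest:
        hr = [rest_point[0]] + hr
        vo2 = [rest_point[1]] + vo2
    hr_arr = np.asarray(hr, dtype=float)
    vo2_arr = np.asarray(vo2, dtype=float)
    if np.ptp(hr_arr) == 0:
        raise DegenerateFitError("zero HR variance; regression line undefined")
    res = stats.linregress(hr_arr, vo2_arr)
    return SubmaximalFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=float(res.rvalue**2),
        n_points=len(hr_arr),
    )


def estimate_vo2max(
    fit: SubmaximalFit,
    hrmax: float,
    *,
    max_observed_hr: Optional[float] = None,
) -> float:
    """Evaluate the individual HR-VO2 line at HRmax (mL/kg/min).

    When ``max_observed_hr`` is given and HRmax does not exceed it, the value
    is an interpolation rather than the intended extrapolation; a warning is
    issued but the value is still returned.
    """
    if not np.isfinite(fit.slope) or not np.isfinite(fit.intercept):
        raise DegenerateFitError("fit coefficients are not finite")
    if max_observed_hr is not None and hrmax <= max_observed_hr:
        warnings.warn(
            f"HRmax {hrmax:.1f} <= max observed HR {max_observed_hr:.1f}; "
            "value is an interpolation", stacklevel=2,
        )
    return fit.intercept + fit.slope * hrmax


def analyze_session(
    ts: PhysioTimeSeries,
    age: Optional[float] = None,
    *,
    hrmax: Optional[float] = None,
    hr_end_mode: str = "stage_avg",
    include_rest: bool = True,
) -> SessionReport:
    """Full reduction of one session: rest, stages, fit, VO2max, HRR60."""
    if hrmax is None:
        if age is None:
            raise ValidationError("either age or hrmax is required")
        hrmax = age_predicted_hrmax(age)
    hr_rest, vo2_rest = resting_values(ts)
    points = stage_endpoints(ts)
    fit = fit_hr_vo2((hr_rest, vo2_rest), points, include_rest=include_rest)
    max_obs = max(p.hr for p in points)
    extrapolated = hrmax > max_obs
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        vo2max = estimate_vo2max(fit, hrmax, max_observed_hr=max_obs)
    rec = recovery_summary(ts, hr_end_mode=hr_end_mode)
    return SessionReport(
        hr_rest=hr_rest,
        vo2_rest=vo2_rest,
        stage_points=tuple(points),
        fit=fit,
        hrmax=float(hrmax),
        vo2max=float(vo2max),
        recovery=rec,
        extrapolated=extrapolated,
    )
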