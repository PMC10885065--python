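"""Synthetic cohorts and test sessions with known ground truth.

The generator emulates the published study conditions: a young-adult cohort
(27 women, 42 men by default) with per-sex anthropometrics, resting values,
and physical-activity-level frequencies matching the printed cohort tables;
heart-rate recovery drawn truncated-normal (37 ± 11 bpm on [19, 63]); and
true VO2max generated from the prediction equation's mean structure plus
Gaussian noise with SD 4.78 (the equation's standard error of estimate).

Sessions are built so that the estimation pipeline is exact in the
noise-free limit: within-stage HR steps instantaneously to a steady state
that rises linearly with cadence and meets the 80%-of-HRmax target exactly
at the crossing stage; per-sample VO2 lies on the line through
(HR_rest, VO2_rest) and (HRmax, true VO2max); recovery decays
mono-exponentially toward resting HR with the time constant back-solved so
the realized HRR60 equals the drawn ground truth.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .agreement import AgreementReport, PairedMeasurements, validate_agreement
from .errors import ConfigurationError, ValidationError
from .estimation import PhysioTimeSeries, analyze_session
from .ipaq import PALevel
from .prediction import (
    DEFAULT_CANDIDATES,
    PUBLISHED_MODEL,
    PredictionModel,
    backward_stepwise,
)
from .protocol import (
    ParticipantProfile,
    Sex,
    age_class_from_age,
    age_predicted_hrmax,
    cadence_schedule,
    fitness_class_from_pa_level,
)

__all__ = [
    "SexParams",
    "SimulationConfig",
    "SyntheticParticipant",
    "sample_cohort",
    "simulate_session",
    "cohort_to_frame",
    "EndToEndResult",
    "end_to_end_validation_run",
]


@dataclass(frozen=True)
class SexParams:
    """Per-sex anthropometric and resting-value targets (mean, SD)."""

    mass_mean: float
    mass_sd: float
    height_mean: float
    height_sd: float
    hr_rest_mean: float
    hr_rest_sd: float
    vo2_rest_mean: float
    vo2_rest_sd: float
    pa_probs: tuple[float, float, float]  # P(level 1), P(2), P(3)

    def __post_init__(self):
        for name in ("mass_sd", "height_sd", "hr_rest_sd", "vo2_rest_sd"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if abs(sum(self.pa_probs) - 1.0) > 1e-9 or any(p < 0 for p in self.pa_probs):
            raise ValidationError("pa_probs must be non-negative and sum to 1")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    Defaults reproduce the published cohort: sample size 69 with 42/69 men;
    age 21.7 ± 3.5 years (truncated to [18, 35]); per-sex body mass, height,
    resting HR and resting VO2 from the cohort table; physical-activity-level
    probabilities from the per-sex level counts (women 15/8/4 of 27, men
    3/24/15 of 42); HRR60 truncated-normal 37 ± 11 bpm on [19, 63]; outcome
    noise SD 4.78 (the published SEE). Session noise SDs and the 1 Hz
    sampling rate are generator choices, small enough that individual
    HR-VO2 fits stay in the reported R² band.
    """

    n: int = 69
    sex_ratio: float = 42.0 / 69.0  # proportion of men
    age_mean: float = 21.7
    age_sd: float = 3.5
    age_bounds: tuple[float, float] = (18.0, 35.0)
    women: SexParams = field(
        default_factory=lambda: SexParams(
            mass_mean=63.5, mass_sd=14.8,
            height_mean=1.64, height_sd=0.06,
            hr_rest_mean=81.0, hr_rest_sd=11.0,
            vo2_rest_mean=3.4, vo2_rest_sd=0.65,
            pa_probs=(15 / 27, 8 / 27, 4 / 27),
        )
    )
    men: SexParams = field(
        default_factory=lambda: SexParams(
            mass_mean=72.0, mass_sd=7.3,
            height_mean=1.77, height_sd=0.07,
            hr_rest_mean=68.0, hr_rest_sd=11.0,
            vo2_rest_mean=3.7, vo2_rest_sd=0.65,
            pa_probs=(3 / 42, 24 / 42, 15 / 42),
        )
    )
    hrr60_mean: float = 37.0
    hrr60_sd: float = 11.0
    hrr60_bounds: tuple[float, float] = (19.0, 63.0)
    smoker_prob: float = 0.2
    outcome_noise_sd: float = 4.78  # SD of true VO2max around the equation mean
    hr_noise_sd: float = 2.0  # per-sample HR noise, bpm
    vo2_noise_sd: float = 1.0  # per-sample VO2 noise, mL/kg/min
    sample_rate_hz: float = 1.0
    rest_duration_s: float = 120.0
    recovery_duration_s: float = 120.0
    target_fraction: float = 0.8
    stage_duration_s: float = 60.0
    seed: Optional[int] = None

    def __post_init__(self):
        if self.n < 0:
            raise ValidationError("n must be >= 0")
        if not 0 <= self.sex_ratio <= 1:
            raise ValidationError("sex_ratio must be in [0, 1]")
        for name in ("age_sd", "hrr60_sd", "outcome_noise_sd", "hr_noise_sd",
                     "vo2_noise_sd"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if not 0 <= self.smoker_prob <= 1:
            raise ValidationError("smoker_prob must be in [0, 1]")

    def sex_params(self, sex: Sex) -> SexParams:
        return self.men if sex is Sex.MAN else self.women


@dataclass(frozen=True)
class SyntheticParticipant:
    """Ground-truth container for one simulated participant."""

    participant_id: int
    profile: ParticipantProfile
    pa_level: PALevel
    true_vo2max: float
    hr_rest: float
    vo2_rest: float
    hrmax: float
    true_hrr60: float


def _truncated_normal(rng, mean, sd, lo, hi, size):
    """Rejection-sampled truncated normal (vectorized redraw)."""
    if sd == 0:
        return np.full(size, float(np.clip(mean, lo, hi)))
    x = rng.normal(mean, sd, size)
    bad = (x < lo) | (x > hi)
    while bad.any():
        x[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = (x < lo) | (x > hi)
    return x


def sample_cohort(
    config: SimulationConfig, rng: Optional[np.random.Generator] = None
) -> list[SyntheticParticipant]:
    """Draw a reproducible cohort under the configured study conditions.

    Per-participant invariants are enforced by redraw: resting HR leaves at
    least 25 bpm of headroom below the termination target, HRR60 stays below
    90% of the exercise HR reserve above rest (so a recovery time constant
    exists), and true VO2max exceeds resting VO2.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n
    if n == 0:
        return []
    is_man = rng.random(n) < config.sex_ratio
    age = _truncated_normal(rng, config.age_mean, config.age_sd,
                            *config.age_bounds, n)
    hrmax = 208.0 - 0.7 * age
    target = config.target_fraction * hrmax

    mass = np.empty(n)
    height = np.empty(n)
    hr_rest = np.empty(n)
    vo2_rest = np.empty(n)
    pa_level = np.empty(n, dtype=int)
    for sex, mask in ((Sex.MAN, is_man), (Sex.WOMAN, ~is_man)):
        m = int(mask.sum())
        if m == 0:
            continue
        p = config.sex_params(sex)
        mass[mask] = _truncated_normal(rng, p.mass_mean, p.mass_sd, 40.0, 150.0, m)
        height[mask] = _truncated_normal(rng, p.height_mean, p.height_sd, 1.40, 2.10, m)
        # resting HR must leave headroom below the per-subject target
        hr = _truncated_normal(rng, p.hr_rest_mean, p.hr_rest_sd, 40.0, 120.0, m)
        cap = target[mask] - 25.0
        bad = hr > cap
        while bad.any():
            hr[bad] = _truncated_normal(rng, p.hr_rest_mean, p.hr_rest_sd, 40.0,
                                        120.0, int(bad.sum()))
            bad = hr > cap
        hr_rest[mask] = hr
        vo2_rest[mask] = _truncated_normal(rng, p.vo2_rest_mean, p.vo2_rest_sd,
                                           1.5, 6.5, m)
        pa_level[mask] = rng.choice([1, 2, 3], size=m, p=p.pa_probs)

    # HRR60: truncated normal, additionally bounded by the subject's reserve
    reserve = target - hr_rest
    lo, hi = config.hrr60_bounds
    hrr60 = _truncated_normal(rng, config.hrr60_mean, config.hrr60_sd, lo, hi, n)
    bad = hrr60 > 0.9 * reserve
    while bad.any():
        hrr60[bad] = _truncated_normal(rng, config.hrr60_mean, config.hrr60_sd,
                                       lo, hi, int(bad.sum()))
        bad = hrr60 > 0.9 * reserve

    sex_code = is_man.astype(float)
    mean_vo2max = PUBLISHED_MODEL.coefficients["intercept"] \
        + PUBLISHED_MODEL.coefficients["hrr60"] * hrr60 \
        + PUBLISHED_MODEL.coefficients["sex"] * sex_code \
        + PUBLISHED_MODEL.coefficients["pa_level"] * pa_level
    vo2max = mean_vo2max + rng.normal(0.0, config.outcome_noise_sd, n)
    bad = vo2max <= vo2_rest + 3.0
    if config.outcome_noise_sd == 0 and bad.any():
        raise ConfigurationError(
            "noise-free outcome below resting VO2 + 3; check config targets"
        )
    while bad.any():
        vo2max[bad] = mean_vo2max[bad] + rng.normal(
            0.0, config.outcome_noise_sd, int(bad.sum())
        )
        bad = vo2max <= vo2_rest + 3.0

    smoker = rng.random(n) < config.smoker_prob

    cohort = []
    for i in range(n):
        sex = Sex.MAN if is_man[i] else Sex.WOMAN
        profile = ParticipantProfile(
            sex=sex,
            age=float(age[i]),
            age_class=age_class_from_age(float(age[i])),
            fitness_class=fitness_class_from_pa_level(int(pa_level[i])),
            body_mass=float(mass[i]),
            height=float(height[i]),
            smoker=bool(smoker[i]),
        )
        cohort.append(
            SyntheticParticipant(
                participant_id=i + 1,
                profile=profile,
                pa_level=PALevel(int(pa_level[i])),
                true_vo2max=float(vo2max[i]),
                hr_rest=float(hr_rest[i]),
                vo2_rest=float(vo2_rest[i]),
                hrmax=float(hrmax[i]),
                true_hrr60=float(hrr60[i]),
            )
        )
    return cohort


def _solve_recovery_tau(amplitude: float, hrr60: float, offsets: np.ndarray) -> float:
    """Time constant giving the drawn HRR60 on the discrete sampling grid.

    Realized HRR60 = A·(1 − mean exp(−t/tau)) over the samples in the
    [55 s, 60 s] window, solved for tau by bracketing.
    """
    if not 0 < hrr60 < amplitude:
        raise ConfigurationError(
            f"HRR60 {hrr60:.1f} not attainable with recovery amplitude "
            f"{amplitude:.1f}"
        )

    def f(tau):
        return amplitude * (1.0 - np.exp(-offsets / tau).mean()) - hrr60

    return brentq(f, 1e-3, 1e5)


def simulate_session(
    participant: SyntheticParticipant,
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
) -> PhysioTimeSeries:
    """One phase-labelled HR/VO2 time series for a participant.

    The crossing stage index depends on activity level and sex (fitter
    participants last longer) and always lies within the 10-stage cap; the
    steady-state HR of that stage equals the termination target, so a
    noise-free session terminates at exactly 80% of HRmax.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    dt = 1.0 / config.sample_rate_hz
    target = config.target_fraction * participant.hrmax
    schedule = cadence_schedule(stage_duration=config.stage_duration_s)

    k_cross = 4 + participant.pa_level.level + participant.profile.sex.code
    if k_cross > schedule.n_stages:
        raise ConfigurationError(
            f"crossing stage {k_cross} exceeds the {schedule.n_stages}-stage cap"
        )
    hr_rest, vo2_rest = participant.hr_rest, participant.vo2_rest
    # VO2 lies on the line through (hr_rest, vo2_rest) and (hrmax, true max)
    slope = (participant.true_vo2max - vo2_rest) / (participant.hrmax - hr_rest)

    times, hrs, vo2s, phases = [], [], [], []

    def emit(t, hr_clean, vo2_clean, phase, hr_noise, vo2_noise):
        times.append(t)
        hrs.append(hr_clean + (rng.normal(0.0, hr_noise) if hr_noise else 0.0))
        if vo2_clean is None:
            vo2s.append(np.nan)
        else:
            vo2s.append(vo2_clean + (rng.normal(0.0, vo2_noise) if vo2_noise else 0.0))
        phases.append(phase)

    t = 0.0
    n_rest = int(round(config.rest_duration_s / dt))
    for _ in range(n_rest):
        emit(t, hr_rest, vo2_rest, "rest", config.hr_noise_sd, config.vo2_noise_sd)
        t += dt

    terminated = False
    samples_per_stage = int(round(config.stage_duration_s / dt))
    for k in range(1, k_cross + 1):
        # exact target at the crossing stage (avoids an ulp of float error)
        hr_k = target if k == k_cross else hr_rest + (target - hr_rest) * k / k_cross
        for _ in range(samples_per_stage):
            vo2_k = vo2_rest + slope * (hr_k - hr_rest)
            emit(t, hr_k, vo2_k, f"stage_{k}",
                 config.hr_noise_sd, config.vo2_noise_sd)
            t += dt
            if hrs[-1] >= target:
                terminated = True
                break
        if terminated:
            break
    if not terminated:
        raise ConfigurationError("session never reached the termination target")

    t_end = times[-1]
    amplitude = hrs[-1] - hr_rest  # decay starts from the terminating HR
    offsets = np.arange(dt, config.recovery_duration_s + dt / 2, dt)
    window = offsets[(offsets >= 60.0 - 5.0) & (offsets <= 60.0)]
    tau = _solve_recovery_tau(amplitude, participant.true_hrr60, window)
    for off in offsets:
        hr_t = hr_rest + amplitude * np.exp(-off / tau)
        emit(t_end + off, hr_t, None, "recovery", config.hr_noise_sd, 0.0)

    df = pd.DataFrame(
        {"time_s": times, "hr_bpm": hrs, "vo2_mlkgmin": vo2s, "phase": phases}
    )
    return PhysioTimeSeries(df)


def cohort_to_frame(
    cohort: Sequence[SyntheticParticipant],
    vo2max: Optional[Sequence[float]] = None,
    hrr60: Optional[Sequence[float]] = None,
) -> pd.DataFrame:
    """Tabulate a cohort for regression; defaults to ground-truth outcomes."""
    rows = []
    for i, p in enumerate(cohort):
        rows.append(
            {
                "participant_id": p.participant_id,
                "sex": p.profile.sex.code,
                "age": p.profile.age,
                "body_mass": p.profile.body_mass,
                "height": p.profile.height,
                "bmi": p.profile.bmi,
                "pa_level": p.pa_level.level,
                "smoker": int(p.profile.smoker),
                "hrr60": hrr60[i] if hrr60 is not None else p.true_hrr60,
                "vo2max": vo2max[i] if vo2max is not None else p.true_vo2max,
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class EndToEndResult:
    model: PredictionModel
    report: AgreementReport
    equation_frame: pd.DataFrame
    validation_frame: pd.DataFrame


def end_to_end_validation_run(
    config: SimulationConfig,
    *,
    use_sessions: bool = False,
    equation_fraction: float = 30.0 / 69.0,
    alpha: float = 0.05,
    candidates: Sequence[str] = DEFAULT_CANDIDATES,
    rng: Optional[np.random.Generator] = None,
) -> EndToEndResult:
    """Two-group design: refit the equation on one group, validate on the other.

    The cohort is randomly split (default 30/69 of participants into the
    equation group). With ``use_sessions=True`` the measured VO2max and HRR60
    come from simulated sessions run through the estimation pipeline;
    otherwise the generator's ground truth is used directly.
    """
    if config.n < 20:
        raise ValidationError("end-to-end run needs a cohort of at least 20")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    cohort = sample_cohort(config, rng)

    if use_sessions:
        vo2max, hrr60 = [], []
        for p in cohort:
            report = analyze_session(simulate_session(p, config, rng),
                                     hrmax=p.hrmax)
            vo2max.append(report.vo2max)
            hrr60.append(report.recovery.hrr60)
        frame = cohort_to_frame(cohort, vo2max=vo2max, hrr60=hrr60)
    else:
        frame = cohort_to_frame(cohort)

    n_eq = max(len(candidates) + 2, int(round(equation_fraction * config.n)))
    order = rng.permutation(config.n)
    eq_frame = frame.iloc[order[:n_eq]].reset_index(drop=True)
    val_frame = frame.iloc[order[n_eq:]].reset_index(drop=True)

    model = backward_stepwise(eq_frame, outcome="vo2max", candidates=candidates,
                              alpha=alpha)
    predicted = [
        model.predict({k: row[k] for k in model.retained})
        for _, row in val_frame.iterrows()
    ]
    pairs = PairedMeasurements(
        measured=tuple(val_frame["vo2max"]), predicted=tuple(predicted)
    )
    report = validate_agreement(pairs)
    return EndToEndResult(
        model=model, report=report,
        equation_frame=eq_frame, validation_frame=val_frame,
    )
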