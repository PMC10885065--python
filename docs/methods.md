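# Methods

This note documents the models, numerical conventions, and design choices
behind `steptest4all`, and states what the synthetic-data checks do and do
not demonstrate.

## Protocol individualization

The step height is a deterministic function of five categorical ponderation
factors: sex (woman 0.5, man 1), age class (senior 0, adult 0.5, young 1),
physical fitness (insufficiently active 0, moderately active 0.5,
vigorously active 1), BMI band (< 25 → 0.5, 25–< 30 → 0, ≥ 30 → −0.5), and
smoking (smoker 0, nonsmoker 0.5). Height = 4 × sum + 15 cm, rounded to the
nearest whole centimetre and clamped to [15, 40]. Under these factor values
the attainable range is exactly [15, 31] cm (verified by enumerating all
108 categorical profiles), so the clamp's upper bound is never active; it
is retained because the protocol's stated operating range extends to 40 cm.

Age cut-offs for the ponderation classes are not part of the protocol
definition; the helper `age_class_from_age` uses young < 35 ≤ adult < 65 ≤
senior, configurable. Likewise the fitness class may be auto-derived from
the IPAQ level (1 → insufficiently, 2 → moderately, 3 → vigorously active),
overridable per participant.

The cadence schedule assumes 60-second stages, inferred from the published
rates (15 → 37.5 cycles·min⁻¹ in 2.5-increments within the 10-minute cap);
`stage_duration` is configurable. HRmax is the Tanaka estimate
208 − 0.7·age; the termination target defaults to 0.8 × HRmax.
`termination_check` fires at the *first* sample at or above the target;
operator flags (discomfort, cadence failure) stop the test at their own
timestamp and win ties.

## Session reduction

Averaging windows are closed intervals anchored at the end of each phase:
the final 60 s of rest, the final 5 s of each stage, and — for the recovery
point — the [55 s, 60 s] window of a clock that starts at the last exercise
sample. In-window samples are averaged arithmetically without time
weighting (a warning is issued when fewer than three samples fall in a 5-s
window, as happens when a stage is truncated by termination). HR at test
end (`hr_end`) defaults to the last-5-s average of the final stage,
consistent with the stage-endpoint convention; an instantaneous-sample
alternative is available. HRR₆₀ = hr_end − hr_60 may be negative for
pathological inputs; such values are flagged rather than rejected. VO₂ may
be absent throughout recovery; recovery summaries use HR only.

The HR–VO₂ line is fit by ordinary least squares through the resting point
plus at least three stage endpoints (the resting point can be excluded by
configuration). Zero HR variance is a degenerate-fit error. VO₂max is the
line evaluated at HRmax; when HRmax does not exceed the largest observed
HR the value is an interpolation and a warning is issued.

## Prediction and refitting

The published equation (intercept 17.105; HRR₆₀ 0.260; sex 8.563;
PA_level 4.097; R² = 74.0 %, SEE = 4.78) is shipped as an immutable
`PredictionModel`. PA_level enters as a numeric 1/2/3 covariate, matching
the single published coefficient, not as dummies. Out-of-domain inputs
(e.g. the formal zero point) are evaluated with a warning rather than
rejected, since the equation surface itself is well defined everywhere.

`backward_stepwise` starts from the full OLS model over the candidate set
(default: sex, body mass, height, BMI, PA_level, HRR₆₀; age optional),
removes the predictor with the largest p ≥ α, refits, and stops when all
remaining p < α. SEE is the residual standard error with the n − p − 1
denominator. Rank-deficient designs raise an error naming the collinear
columns. Note that at the original study size (n = 30) this procedure has
limited power and a non-trivial false-retention rate — in simulation the
true predictors are retained far more often than noise covariates but the
exact published set is recovered in only a minority of replicates; at
n = 2000 the exact set is recovered in roughly 85 % of replicates, the
remainder retaining one spurious anthropometric covariate, which is the
expected behaviour of α = 0.05 backward elimination, not a defect.

Cardiovascular-capacity classification keys on HRR₆₀ alone with half-open
bands Poor [0, 25), Moderate [25, 40), Good [40, 55), Excellent [55, ∞), so
that every value maps to exactly one class; negative inputs are flagged and
classified Poor. The sex-specific VO₂max reference intervals attached to
the bands are literature values shipped verbatim (including their printed
gaps) for reporting only — they are never used for classification.

## Agreement battery

Paired t uses df = n − 1 with a two-sided p and a 95 % t-interval;
zero-variance differences with nonzero mean report an infinite t with a
flag. Cohen's d defaults to the pooled-SD denominator
|m̄₁ − m̄₂| / √((s₁² + s₂²)/2), which reproduces the published validation
table's effect size from its printed summaries (the difference-SD variant
is exposed as an option). Descriptor bands: trivial < 0.20, small
0.20–0.59, moderate 0.6–1.19, large 1.2–1.99, very large ≥ 2.0.

The ICC is the single-measure two-way model with absolute agreement,
ICC(A,1), computed from the two-way ANOVA mean squares
(MSR − MSE) / (MSR + MSE + (2/n)(MSC − MSE)) for two methods; the
qualitative bands are poor < 0.5, moderate [0.5, 0.75), good [0.75, 0.90),
excellent ≥ 0.90 (half-open, so the bands partition the line). Bland–Altman
limits are bias ± 1.96·SD of the differences; differences exactly on a
limit count as within, and the qualitative criterion passes at ≥ 80 %
coverage. All label functions are pure threshold maps.

## Synthetic cohort and sessions

`SimulationConfig` defaults encode the study conditions: n = 69 with 42/69
men; age 21.7 ± 3.5 years truncated to [18, 35] (a young-adult cohort);
per-sex body mass (women 63.5 ± 14.8 kg, men 72.0 ± 7.3 kg), height
(1.64 ± 0.06 / 1.77 ± 0.07 m), resting HR (81 / 68 ± 11 bpm) and resting
VO₂ (3.4 / 3.7 ± 0.65 mL·kg⁻¹·min⁻¹); PA-level probabilities from the
published per-sex counts (women 15/8/4 of 27, men 3/24/15 of 42); HRR₆₀
truncated-normal 37 ± 11 bpm on [19, 63]. True VO₂max is drawn from the
prediction equation's mean structure plus Gaussian noise with SD 4.78 (the
published SEE), so refitting the equation on a synthetic cohort is a
well-posed parameter-recovery problem. Smoking prevalence (unreported in
the source cohort) is set to 20 %, a realistic figure for young European
adults; it feeds only the step-height factor. Continuous draws are
truncated to physiological ranges by rejection, which shifts heavy-tailed
means slightly (women's body mass by about +1.7 kg); tests compare sample
moments against the truncated-normal expectations. Per-participant
invariants are enforced by redraw: resting HR at least 25 bpm below the
termination target, HRR₆₀ below 90 % of the reserve between resting HR and
the target, and true VO₂max above resting VO₂.

Sessions are sampled at 1 Hz with 120 s of rest and recovery. Within-stage
HR steps instantaneously to a steady state rising linearly with cadence;
the crossing stage (stage 5–8, later for fitter participants) has its
steady state set exactly at the 80 % target, so a noise-free session
terminates at precisely 80 % of HRmax and the truncated final stage
contributes a single on-target sample. Per-sample VO₂ lies on the line
through (HR_rest, VO₂_rest) and (HRmax, true VO₂max) plus noise, which
makes the estimation pipeline exact in the noise-free limit — the core
identifiability check. Recovery HR decays mono-exponentially toward
resting HR, the simplest model consistent with parasympathetic
reactivation; the time constant is back-solved (Brent's method on the
discrete sampling grid) so the realized HRR₆₀ equals the drawn ground
truth. Default measurement noise (HR 2 bpm, VO₂ 1 mL·kg⁻¹·min⁻¹ per
sample) keeps individual fit R² above 0.97, inside the reported range.

What the generator does *not* emulate: breath-by-breath noise spectra, VO₂
on-kinetics and the slow component, within-stage HR drift, ectopic beats,
and day-to-day biological variability. Passing tests therefore demonstrate
the correctness and internal consistency of the computational chain under
the stated generative model, not the field validity of the protocol on
real participants.

## Problem sizes and numerics

The test suite runs the full pipeline on cohorts up to n = 10 000
(moment checks), 100 noise-free sessions for pipeline-recovery, 100
replicates of n = 2000 for parameter recovery, and 500 random small
instances for oracle equivalence of the paired t, OLS, and ICC
computations against independent summation/ANOVA implementations. All
random draws use seeded `numpy` generators; hypothesis runs derandomized.
Floating-point ties at window boundaries are resolved by closed intervals,
and the crossing-stage steady state is assigned the target exactly to
avoid an ulp-level shortfall in the termination comparison.
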