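# steptest4all

A toolkit for submaximal cardiovascular-capacity assessment with an
individualized step test. It is aimed at exercise physiologists and sports
scientists who estimate maximal oxygen uptake (VO₂max) without running
participants to exhaustion, and at methodologists who want the full
estimation-and-validation chain — protocol individualization, submaximal
extrapolation, prediction equation, classification, and method-agreement
statistics — as tested, scriptable building blocks.

## The method

**Protocol.** Each participant steps up and down a single step whose height
is individualized from five categorical ponderation factors (sex, age class,
physical fitness, BMI band, smoking status):

```
step height (cm) = 4 × (sum of factor values) + 15        ∈ [15, 40]
```

Cadence starts at 15 cycles·min⁻¹ (0.25 Hz) and rises by 2.5 cycles·min⁻¹
per one-minute stage up to 37.5 cycles·min⁻¹, within a 10-minute cap. The
test ends at the first heart-rate sample reaching 80 % of the age-predicted
maximum, HRmax = 208 − 0.7·age (Tanaka formula).

**Estimation.** HR and VO₂ are reduced to a resting point (last-minute
average of rest) and per-stage endpoints (last-5-s averages). The individual
ordinary-least-squares line VO₂ = a + b·HR through these points is
extrapolated to HRmax to estimate VO₂max. Heart-rate recovery at 60 s,
HRR₆₀ = HR at termination − HR one minute into recovery, summarizes
autonomic recovery.

**Prediction.** A population-level equation predicts VO₂max
(mL·kg⁻¹·min⁻¹) from HRR₆₀ (bpm), sex (women 0, men 1), and the IPAQ
short-form physical-activity level PA_level ∈ {1, 2, 3}:

```
VO₂max = 17.105 + 0.260·HRR₆₀ + 8.563·sex + 4.097·PA_level
```

(R² = 74.0 %, SEE = 4.78). `backward_stepwise` refits it on new cohorts by
backward elimination at α = 0.05. HRR₆₀ also maps to a qualitative
cardiovascular-capacity class: Poor < 25, Moderate 25–39, Good 40–54,
Excellent ≥ 55 bpm.

**Validation.** The agreement battery compares measured and predicted
VO₂max with a paired t-test, Cohen's d (with descriptors), single-measure
two-way mixed absolute-agreement ICC (with qualitative bands), and
Bland–Altman limits of agreement with a ≥ 80 % coverage criterion.

**Simulation.** `steptest4all.simulate` generates cohorts and full
phase-labelled sessions with known ground truth under the study conditions,
so every stage of the chain can be verified end to end.

## Worked example

```python
import numpy as np
from steptest4all import (
    SimulationConfig, sample_cohort, simulate_session, analyze_session,
    predict_vo2max, classify_cvc,
)

cfg = SimulationConfig(n=1, seed=424242, hr_noise_sd=0.0, vo2_noise_sd=0.0)
participant = sample_cohort(cfg)[0]
session = simulate_session(participant, cfg, np.random.default_rng(424242))
report = analyze_session(session, hrmax=participant.hrmax)
print(f"HR rest      {report.hr_rest:.1f} bpm")
print(f"fit          VO2 = {report.fit.intercept:.3f} + {report.fit.slope:.4f} x HR  (R2 = {report.fit.r2:.4f})")
print(f"VO2max       {report.vo2max:.2f} (true {participant.true_vo2max:.2f}) mL/kg/min")
print(f"HRR60        {report.recovery.hrr60:.1f} bpm -> {classify_cvc(report.recovery.hrr60).label}")
print(f"equation     {predict_vo2max(report.recovery.hrr60, 1, 3):.2f} mL/kg/min")
```

prints

```
HR rest      77.7 bpm
fit          VO2 = -28.949 + 0.4204 x HR  (R2 = 1.0000)
VO2max       51.48 (true 51.48) mL/kg/min
HRR60        35.4 bpm -> Moderate
equation     47.17 mL/kg/min
```

— the noise-free session recovers the simulated true VO₂max exactly, the
HRR₆₀ of 35.4 bpm falls in the Moderate band, and the population equation
evaluated for this highly active man at that HRR₆₀ gives 47.17
mL·kg⁻¹·min⁻¹ (the gap to 51.48 is exactly the kind of individual residual
the equation's SEE of 4.78 describes).

The same operations are available from a shell:

```bash
steptest4all predict --hrr60 38 --sex M --pa-level 2   # 43.742
steptest4all classify --hrr60 42                       # Good (HRR60 band [40, 55) bpm)
steptest4all simulate cohort --n 69 --seed 7 --out sim/ --sessions
steptest4all refit sim/cohort.csv
```

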