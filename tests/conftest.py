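import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from steptest4all.estimation import PhysioTimeSeries

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def make_session():
    """Build a 1 Hz phase-labelled session from per-phase HR/VO2 values.

    ``stage_hr``/``stage_vo2`` are per-stage constants (or callables of the
    in-stage second); ``recovery_hr`` is a callable of seconds since the end
    of exercise (defaults to instant return to 80 bpm).
    """

    def _build(
        rest_hr=70.0,
        rest_vo2=3.5,
        rest_dur=120,
        stage_hr=(100.0, 115.0, 130.0),
        stage_vo2=(10.0, 15.0, 20.0),
        stage_dur=60,
        recovery_hr=lambda t: 80.0,
        recovery_dur=120,
    ):
        times, hrs, vo2s, phases = [], [], [], []
        t = 0
        for _ in range(rest_dur):
            times.append(t)
            hrs.append(rest_hr(t) if callable(rest_hr) else rest_hr)
            vo2s.append(rest_vo2)
            phases.append("rest")
            t += 1
        for k, (hr_k, vo2_k) in enumerate(zip(stage_hr, stage_vo2), start=1):
            for j in range(stage_dur):
                times.append(t)
                hrs.append(hr_k(j) if callable(hr_k) else hr_k)
                vo2s.append(vo2_k(j) if callable(vo2_k) else vo2_k)
                phases.append(f"stage_{k}")
                t += 1
        t_end = times[-1]
        for off in range(1, recovery_dur + 1):
            times.append(t_end + off)
            hrs.append(recovery_hr(off))
            vo2s.append(math.nan)
            phases.append("recovery")
        return PhysioTimeSeries(
            pd.DataFrame(
                {"time_s": [float(x) for x in times], "hr_bpm": hrs,
                 "vo2_mlkgmin": vo2s, "phase": phases}
            )
        )

    return _build


@pytest.fixture
def rng():
    return np.random.default_rng(20240208)
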