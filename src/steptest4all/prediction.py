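"""VO2max prediction equation, refitting, and HRR60-based classification.

The published equation predicts maximal oxygen uptake (mL·kg⁻¹·min⁻¹) from
heart-rate recovery at 60 s, sex (women 0, men 1), and the ordinal IPAQ
physical-activity level (1/2/3, entered as a numeric covariate):

    VO2max = 17.105 + 0.260·HRR60 + 8.563·sex + 4.097·PA_level
    (R² = 74.0%, SEE = 4.78 mL·kg⁻¹·min⁻¹)

``backward_stepwise`` reproduces the selection procedure that produced it:
start from the full OLS model over the candidate predictors, repeatedly drop
the predictor with the largest p-value >= alpha, refit, and stop when every
remaining predictor is significant.

Cardiovascular capacity is classified from HRR60 alone with half-open bands:
Poor [0, 25), Moderate [25, 40), Good [40, 55), Excellent [55, inf).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import DegenerateDesignError, ModelError, ValidationError
from .protocol import Sex

__all__ = [
    "PredictionModel",
    "PUBLISHED_MODEL",
    "CVCClass",
    "predict_vo2max",
    "backward_stepwise",
    "classify_cvc",
    "reference_bands",
    "DEFAULT_CANDIDATES",
]

DEFAULT_CANDIDATES = ("sex", "body_mass", "height", "bmi", "pa_level", "hrr60")


@dataclass(frozen=True)
class PredictionModel:
    """Linear VO2max model: coefficients plus fit diagnostics.

    ``coefficients`` maps ``"intercept"`` and each retained predictor to its
    value; ``pvalues`` (when available) maps retained predictors to their
    two-sided p; ``see`` is the residual standard error in outcome units.
    """

    coefficients: Mapping[str, float]
    retained: tuple[str, ...]
    r2: Optional[float] = None
    see: Optional[float] = None
    pvalues: Optional[Mapping[str, float]] = None
    n: Optional[int] = None

    def __post_init__(self):
        if "intercept" not in self.coefficients:
            raise ModelError("model must include an intercept coefficient")
        extras = set(self.coefficients) - {"intercept"} - set(self.retained)
        missing = set(self.retained) - set(self.coefficients)
        if extras or missing:
            raise ModelError(
                f"coefficients/retained mismatch (extra={sorted(extras)}, "
                f"missing={sorted(missing)})"
            )

    def predict(self, values: Mapping[str, float]) -> float:
        """Evaluate the linear combination for one record."""
        unknown = set(values) - set(self.retained)
        if unknown:
            raise ModelError(f"unknown predictor keys: {sorted(unknown)}")
        missing = set(self.retained) - set(values)
        if missing:
            raise ModelError(f"missing predictor values: {sorted(missing)}")
        return self.coefficients["intercept"] + sum(
            self.coefficients[k] * float(values[k]) for k in self.retained
        )


#: Coefficients of the published prediction equation.
PUBLISHED_MODEL = PredictionModel(
    coefficients={
        "intercept": 17.105,
        "hrr60": 0.260,
        "sex": 8.563,
        "pa_level": 4.097,
    },
    retained=("hrr60", "sex", "pa_level"),
    r2=0.740,
    see=4.78,
    pvalues={"sex": 0.001, "pa_level": 0.014, "hrr60": 0.020},
    n=30,
)


def predict_vo2max(
    hrr60: float,
    sex_code: int,
    pa_level: int,
    model: PredictionModel = PUBLISHED_MODEL,
) -> float:
    """Predicted VO2max (mL·kg⁻¹·min⁻¹) for one participant.

    ``sex_code`` is 0 for women, 1 for men. Values outside the nominal
    domains (sex in {0,1}, pa_level in {1,2,3}, hrr60 >= 0) are evaluated
    formally with a warning.
    """
    if sex_code not in (0, 1) or pa_level not in (1, 2, 3) or hrr60 < 0:
        warnings.warn(
            "inputs outside nominal domain (sex {0,1}, pa_level {1,2,3}, "
            "hrr60 >= 0); evaluating formally", stacklevel=2,
        )
    return model.predict({"hrr60": hrr60, "sex": sex_code, "pa_level": pa_level})


def _check_design(X: pd.DataFrame) -> None:
    arr = np.column_stack([np.ones(len(X)), X.to_numpy(dtype=float)])
    if np.linalg.matrix_rank(arr) < arr.shape[1]:
        # name the columns that are linear combinations of the earlier ones
        offending = []
        cols = [np.ones(len(X))]
        for name in X.columns:
            trial = np.column_stack(cols + [X[name].to_numpy(dtype=float)])
            if np.linalg.matrix_rank(trial) < trial.shape[1]:
                offending.append(name)
            else:
                cols.append(X[name].to_numpy(dtype=float))
        raise DegenerateDesignError(
            f"design matrix is rank deficient; collinear columns: {offending}",
            columns=offending,
        )


def backward_stepwise(
    cohort: pd.DataFrame,
    outcome: str = "vo2max",
    candidates: Sequence[str] = DEFAULT_CANDIDATES,
    alpha: float = 0.05,
) -> PredictionModel:
    """Backward elimination OLS at significance level ``alpha``.

    Starts from the full model over ``candidates``, removes the predictor
    with the largest p >= alpha, refits, and stops when all remaining
    predictors have p < alpha (possibly the intercept-only model). Returns
    the selected model with per-predictor p-values, R², and SEE (residual
    standard error with n − p − 1 denominator).
    """
    if not 0 < alpha < 1:
        raise ValidationError(f"alpha must be in (0, 1), got {alpha!r}")
    missing = [c for c in list(candidates) + [outcome] if c not in cohort.columns]
    if missing:
        raise ValidationError(f"cohort lacks columns: {missing}")
    data = cohort[[outcome, *candidates]].dropna()
    n = len(data)
    if n < len(candidates) + 2:
        raise ValidationError(
            f"need >= {len(candidates) + 2} complete records, got {n}"
        )
    y = data[outcome].astype(float)
    remaining = list(candidates)
    _check_design(data[remaining])

    while True:
        X = sm.add_constant(data[remaining].astype(float)) if remaining else (
            pd.DataFrame({"const": np.ones(n)}, index=data.index)
        )
        res = sm.OLS(y, X).fit()
        pvals = res.pvalues.drop("const", errors="ignore")
        if len(pvals) and pvals.max() >= alpha:
            remaining.remove(pvals.idxmax())
            continue
        break

    coefficients = {"intercept": float(res.params["const"])}
    for name in remaining:
        coefficients[name] = float(res.params[name])
    see = float(np.sqrt(res.mse_resid)) if res.df_resid > 0 else float("nan")
    return PredictionModel(
        coefficients=coefficients,
        retained=tuple(remaining),
        r2=float(res.rsquared),
        see=see,
        pvalues={name: float(res.pvalues[name]) for name in remaining},
        n=n,
    )


# --- HRR60-based cardiovascular capacity classification -------------------

@dataclass(frozen=True)
class CVCClass:
    """Qualitative cardiovascular-capacity band keyed on HRR60.

    ``hrr60_band`` is the half-open interval [low, high) in bpm.
    ``reference_vo2max`` and ``mcardle_vo2max`` are literature reference
    intervals (mL·kg⁻¹·min⁻¹) shipped verbatim; they are descriptive only
    and never used for classification.
    """

    label: str
    hrr60_band: tuple[float, float]
    reference_vo2max: Optional[tuple[Optional[float], Optional[float]]] = None
    mcardle_vo2max: Optional[tuple[Optional[float], Optional[float]]] = None
    flagged: bool = False


_CVC_BANDS = (
    ("Poor", (0.0, 25.0)),
    ("Moderate", (25.0, 40.0)),
    ("Good", (40.0, 55.0)),
    ("Excellent", (55.0, math.inf)),
)

# Literature VO2max reference intervals per sex and band, shipped untransformed.
# (lower, upper); None marks an open end.
_REFERENCE_VO2MAX = {
    Sex.MAN: {
        "Poor": ((None, 40.0), (None, 36.5)),
        "Moderate": ((42.0, 44.2), (36.5, 42.4)),
        "Good": ((44.3, 49.0), (42.5, 46.4)),
        "Excellent": ((49.0, None), (46.5, None)),
    },
    Sex.WOMAN: {
        "Poor": ((None, 28.0), (None, 29.0)),
        "Moderate": ((28.0, 32.2), (29.0, 32.0)),
        "Good": ((32.3, 36.9), (33.0, 36.0)),
        "Excellent": ((37.0, None), (37.0, None)),
    },
}


def classify_cvc(hrr60: float) -> CVCClass:
    """Band for one HRR60 value. Negative inputs are flagged and mapped to Poor."""
    if hrr60 < 0:
        return CVCClass(label="Poor", hrr60_band=(0.0, 25.0), flagged=True)
    for label, (lo, hi) in _CVC_BANDS:
        if lo <= hrr60 < hi:
            return CVCClass(label=label, hrr60_band=(lo, hi))
    raise AssertionError("bands must partition [0, inf)")  # pragma: no cover


def reference_bands(sex: Sex | str) -> list[CVCClass]:
    """The four bands with sex-specific literature VO2max reference intervals."""
    sex = Sex(sex)
    out = []
    for label, band in _CVC_BANDS:
        ref, mcardle = _REFERENCE_VO2MAX[sex][label]
        out.append(
            CVCClass(
                label=label,
                hrr60_band=band,
                reference_vo2max=ref,
                mcardle_vo2max=mcardle,
            )
        )
    return out
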