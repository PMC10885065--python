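"""Measured-vs-predicted agreement battery.

Validation of the prediction equation against measured VO2max uses four
complementary views of the paired data:

* paired t-test on the differences with a 95% CI on the mean difference;
* Cohen's d with qualitative descriptors (trivial < 0.20, small 0.20-0.59,
  moderate 0.6-1.19, large 1.2-1.99, very large >= 2.0);
* single-measure two-way mixed-model intraclass correlation with an
  absolute-agreement definition, labelled poor < 0.5, moderate [0.5, 0.75),
  good [0.75, 0.90), excellent >= 0.90;
* Bland-Altman bias and limits of agreement (bias ± 1.96·SD of the
  differences), with the qualitative criterion that >= 80% of paired
  differences fall within the limits.

Cohen's d defaults to the pooled-SD denominator
|m1 − m2| / sqrt((sd1² + sd2²)/2); the difference-SD variant is available.
Differences exactly on a limit of agreement count as within.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import UndefinedStatisticError, ValidationError

__all__ = [
    "PairedMeasurements",
    "PairedTResult",
    "AgreementReport",
    "paired_t",
    "implied_t_from_ci",
    "cohens_d",
    "cohens_d_from_summary",
    "d_label",
    "icc_absolute_agreement",
    "icc_label",
    "bland_altman",
    "validate_agreement",
]


@dataclass(frozen=True)
class PairedMeasurements:
    """Per-subject measured and predicted values (equal lengths >= 3)."""

    measured: tuple[float, ...]
    predicted: tuple[float, ...]

    def __post_init__(self):
        m = np.asarray(self.measured, dtype=float)
        p = np.asarray(self.predicted, dtype=float)
        if m.shape != p.shape:
            raise ValidationError("measured and predicted must have equal length")
        if len(m) < 3:
            raise ValidationError(f"need >= 3 pairs, got {len(m)}")
        if not (np.all(np.isfinite(m)) and np.all(np.isfinite(p))):
            raise ValidationError("values must be finite")
        object.__setattr__(self, "measured", tuple(float(x) for x in m))
        object.__setattr__(self, "predicted", tuple(float(x) for x in p))

    @property
    def n(self) -> int:
        return len(self.measured)

    @property
    def differences(self) -> np.ndarray:
        return np.asarray(self.measured) - np.asarray(self.predicted)


@dataclass(frozen=True)
class PairedTResult:
    mean_diff: float
    ci95: tuple[float, float]
    t_stat: float
    df: int
    p_value: float
    infinite: bool = False  # zero-variance differences with nonzero mean


def paired_t(pairs: PairedMeasurements, conf: float = 0.95) -> PairedTResult:
    """Paired-difference t-test with df = n − 1 and a two-sided p."""
    d = pairs.differences
    n = pairs.n
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    df = n - 1
    if sd == 0.0:
        if mean == 0.0:
            return PairedTResult(0.0, (0.0, 0.0), 0.0, df, 1.0)
        t = math.copysign(math.inf, mean)
        return PairedTResult(mean, (mean, mean), t, df, 0.0, infinite=True)
    se = sd / math.sqrt(n)
    t = mean / se
    p = 2.0 * stats.t.sf(abs(t), df)
    tcrit = stats.t.ppf(0.5 + conf / 2.0, df)
    ci = (mean - tcrit * se, mean + tcrit * se)
    return PairedTResult(mean, ci, t, df, float(p))


def implied_t_from_ci(ci_low: float, ci_high: float, n: int, conf: float = 0.95) -> float:
    """Back out the paired t statistic from a printed mean-difference CI.

    The CI center is the mean difference and the half-width equals
    t_crit · SE, so t = center / (half_width / t_crit).
    """
    if n < 2:
        raise ValidationError("need n >= 2")
    if ci_high <= ci_low:
        raise ValidationError("ci_high must exceed ci_low")
    center = (ci_low + ci_high) / 2.0
    half = (ci_high - ci_low) / 2.0
    tcrit = stats.t.ppf(0.5 + conf / 2.0, n - 1)
    return center / (half / tcrit)


_D_BANDS = (
    (0.20, "trivial"),
    (0.60, "small"),
    (1.20, "moderate"),
    (2.00, "large"),
    (math.inf, "very large"),
)


def d_label(d: float) -> str:
    """Qualitative descriptor for an (absolute) effect size."""
    d = abs(d)
    for upper, label in _D_BANDS:
        if d < upper:
            return label
    return "very large"  # pragma: no cover


def cohens_d_from_summary(
    mean1: float, sd1: float, mean2: float, sd2: float
) -> tuple[float, str]:
    """Pooled-SD effect size from printed group summaries."""
    denom = math.sqrt((sd1**2 + sd2**2) / 2.0)
    if denom == 0.0:
        raise UndefinedStatisticError("zero pooled SD; effect size undefined")
    d = abs(mean1 - mean2) / denom
    return d, d_label(d)


def cohens_d(
    pairs: PairedMeasurements, variant: str = "pooled_sd"
) -> tuple[float, str]:
    """Effect size of the measured-predicted difference with its descriptor."""
    m = np.asarray(pairs.measured)
    p = np.asarray(pairs.predicted)
    if variant == "pooled_sd":
        return cohens_d_from_summary(
            float(m.mean()), float(m.std(ddof=1)),
            float(p.mean()), float(p.std(ddof=1)),
        )
    if variant == "diff_sd":
        sd = float(pairs.differences.std(ddof=1))
        if sd == 0.0:
            raise UndefinedStatisticError("zero SD of differences")
        d = abs(float(pairs.differences.mean())) / sd
        return d, d_label(d)
    raise ValidationError(f"unknown Cohen's d variant {variant!r}")


def icc_label(icc: float) -> str:
    """Qualitative agreement band for an ICC value."""
    if icc < 0.5:
        return "poor"
    if icc < 0.75:
        return "moderate"
    if icc < 0.90:
        return "good"
    return "excellent"


def icc_absolute_agreement(pairs: PairedMeasurements) -> tuple[float, str]:
    """Single-measure two-way mixed-model ICC with absolute agreement.

    Computed from the two-way ANOVA mean squares of the n x 2 table
    (subjects x methods): with MSR the between-subject, MSC the
    between-method, and MSE the residual mean square,

        ICC = (MSR − MSE) / (MSR + (k−1)·MSE + k/n·(MSC − MSE)),  k = 2.
    """
    data = np.column_stack([pairs.measured, pairs.predicted])
    n, k = data.shape
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * float(((row_means - grand) ** 2).sum())
    ss_cols = n * float(((col_means - grand) ** 2).sum())
    ss_total = float(((data - grand) ** 2).sum())
    ss_err = ss_total - ss_rows - ss_cols
    if ss_total == 0.0:
        raise UndefinedStatisticError("zero total variance; ICC undefined")
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if denom == 0.0:
        raise UndefinedStatisticError("degenerate ANOVA decomposition")
    icc = (msr - mse) / denom
    return float(icc), icc_label(float(icc))


@dataclass(frozen=True)
class BlandAltmanResult:
    bias: float
    loa: tuple[float, float]
    pct_within_loa: float
    loa_pass: bool


def bland_altman(
    pairs: PairedMeasurements, z: float = 1.96, pass_threshold: float = 80.0
) -> BlandAltmanResult:
    """Bias, limits of agreement, and the >= 80% coverage criterion.

    Limits are bias ± z·SD of the differences; differences exactly on a
    limit count as within.
    """
    d = pairs.differences
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    loa = (bias - z * sd, bias + z * sd)
    within = np.sum((d >= loa[0]) & (d <= loa[1]))
    pct = 100.0 * float(within) / pairs.n
    return BlandAltmanResult(bias, loa, pct, pct >= pass_threshold)


@dataclass(frozen=True)
class AgreementReport:
    """All agreement statistics for one measured-vs-predicted comparison."""

    n: int
    mean_diff: float
    ci95: tuple[float, float]
    t_stat: float
    df: int
    p_value: float
    d: float
    d_label: str
    icc: float
    icc_label: str
    bias: float
    loa: tuple[float, float]
    pct_within_loa: float
    loa_pass: bool


def validate_agreement(
    pairs: PairedMeasurements, d_variant: str = "pooled_sd"
) -> AgreementReport:
    """Run the full battery on one set of pairs."""
    t_res = paired_t(pairs)
    d, dl = cohens_d(pairs, variant=d_variant)
    icc, il = icc_absolute_agreement(pairs)
    ba = bland_altman(pairs)
    return AgreementReport(
        n=pairs.n,
        mean_diff=t_res.mean_diff,
        ci95=t_res.ci95,
        t_stat=t_res.t_stat,
        df=t_res.df,
        p_value=t_res.p_value,
        d=d,
        d_label=dl,
        icc=icc,
        icc_label=il,
        bias=ba.bias,
        loa=ba.loa,
        pct_within_loa=ba.pct_within_loa,
        loa_pass=ba.loa_pass,
    )
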