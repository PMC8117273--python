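"""Repeatability and agreement statistics for paired scan measurements.

Used to compare repeated breath-hold scans (BH1 vs BH2) and breath-hold vs
free-breathing quantification: Bland–Altman bias and limits of agreement,
test–retest intraclass correlation ICC(A,1) — two-way mixed effects,
absolute agreement, single measurement — and ordinary least-squares
regression with the Pearson correlation coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .datamodel import ValidationError

ICC_BANDS = ((0.90, "excellent"), (0.75, "good"), (0.50, "moderate"))


@dataclass
class PairedMeasurements:
    """Two measurements of the same quantity in the same subjects."""

    x: np.ndarray
    y: np.ndarray
    subjects: list | None = None
    label: str = ""

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape or self.x.ndim != 1:
            raise ValidationError("x and y must be 1-D arrays of equal length")
        if self.x.size < 3:
            raise ValidationError("need at least 3 pairs")
        if not (np.isfinite(self.x).all() and np.isfinite(self.y).all()):
            raise ValidationError("pairs must be finite")
        if self.subjects is None:
            self.subjects = list(range(self.x.size))

    @property
    def n(self) -> int:
        return self.x.size


@dataclass
class BlandAltmanResult:
    bias: float
    loa_low: float
    loa_high: float
    sd_diff: float
    outlier_flags: np.ndarray


def bland_altman(pairs: PairedMeasurements) -> BlandAltmanResult:
    """Bland–Altman agreement: differences are first-minus-second scan,
    limits of agreement are bias ± 1.96 x sample SD of the differences."""
    d = pairs.x - pairs.y
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    lo, hi = bias - 1.96 * sd, bias + 1.96 * sd
    flags = (d < lo) | (d > hi)
    return BlandAltmanResult(
        bias=bias, loa_low=lo, loa_high=hi, sd_diff=sd, outlier_flags=flags
    )


def icc_test_retest(pairs: PairedMeasurements) -> tuple[float, str]:
    """Test–retest ICC(A,1): two-way mixed effects, absolute agreement,
    single measurement, from the two-way ANOVA mean squares.

    With n subjects and k = 2 repeated measurements,
    ``ICC = (MSR − MSE) / (MSR + (k−1)·MSE + k·(MSC − MSE)/n)``.
    Values are reported unclipped (sampling can push them below 0);
    classification bands: < 0.5 poor, 0.5–0.75 moderate, 0.75–0.90 good,
    ≥ 0.90 excellent.
    """
    data = np.column_stack([pairs.x, pairs.y])
    n, k = data.shape
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * float(np.sum((row_means - grand) ** 2))
    ss_cols = n * float(np.sum((col_means - grand) ** 2))
    ss_total = float(np.sum((data - grand) ** 2))
    ss_err = ss_total - ss_rows - ss_cols
    if ss_total == 0:
        raise ValidationError("zero total variance: ICC undefined")
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    icc = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    band = "poor"
    for cut, name in ICC_BANDS:
        if icc >= cut:
            band = name
            break
    return float(icc), band


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r: float
    p_value: float


def regression(pairs: PairedMeasurements) -> RegressionResult:
    """OLS of y on x with Pearson r and the two-sided p-value from the t
    distribution with n − 2 degrees of freedom."""
    if np.var(pairs.x) == 0:
        raise ValidationError("constant x: regression undefined")
    res = sps.linregress(pairs.x, pairs.y)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r=float(res.rvalue),
        p_value=float(res.pvalue),
    )


@dataclass
class RepeatabilityReport:
    """Everything the paired-scan comparison produces for one metabolite."""

    label: str
    bias: float
    loa_low: float
    loa_high: float
    icc: float
    icc_class: str
    r: float
    slope: float
    intercept: float
    p_value: float
    outlier_flags: np.ndarray = field(default_factory=lambda: np.array([]))


def repeatability_report(pairs: PairedMeasurements) -> RepeatabilityReport:
    """Bland–Altman + ICC + regression in one record."""
    ba = bland_altman(pairs)
    icc, band = icc_test_retest(pairs)
    reg = regression(pairs)
    return RepeatabilityReport(
        label=pairs.label,
        bias=ba.bias,
        loa_low=ba.loa_low,
        loa_high=ba.loa_high,
        icc=icc,
        icc_class=band,
        r=reg.r,
        slope=reg.slope,
        intercept=reg.intercept,
        p_value=reg.p_value,
        outlier_flags=ba.outlier_flags,
    )
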