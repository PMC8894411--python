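"""Agreement statistics for paired angle measurements.

Implements the three summaries used to validate one measurement route
against another:

* single-rater **intraclass correlation for absolute agreement** — ICC(A,1)
  in McGraw-Wong terms — from the two-way ANOVA mean squares, with the
  F-distribution 95% confidence interval.  The point estimator is identical
  for the two-way random and two-way mixed designs; the ``model`` flag is
  recorded for interpretation.
* **Bland-Altman** bias and 95% limits of agreement (bias +/- 1.96 SD of
  the paired differences, sample SD), with an optional plot.
* **median absolute difference** with interquartile range
  (linear-interpolation percentiles).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "PairedMeasurements",
    "ICCResult",
    "BlandAltmanResult",
    "MedianAbsDiffResult",
    "AgreementReport",
    "UndefinedICCError",
    "icc_absolute_agreement",
    "bland_altman",
    "bland_altman_plot",
    "median_abs_diff",
    "agreement_report",
]

logger = logging.getLogger(__name__)


class UndefinedICCError(ValueError):
    """The ICC is undefined (no between-subject variance)."""


@dataclass(frozen=True)
class PairedMeasurements:
    """Two same-length measurement series on the same subjects (degrees)."""

    a: np.ndarray
    b: np.ndarray
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "a", np.asarray(self.a, dtype=float))
        object.__setattr__(self, "b", np.asarray(self.b, dtype=float))
        if self.a.ndim != 1 or self.a.shape != self.b.shape:
            raise ValueError("a and b must be 1-D and of equal length")
        if not (np.all(np.isfinite(self.a)) and np.all(np.isfinite(self.b))):
            raise ValueError("missing/non-finite values are not allowed")
        if self.labels is not None:
            object.__setattr__(self, "labels", np.asarray(self.labels))
            if len(self.labels) != len(self.a):
                raise ValueError("labels length mismatch")

    def __len__(self) -> int:
        return len(self.a)

    def table(self) -> np.ndarray:
        return np.column_stack([self.a, self.b])

    def differences(self) -> np.ndarray:
        return self.a - self.b


@dataclass(frozen=True)
class ICCResult:
    icc: float
    ci_low: float
    ci_high: float
    model: str
    n_subjects: int
    n_raters: int


@dataclass(frozen=True)
class BlandAltmanResult:
    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    n: int


@dataclass(frozen=True)
class MedianAbsDiffResult:
    median: float
    iqr_low: float
    iqr_high: float


@dataclass(frozen=True)
class AgreementReport:
    """One row of a validity/reliability table: ICC with 95% CI,
    Bland-Altman bias with limits of agreement, and the median absolute
    difference with IQR."""

    icc: float
    icc_ci_low: float
    icc_ci_high: float
    bias: float
    loa_low: float
    loa_high: float
    median_abs_diff: float
    mad_iqr_low: float
    mad_iqr_high: float
    model: str
    n: int

    def __post_init__(self) -> None:
        if not (self.icc_ci_low <= self.icc <= self.icc_ci_high):
            raise ValueError("ICC must lie inside its confidence interval")
        if not (self.loa_low <= self.bias <= self.loa_high):
            raise ValueError("bias must lie inside the limits of agreement")
        if not (self.mad_iqr_low <= self.median_abs_diff <= self.mad_iqr_high):
            raise ValueError("median must lie inside its IQR")


def _as_table(data) -> np.ndarray:
    if isinstance(data, PairedMeasurements):
        return data.table()
    table = np.asarray(data, dtype=float)
    if table.ndim != 2:
        raise ValueError("expected an n_subjects x k_raters table")
    if not np.all(np.isfinite(table)):
        raise ValueError("missing/non-finite values are not allowed")
    return table


def icc_absolute_agreement(data, model: str = "mixed") -> ICCResult:
    """Single-rater absolute-agreement ICC with 95% confidence interval.

    ``data`` is either :class:`PairedMeasurements` or an
    ``n_subjects x k_raters`` array.  From the two-way ANOVA mean squares
    (rows = subjects, columns = raters/measurements):

        ICC(A,1) = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)

    The confidence interval uses the F-distribution method with
    Satterthwaite degrees of freedom.  ``model`` is ``"mixed"`` (fixed
    raters) or ``"random"``; the estimator is the same, the flag is carried
    in the result.
    """
    if model not in ("mixed", "random"):
        raise ValueError("model must be 'mixed' or 'random'")
    table = _as_table(data)
    n, k = table.shape
    if n < 3:
        raise ValueError(f"need at least 3 subjects, got {n}")
    if k < 2:
        raise ValueError(f"need at least 2 raters/measurements, got {k}")

    grand = table.mean()
    row_means = table.mean(axis=1)
    col_means = table.mean(axis=0)
    ss_rows = k * float(np.sum((row_means - grand) ** 2))
    ss_cols = n * float(np.sum((col_means - grand) ** 2))
    resid = table - row_means[:, None] - col_means[None, :] + grand
    ss_err = float(np.sum(resid**2))
    ss_total = float(np.sum((table - grand) ** 2))
    if ss_rows <= 1e-12 * max(1.0, ss_total):
        raise UndefinedICCError("zero between-subject variance: ICC undefined")

    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))

    if mse == 0.0 and msc == 0.0:
        # perfect agreement: every column identical
        return ICCResult(1.0, 1.0, 1.0, model, n, k)

    r = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)

    # F-method CI (two-way, absolute agreement, single rater)
    alpha = 0.05
    a = k * r / (n * (1.0 - r)) if r < 1.0 else np.inf
    b = 1.0 + k * r * (n - 1.0) / (n * (1.0 - r)) if r < 1.0 else np.inf
    if not np.isfinite(a):
        lo, hi = 1.0, 1.0
    else:
        num = (a * msc + b * mse) ** 2
        den = (a * msc) ** 2 / (k - 1.0) + (b * mse) ** 2 / ((n - 1.0) * (k - 1.0))
        v = num / den
        f_lo = stats.f.ppf(1.0 - alpha / 2.0, n - 1.0, v)
        f_hi = stats.f.ppf(1.0 - alpha / 2.0, v, n - 1.0)
        lo = n * (msr - f_lo * mse) / (
            f_lo * (k * msc + (k * n - k - n) * mse) + n * msr
        )
        hi = n * (f_hi * msr - mse) / (
            k * msc + (k * n - k - n) * mse + n * f_hi * msr
        )
        lo, hi = float(np.clip(lo, -1.0, 1.0)), float(np.clip(hi, -1.0, 1.0))
    return ICCResult(float(r), lo, hi, model, n, k)


def bland_altman(data: PairedMeasurements) -> BlandAltmanResult:
    """Bias and 95% limits of agreement for paired measurements.

    bias = mean(a - b); LoA = bias +/- 1.96 * SD(a - b) with the n-1 sample
    SD.  Identical series yield a degenerate zero-width interval (logged,
    not an error).
    """
    d = data.differences()
    if len(d) < 2:
        raise ValueError("need at least 2 pairs")
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    if sd == 0.0:
        logger.warning("zero SD of differences: limits of agreement collapse to the bias")
    return BlandAltmanResult(
        bias=bias,
        sd_diff=sd,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
        n=len(d),
    )


def bland_altman_plot(data: PairedMeasurements, path=None, ax=None):
    """Mean-vs-difference plot with the bias line and 95% limits of
    agreement; saves to ``path`` when given, returns the axes."""
    import matplotlib

    if path is not None and ax is None:
        matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    res = bland_altman(data)
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    mean = (data.a + data.b) / 2.0
    ax.scatter(mean, data.differences(), s=12, alpha=0.6, edgecolor="none")
    ax.axhline(res.bias, color="k", lw=1.2, label=f"bias {res.bias:.2f}")
    for y in (res.loa_low, res.loa_high):
        ax.axhline(y, color="k", lw=1.0, ls=":")
    ax.set_xlabel("mean of methods (deg)")
    ax.set_ylabel("difference (deg)")
    ax.legend(frameon=False)
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
    return ax


def median_abs_diff(data: PairedMeasurements) -> MedianAbsDiffResult:
    """Median and interquartile range of |a - b| (linear-interpolation
    percentile rule)."""
    d = np.abs(data.differences())
    if len(d) < 1:
        raise ValueError("need at least 1 pair")
    q25, q50, q75 = np.percentile(d, [25.0, 50.0, 75.0])
    return MedianAbsDiffResult(median=float(q50), iqr_low=float(q25), iqr_high=float(q75))


def agreement_report(a, b=None, model: str = "mixed", labels=None) -> AgreementReport:
    """All three agreement statistics for two measurement series."""
    data = a if isinstance(a, PairedMeasurements) else PairedMeasurements(a=a, b=b, labels=labels)
    icc = icc_absolute_agreement(data, model=model)
    ba = bland_altman(data)
    mad = median_abs_diff(data)
    return AgreementReport(
        icc=icc.icc,
        icc_ci_low=icc.ci_low,
        icc_ci_high=icc.ci_high,
        bias=ba.bias,
        loa_low=ba.loa_low,
        loa_high=ba.loa_high,
        median_abs_diff=mad.median,
        mad_iqr_low=mad.iqr_low,
        mad_iqr_high=mad.iqr_high,
        model=icc.model,
        n=len(data),
    )
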