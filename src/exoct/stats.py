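"""Evaluation statistics: mask-overlap metrics and method agreement.

Two families of measures are provided:

* pixel-overlap metrics between a predicted and a true segmentation mask
  (Dice, IoU, precision, recall from the TP/FP/FN/TN counts);
* agreement between two series of paired measurements (automatic vs
  manual exophthalmometry): Lin's concordance correlation coefficient,
  the two-way absolute-agreement single-measure intraclass correlation
  ICC(A,1), Pearson's r, and Bland-Altman bias with 1.96-sd limits of
  agreement.

Conventions (documented because they change values slightly): the CCC uses
Lin's original 1/n (biased) variance estimator; Bland-Altman limits use the
sample (n-1) standard deviation of the differences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Tuple

import numpy as np

from .errors import DegenerateInputError
from .types import as_binary_mask


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class OverlapMetrics:
    dice: float
    iou: float
    precision: float
    recall: float


@dataclass(frozen=True)
class AgreementReport:
    """Paired-measurement agreement between two methods."""

    n_pairs: int
    ccc: float
    icc: float
    pearson_r: float
    bias: float
    loa_low: float
    loa_high: float
    icc_definition: str = "two-way absolute agreement, single measurement (A,1)"
    ccc_variance_convention: str = "1/n (Lin)"


def confusion_counts(pred: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    """Pixelwise TP/FP/FN/TN between two masks on the same grid."""
    p = as_binary_mask(pred)
    t = as_binary_mask(truth)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: pred {p.shape} vs truth {t.shape}")
    return ConfusionCounts(
        tp=int((p & t).sum()),
        fp=int((p & ~t).sum()),
        fn=int((~p & t).sum()),
        tn=int((~p & ~t).sum()),
    )


def _safe_ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator); returning 0", stacklevel=3)
        return 0.0
    return num / den


def overlap_metrics(pred: np.ndarray, truth: np.ndarray) -> OverlapMetrics:
    """Dice = 2TP/(FP+2TP+FN), IoU = TP/(TP+FN+FP), precision, recall.

    Zero-denominator cases return 0 with a warning so that corpus averages
    stay total.
    """
    c = confusion_counts(pred, truth)
    return OverlapMetrics(
        dice=_safe_ratio(2 * c.tp, c.fp + 2 * c.tp + c.fn, "dice"),
        iou=_safe_ratio(c.tp, c.tp + c.fn + c.fp, "iou"),
        precision=_safe_ratio(c.tp, c.tp + c.fp, "precision"),
        recall=_safe_ratio(c.tp, c.tp + c.fn, "recall"),
    )


def _paired(x, y) -> Tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=np.float64).ravel()
    y = np.asarray(y, dtype=np.float64).ravel()
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if x.size < 2:
        raise DegenerateInputError("need at least 2 paired measurements")
    return x, y


def ccc(x, y) -> float:
    """Lin's concordance correlation coefficient.

    ``2*s_xy / (s_x^2 + s_y^2 + (mean_x - mean_y)^2)`` with 1/n moment
    estimators (Lin's original convention).
    """
    x, y = _paired(x, y)
    mx, my = x.mean(), y.mean()
    sx2 = ((x - mx) ** 2).mean()
    sy2 = ((y - my) ** 2).mean()
    sxy = ((x - mx) * (y - my)).mean()
    den = sx2 + sy2 + (mx - my) ** 2
    if den == 0:
        raise DegenerateInputError("degenerate input: zero variance and equal means")
    return float(2.0 * sxy / den)


def pearson_r(x, y) -> float:
    x, y = _paired(x, y)
    sx = x.std()
    sy = y.std()
    if sx == 0 or sy == 0:
        raise DegenerateInputError("degenerate input: a series has zero variance")
    return float(((x - x.mean()) * (y - y.mean())).mean() / (sx * sy))


def icc(x, y) -> float:
    """ICC(A,1): two-way model, absolute agreement, single measurement.

    From the two-way ANOVA decomposition of the ``n x 2`` table with
    subjects as rows and the two methods as columns::

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + (k/n) (MSC - MSE)),  k = 2

    where MSR, MSC, MSE are the subject, method, and residual mean squares.
    """
    x, y = _paired(x, y)
    n, k = x.size, 2
    table = np.stack([x, y], axis=1)
    grand = table.mean()
    row_means = table.mean(axis=1)
    col_means = table.mean(axis=0)
    ssr = k * ((row_means - grand) ** 2).sum()
    ssc = n * ((col_means - grand) ** 2).sum()
    sst = ((table - grand) ** 2).sum()
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    den = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if msr <= 1e-300 and mse <= 1e-300:
        raise DegenerateInputError("degenerate input: no variance in the table")
    if den == 0:
        raise DegenerateInputError("degenerate input: zero ICC denominator")
    return float((msr - mse) / den)


def bland_altman(x, y) -> Tuple[float, float, float]:
    """Bias and 1.96-sd limits of agreement of the differences ``x - y``.

    Returns ``(bias, loa_low, loa_high)``; the sd is the sample (n-1)
    standard deviation.
    """
    x, y = _paired(x, y)
    d = x - y
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return bias, bias - 1.96 * sd, bias + 1.96 * sd


def agreement_report(x, y) -> AgreementReport:
    """All paired-agreement statistics for two measurement series."""
    x, y = _paired(x, y)
    bias, lo, hi = bland_altman(x, y)
    return AgreementReport(
        n_pairs=int(x.size),
        ccc=ccc(x, y),
        icc=icc(x, y),
        pearson_r=pearson_r(x, y),
        bias=bias,
        loa_low=lo,
        loa_high=hi,
    )


def bland_altman_figure(x, y, path, title: str = "Bland-Altman") -> None:
    """Write a minimal Bland-Altman + scatter figure to ``path``."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    x, y = _paired(x, y)
    bias, lo, hi = bland_altman(x, y)
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 4))
    mean = (x + y) / 2
    ax1.scatter(mean, x - y, s=12)
    for val, style in ((bias, "-"), (lo, "--"), (hi, "--")):
        ax1.axhline(val, linestyle=style, color="gray")
    ax1.set_xlabel("mean of methods")
    ax1.set_ylabel("difference (x - y)")
    ax1.set_title(title)
    ax2.scatter(x, y, s=12)
    lims = [min(x.min(), y.min()), max(x.max(), y.max())]
    ax2.plot(lims, lims, "--", color="gray")
    ax2.set_xlabel("method x")
    ax2.set_ylabel("method y")
    ax2.set_title("scatter")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
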