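"""Model evaluation: r-squared, RMSE, RPD, and performance classification.

Conventions (the ones that reproduce every printed summary triplet of the
emulated study):

- r^2 is the squared Pearson correlation of observed and predicted values
  (not 1 - SSE/SST);
- RPD = SD(observed split, n-1 denominator) / RMSE — the ratio of
  performance to deviation, also called relative percent deviation;
- performance classes: r^2 < 0.50 unacceptable, 0.50 <= r^2 <= 0.75
  acceptable, > 0.75 excellent; RPD < 1.40 unacceptable, 1.40 <= RPD <=
  2.00 acceptable, > 2.00 excellent (the acceptable interval is closed on
  both ends).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np

from .exceptions import DegenerateDataError, SizeError

CLASS_LABELS = ("unacceptable", "acceptable", "excellent")


@dataclass
class EvaluationReport:
    """Metrics for one split (calibration or validation)."""

    split: str
    r2: float
    rmse: float
    rpd: float
    sd_reference: float
    slope: float
    intercept: float
    performance_class: tuple[str, str]  # (r2 class, RPD class)


class DatasetSummary(NamedTuple):
    n: int
    mean: float
    max: float
    min: float
    sd: float
    cv_pct: float


def relative_percent_deviation(sd_reference: float, rmse: float) -> float:
    """RPD = SD of the observed split / RMSE; +inf for a perfect fit."""
    if rmse == 0:
        return math.inf
    return sd_reference / rmse


def cv_percent(mean: float, sd: float) -> float:
    """Coefficient of variation in percent, 100 * SD / mean."""
    return 100.0 * sd / mean


def classify_performance(r2: float, rpd: float) -> tuple[str, str]:
    """Class labels for (r^2, RPD); boundary values fall in 'acceptable'."""
    if r2 < 0.50:
        r2_class = "unacceptable"
    elif r2 <= 0.75:
        r2_class = "acceptable"
    else:
        r2_class = "excellent"
    if rpd < 1.40:
        rpd_class = "unacceptable"
    elif rpd <= 2.00:
        rpd_class = "acceptable"
    else:
        rpd_class = "excellent"
    return r2_class, rpd_class


def evaluate(
    y_obs: np.ndarray,
    y_pred: np.ndarray,
    sd_reference: float | None = None,
    split: str = "validation",
) -> EvaluationReport:
    """Score predictions against observations for one split.

    ``sd_reference`` defaults to the SD (n-1) of ``y_obs`` — the observed
    split's own dispersion, which is what RPD is defined against.
    """
    y_obs = np.asarray(y_obs, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y_obs.size != y_pred.size:
        raise SizeError("y_obs and y_pred must have equal lengths")
    if y_obs.size < 3:
        raise SizeError("evaluation needs at least 3 samples")
    if np.ptp(y_obs) == 0:
        raise DegenerateDataError("y_obs is constant; r2 and slope undefined")
    if sd_reference is None:
        sd_reference = float(np.std(y_obs, ddof=1))
    rmse = float(np.sqrt(np.mean((y_obs - y_pred) ** 2)))
    if np.ptp(y_pred) == 0:
        r2 = 0.0
    else:
        r2 = float(np.corrcoef(y_obs, y_pred)[0, 1] ** 2)
    rpd = relative_percent_deviation(sd_reference, rmse)
    slope, intercept = np.polyfit(y_obs, y_pred, 1)
    return EvaluationReport(
        split=split,
        r2=r2,
        rmse=rmse,
        rpd=rpd,
        sd_reference=float(sd_reference),
        slope=float(slope),
        intercept=float(intercept),
        performance_class=classify_performance(r2, rpd),
    )


def dataset_summary(leaf_n: np.ndarray) -> DatasetSummary:
    """n, mean, max, min, SD (n-1) and CV% of a leaf N vector."""
    leaf_n = np.asarray(leaf_n, dtype=float).ravel()
    if leaf_n.size < 2:
        raise SizeError("summary needs at least 2 samples")
    sd = float(np.std(leaf_n, ddof=1))
    mean = float(leaf_n.mean())
    return DatasetSummary(
        n=int(leaf_n.size),
        mean=mean,
        max=float(leaf_n.max()),
        min=float(leaf_n.min()),
        sd=sd,
        cv_pct=cv_percent(mean, sd),
    )


def pooled_summary(parts: Sequence[tuple[int, float, float]]) -> tuple[int, float, float]:
    """Pooled (n, mean, SD) from per-split (n, mean, SD) summaries.

    Exact pooling: the combined sum of squares is the within-split SS plus
    the between-split SS about the pooled mean, with an n-1 denominator.
    """
    n_total = sum(n for n, _, _ in parts)
    if n_total < 2:
        raise SizeError("pooled summary needs at least 2 samples in total")
    mean = sum(n * m for n, m, _ in parts) / n_total
    ss = sum((n - 1) * s**2 + n * (m - mean) ** 2 for n, m, s in parts)
    return n_total, float(mean), float(math.sqrt(ss / (n_total - 1)))
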