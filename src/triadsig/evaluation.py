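"""Metrics, trivial baselines and precision-sensitivity curves.

Five standard binary-classification measurements are reported: precision
TP/(TP+FP), sensitivity TP/(TP+FN), specificity TN/(TN+FP), accuracy
(TP+TN)/total and F-measure 2TP/(2TP+FP+FN).  On imbalanced data,
accuracy rewards predictors that favour the majority (non-interacting)
class -- an all-negative predictor scores r/(r+1) accuracy on a 1:r set
-- so the F-measure, which weighs only the positive class, is the
headline metric.

Ratios with a zero denominator are reported as NaN (an explicit
undefined marker), except the F-measure which is 0 whenever its
denominator 2TP+FP+FN is positive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

METRIC_NAMES = ("precision", "sensitivity", "specificity", "accuracy",
                "f_measure")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricPanel:
    """The five measurements, as fractions in [0, 1]; NaN marks undefined."""

    precision: float
    sensitivity: float
    specificity: float
    accuracy: float
    f_measure: float

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in METRIC_NAMES}


def confusion_counts(y_true, y_pred) -> ConfusionCounts:
    """Confusion counts from boolean label/prediction arrays."""
    y_true = np.asarray(y_true).astype(bool)
    y_pred = np.asarray(y_pred).astype(bool)
    if y_true.shape != y_pred.shape:
        raise ValueError("label and prediction lengths differ")
    return ConfusionCounts(
        tp=int(np.sum(y_true & y_pred)),
        fp=int(np.sum(~y_true & y_pred)),
        tn=int(np.sum(~y_true & ~y_pred)),
        fn=int(np.sum(y_true & ~y_pred)),
    )


def _ratio(num: int, denom: int) -> float:
    return num / denom if denom else math.nan


def compute_metrics(c: ConfusionCounts) -> MetricPanel:
    """All five measurements; undefined ratios surface as NaN, never 0."""
    if c.total == 0:
        raise ValueError("cannot compute metrics from all-zero counts")
    return MetricPanel(
        precision=_ratio(c.tp, c.tp + c.fp),
        sensitivity=_ratio(c.tp, c.tp + c.fn),
        specificity=_ratio(c.tn, c.tn + c.fp),
        accuracy=_ratio(c.tp + c.tn, c.total),
        f_measure=_ratio(2 * c.tp, 2 * c.tp + c.fp + c.fn),
    )


def f_measure(y_true, y_pred) -> float:
    """F-measure 2TP/(2TP+FP+FN) straight from label arrays."""
    c = confusion_counts(y_true, y_pred)
    return _ratio(2 * c.tp, 2 * c.tp + c.fp + c.fn)


BASELINE_KINDS = ("random", "opportunistic_neg", "opportunistic_pos")


def baseline_predict(kind: str, n_instances: int, seed: int = 0) -> np.ndarray:
    """Trivial baseline predictions.

    ``random`` flips a fair coin per instance; ``opportunistic_neg``
    always predicts non-interacting (flatters accuracy on imbalanced
    data); ``opportunistic_pos`` always predicts interacting (flatters
    sensitivity).
    """
    if n_instances < 1:
        raise ValueError("need at least one instance")
    if kind == "random":
        return np.random.default_rng(seed).random(n_instances) < 0.5
    if kind == "opportunistic_neg":
        return np.zeros(n_instances, dtype=bool)
    if kind == "opportunistic_pos":
        return np.ones(n_instances, dtype=bool)
    raise ValueError(f"unknown baseline kind {kind!r}; expected one of "
                     f"{BASELINE_KINDS}")


def pr_curve(scores, labels) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Precision-sensitivity curve by descending threshold sweep.

    One point per unique score (ties grouped at a single threshold, no
    interpolation); at each threshold t the prediction is score >= t.
    Returns (precision, sensitivity, thresholds); the final point always
    has sensitivity 1.  Requires both classes present.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be matching 1-D arrays")
    n_pos = int(labels.sum())
    if n_pos == 0 or n_pos == len(labels):
        raise ValueError("precision-sensitivity curve needs both classes")
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    y = labels[order]
    tp = np.cumsum(y)
    fp = np.cumsum(~y)
    # Last index of each tie group of equal scores.
    last = np.flatnonzero(np.r_[np.diff(s) != 0, True])
    precision = tp[last] / (tp[last] + fp[last])
    sensitivity = tp[last] / n_pos
    return precision, sensitivity, s[last]


def aggregate_repetitions(
    panels: Sequence[MetricPanel],
) -> dict[str, tuple[float, float]]:
    """Per-metric (mean, sample sd) in percent over repeated runs.

    The dispersion is the sample standard deviation (ddof=1) across
    repetitions.  Requires at least two panels.
    """
    if len(panels) < 2:
        raise ValueError("need at least two repetitions to aggregate")
    out: dict[str, tuple[float, float]] = {}
    for name in METRIC_NAMES:
        vals = np.array([getattr(p, name) for p in panels], dtype=float) * 100
        out[name] = (float(np.mean(vals)), float(np.std(vals, ddof=1)))
    return out


def format_aggregate(agg: dict[str, tuple[float, float]]) -> dict[str, str]:
    """Render mean +/- sd to one decimal in percent."""
    return {name: f"{mean:.1f} ± {sd:.1f}" for name, (mean, sd) in
            agg.items()}


def plot_pr_curve(precision, sensitivity, path) -> None:
    """Write a precision vs. sensitivity plot to ``path`` (PNG/PDF)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(sensitivity, precision, lw=1.5)
    ax.set_xlabel("Sensitivity")
    ax.set_ylabel("Precision")
    ax.set_xlim(0, 1.02)
    ax.set_ylim(0, 1.02)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
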