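"""Pixel-level evaluation: confusion counts, precision / sensitivity / F1
in percent, and the cross-validation aggregation conventions.

The fold aggregate reports the arithmetic means of the per-fold precision
and sensitivity, and an F1 that is the *harmonic mean of those two means*
rather than the mean of per-fold F1 values; this is the convention that
exactly reproduces the printed summary rows of the clinical benchmark
tables shipped with the package (see ``load_benchmark_tables``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

import numpy as np

__all__ = [
    "ConfusionCounts",
    "MetricsRecord",
    "FoldResult",
    "confusion",
    "metrics_from_counts",
    "aggregate_folds",
    "improvement",
    "load_benchmark_tables",
    "f1_from",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """Pixel-level confusion counts for one binary decision (M vs rest)."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp,
            self.fp + other.fp,
            self.tn + other.tn,
            self.fn + other.fn,
        )


@dataclass(frozen=True)
class MetricsRecord:
    """Precision, sensitivity and F1 in percent (0..100)."""

    precision: float
    sensitivity: float
    f1: float

    def rounded(self, ndigits: int = 2) -> "MetricsRecord":
        return MetricsRecord(
            round(self.precision, ndigits),
            round(self.sensitivity, ndigits),
            round(self.f1, ndigits),
        )

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.precision, self.sensitivity, self.f1)


@dataclass(frozen=True)
class FoldResult:
    """Metrics of one cross-validation fold."""

    fold_id: int
    metrics: MetricsRecord
    counts: ConfusionCounts | None = None


def confusion(
    pred_classes: np.ndarray,
    truth_classes: np.ndarray,
    positive_class: int = 2,
) -> ConfusionCounts:
    """Count pixels treating ``positive_class`` as positive, all else negative."""
    pred = np.asarray(pred_classes)
    truth = np.asarray(truth_classes)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    pp = pred == positive_class
    tp_ = truth == positive_class
    tp = int(np.count_nonzero(pp & tp_))
    fp = int(np.count_nonzero(pp & ~tp_))
    fn = int(np.count_nonzero(~pp & tp_))
    tn = int(np.count_nonzero(~pp & ~tp_))
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def f1_from(precision: float, sensitivity: float) -> float:
    """Harmonic mean of precision and sensitivity (percent scale); 0 when
    both are 0."""
    if precision + sensitivity == 0:
        return 0.0
    return 2.0 * precision * sensitivity / (precision + sensitivity)


def metrics_from_counts(c: ConfusionCounts) -> MetricsRecord:
    """Precision = TP/(TP+FP), sensitivity = TP/(TP+FN), F1 = their harmonic
    mean, all in percent.  Degenerate 0/0 ratios are defined as 0."""
    precision = 100.0 * c.tp / (c.tp + c.fp) if (c.tp + c.fp) else 0.0
    sensitivity = 100.0 * c.tp / (c.tp + c.fn) if (c.tp + c.fn) else 0.0
    return MetricsRecord(
        precision=precision,
        sensitivity=sensitivity,
        f1=f1_from(precision, sensitivity),
    )


def aggregate_folds(folds: list) -> MetricsRecord:
    """Aggregate per-fold metrics the way the benchmark summary rows do:
    mean precision, mean sensitivity, and F1 as the harmonic mean of those
    two means.

    Accepts ``FoldResult``, ``MetricsRecord`` or ``(p, s, f1)`` items.
    """
    if not folds:
        raise ValueError("no folds to aggregate")
    recs = []
    for f in folds:
        if isinstance(f, FoldResult):
            recs.append(f.metrics)
        elif isinstance(f, MetricsRecord):
            recs.append(f)
        else:
            p, s = f[0], f[1]
            recs.append(MetricsRecord(p, s, f1_from(p, s)))
    mp = float(np.mean([r.precision for r in recs]))
    ms = float(np.mean([r.sensitivity for r in recs]))
    return MetricsRecord(precision=mp, sensitivity=ms, f1=f1_from(mp, ms))


def improvement(a: MetricsRecord, b: MetricsRecord, ndigits: int = 2):
    """Componentwise ``a - b``, rounded for reporting."""
    return MetricsRecord(
        precision=round(a.precision - b.precision, ndigits),
        sensitivity=round(a.sensitivity - b.sensitivity, ndigits),
        f1=round(a.f1 - b.f1, ndigits),
    )


def load_benchmark_tables() -> dict:
    """Reference per-fold metrics from a published clinical benchmark of
    this pipeline (packaged data).  Keys: ``protocols`` (per-fold
    [precision, sensitivity, f1] rows per protocol and loss),
    ``printed_means``, ``single_image_examples``, ``reported_improvements``."""
    with resources.files("scintiseg.data").joinpath("benchmark_tables.json").open() as fh:
        return json.load(fh)
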