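"""Confusion-matrix summary and the three report metrics.

Accuracy A_c = (TP+TN)/(TP+FP+FN+TN), sensitivity S_n = TP/(TP+FN) and
specificity S_p = TN/(TN+FP), with the positive class always named
explicitly.  Ratios with an empty denominator raise
:class:`~evosvm.exceptions.UndefinedMetricError` rather than silently
reporting 0 — at cohort sizes of a few dozen subjects a silent zero is a
corrupted report.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .exceptions import InvalidInputError, UndefinedMetricError

__all__ = [
    "ConfusionCounts",
    "MetricReport",
    "confusion",
    "accuracy",
    "sensitivity",
    "specificity",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """The 2x2 tally: true/false positives and negatives."""

    TP: int
    FP: int
    FN: int
    TN: int

    def __post_init__(self) -> None:
        for name in ("TP", "FP", "FN", "TN"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise InvalidInputError(f"{name} must be a non-negative integer, got {v!r}")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.FN + self.TN


def confusion(
    y_true: Sequence[int], y_pred: Sequence[int], positive: int = 1
) -> ConfusionCounts:
    """Tally the confusion counts with an explicit positive class."""
    yt = np.asarray(y_true)
    yp = np.asarray(y_pred)
    if yt.shape != yp.shape or yt.ndim != 1 or yt.size < 1:
        raise InvalidInputError(
            f"need two equal-length label vectors, got shapes {yt.shape} and {yp.shape}"
        )
    if positive not in (1, -1):
        raise InvalidInputError(f"positive label must be +1 or -1, got {positive!r}")
    for name, arr in (("true", yt), ("predicted", yp)):
        bad = set(np.unique(arr)) - {-1, 1}
        if bad:
            raise InvalidInputError(f"unknown {name} label(s): {sorted(bad)}")
    pos_t = yt == positive
    pos_p = yp == positive
    return ConfusionCounts(
        TP=int(np.sum(pos_t & pos_p)),
        FP=int(np.sum(~pos_t & pos_p)),
        FN=int(np.sum(pos_t & ~pos_p)),
        TN=int(np.sum(~pos_t & ~pos_p)),
    )


def accuracy(c: ConfusionCounts) -> float:
    """Fraction of correctly identified samples."""
    if c.total == 0:
        raise UndefinedMetricError("accuracy undefined: no evaluated samples")
    return (c.TP + c.TN) / c.total


def sensitivity(c: ConfusionCounts) -> float:
    """Fraction of actual positives correctly identified (true-positive rate)."""
    if c.TP + c.FN == 0:
        raise UndefinedMetricError(
            "sensitivity undefined: no actual positive samples"
        )
    return c.TP / (c.TP + c.FN)


def specificity(c: ConfusionCounts) -> float:
    """Fraction of actual negatives correctly identified (true-negative rate)."""
    if c.TN + c.FP == 0:
        raise UndefinedMetricError(
            "specificity undefined: no actual negative samples"
        )
    return c.TN / (c.TN + c.FP)


@dataclass(frozen=True)
class MetricReport:
    """Accuracy/sensitivity/specificity bundle with its counts and class names.

    A metric whose denominator is empty is carried as ``None`` and printed
    as "n/a"; it is never coerced to 0.
    """

    counts: ConfusionCounts
    positive_name: str = "+1"
    negative_name: str = "-1"

    @classmethod
    def from_labels(
        cls,
        y_true: Sequence[int],
        y_pred: Sequence[int],
        positive: int = 1,
        positive_name: str | None = None,
        negative_name: str | None = None,
    ) -> "MetricReport":
        c = confusion(y_true, y_pred, positive=positive)
        return cls(
            counts=c,
            positive_name=positive_name or f"{positive:+d}",
            negative_name=negative_name or f"{-positive:+d}",
        )

    @property
    def accuracy(self) -> float:
        return accuracy(self.counts)

    @property
    def sensitivity(self) -> float | None:
        try:
            return sensitivity(self.counts)
        except UndefinedMetricError:
            return None

    @property
    def specificity(self) -> float | None:
        try:
            return specificity(self.counts)
        except UndefinedMetricError:
            return None

    def to_dict(self) -> dict:
        c = self.counts
        return {
            "positive_class": self.positive_name,
            "negative_class": self.negative_name,
            "counts": {"TP": c.TP, "FP": c.FP, "FN": c.FN, "TN": c.TN},
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    def __str__(self) -> str:
        def pct(v: float | None) -> str:
            return "n/a" if v is None else f"{100 * v:.2f}%"

        c = self.counts
        lines = [
            f"positive class: {self.positive_name}   "
            f"negative class: {self.negative_name}",
            f"TP={c.TP}  FP={c.FP}  FN={c.FN}  TN={c.TN}  (n={c.total})",
            f"accuracy:    {pct(self.accuracy)}",
            f"sensitivity: {pct(self.sensitivity)}",
            f"specificity: {pct(self.specificity)}",
        ]
        return "\n".join(lines)
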