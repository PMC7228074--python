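"""Classification calls and performance metrics.

A prediction y_hat below zero calls LGG, above zero HGG (exactly zero is
called HGG — a measure-zero convention that avoids missing the clinically
costlier class).  HGG is the positive class throughout: sensitivity is the
fraction of HGGs called HGG, specificity the fraction of LGGs called LGG.

The mean absolute error is *clipped*: an LGG predicted below −10 or an HGG
above +10 already exceeds its class ideal, so its error counts as zero —
only shortfalls toward the decision boundary contribute.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .models import LinearModel, predict_table

POSITIVE_GRADE = "HGG"  # positive class
NEGATIVE_GRADE = "LGG"
IDEAL = 10.0


def classify(y_hat: float) -> str:
    """Grade call for one prediction (y_hat >= 0 -> HGG, < 0 -> LGG)."""
    if not math.isfinite(y_hat):
        raise ValueError(f"non-finite prediction {y_hat!r}")
    return NEGATIVE_GRADE if y_hat < 0 else POSITIVE_GRADE


def clipped_error(y_hat: float, grade: str) -> float:
    """Absolute error against the class ideal, clamped at over-shoot.

    LGG ideal is −10 (predictions below clamp to −10); HGG ideal is +10
    (predictions above clamp to +10).
    """
    if grade == NEGATIVE_GRADE:
        return abs(max(y_hat, -IDEAL) - (-IDEAL))
    if grade == POSITIVE_GRADE:
        return abs(min(y_hat, IDEAL) - IDEAL)
    raise ValueError(f"unknown grade {grade!r}")


@dataclass(frozen=True)
class EvaluationReport:
    """Confusion counts, percent metrics and the clipped MAE."""

    tp: int
    tn: int
    fp: int
    fn: int
    mae: float
    predictions: pd.DataFrame  # id-indexed: grade, y_hat, call

    @property
    def sensitivity(self) -> float:
        if self.tp + self.fn == 0:
            return float("nan")
        return round(100.0 * self.tp / (self.tp + self.fn), 2)

    @property
    def specificity(self) -> float:
        if self.tn + self.fp == 0:
            return float("nan")
        return round(100.0 * self.tn / (self.tn + self.fp), 2)

    @property
    def accuracy(self) -> float:
        total = self.tp + self.tn + self.fp + self.fn
        if total == 0:
            return float("nan")
        return round(100.0 * (self.tp + self.tn) / total, 2)

    def to_dict(self) -> dict:
        return {
            "tp": self.tp, "tn": self.tn, "fp": self.fp, "fn": self.fn,
            "sensitivity": self.sensitivity, "specificity": self.specificity,
            "accuracy": self.accuracy, "mae": self.mae,
        }


def evaluate_predictions(predictions: pd.Series, grades: pd.Series) -> EvaluationReport:
    """Score predictions against true grades (HGG positive)."""
    if predictions.empty:
        raise ValueError("nothing to evaluate")
    frame = pd.DataFrame({"grade": grades.loc[predictions.index], "y_hat": predictions})
    frame["call"] = frame["y_hat"].map(classify)

    tp = int(((frame["grade"] == POSITIVE_GRADE) & (frame["call"] == POSITIVE_GRADE)).sum())
    fn = int(((frame["grade"] == POSITIVE_GRADE) & (frame["call"] == NEGATIVE_GRADE)).sum())
    tn = int(((frame["grade"] == NEGATIVE_GRADE) & (frame["call"] == NEGATIVE_GRADE)).sum())
    fp = int(((frame["grade"] == NEGATIVE_GRADE) & (frame["call"] == POSITIVE_GRADE)).sum())

    mae = float(
        sum(clipped_error(y, g) for y, g in zip(frame["y_hat"], frame["grade"])) / len(frame)
    )
    return EvaluationReport(tp=tp, tn=tn, fp=fp, fn=fn, mae=mae, predictions=frame)


def evaluate(model: LinearModel, features_df: pd.DataFrame) -> EvaluationReport:
    """Apply a model to an id-indexed feature table (with ``grade``) and score it."""
    return evaluate_predictions(predict_table(model, features_df), features_df["grade"])
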