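"""Evaluation metrics: confusion counts, Sen/Spe/Acc/MCC, ROC/AUC.

The four headline metrics are expressed in the class-total form common in
the site-prediction literature: with N⁺/N⁻ the class sizes, N⁺₋ the false
negatives and N⁻₊ the false positives,

    Sen = 1 − N⁺₋/N⁺
    Spe = 1 − N⁻₊/N⁻
    Acc = 1 − (N⁺₋+N⁻₊)/(N⁺+N⁻)
    MCC = (1 − (N⁺₋/N⁺ + N⁻₊/N⁻)) /
          sqrt((1 + (N⁻₊−N⁺₋)/N⁺)(1 + (N⁺₋−N⁻₊)/N⁻))

which is algebraically identical to the textbook TP/TN/FP/FN Matthews
correlation coefficient (a property the test suite checks exhaustively).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.metrics import roc_auc_score, roc_curve

from pseui.errors import ValidationError


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary confusion table in class-total form.

    ``fn`` (N⁺₋) is the number of positives predicted negative; ``fp``
    (N⁻₊) is the number of negatives predicted positive.
    """

    n_plus: int
    n_minus: int
    fn: int
    fp: int

    def __post_init__(self) -> None:
        if self.n_plus < 1 or self.n_minus < 1:
            raise ValidationError(
                f"both classes must be nonempty (N+={self.n_plus}, N-={self.n_minus})"
            )
        if not 0 <= self.fn <= self.n_plus:
            raise ValidationError(f"FN={self.fn} outside [0, {self.n_plus}]")
        if not 0 <= self.fp <= self.n_minus:
            raise ValidationError(f"FP={self.fp} outside [0, {self.n_minus}]")

    @classmethod
    def from_predictions(
        cls, labels: Sequence[bool] | np.ndarray, predicted: Sequence[bool] | np.ndarray
    ) -> "ConfusionCounts":
        y = np.asarray(labels, dtype=bool)
        p = np.asarray(predicted, dtype=bool)
        if y.shape != p.shape:
            raise ValidationError("labels and predictions differ in length")
        return cls(
            n_plus=int(y.sum()),
            n_minus=int((~y).sum()),
            fn=int((y & ~p).sum()),
            fp=int((~y & p).sum()),
        )


@dataclass(frozen=True)
class MetricSet:
    """Sen/Spe/Acc in [0,1], MCC in [−1,1], optional AUC.

    ``mcc_degenerate`` flags an MCC reported as 0 because its denominator
    vanished (all-positive or all-negative predictions).
    """

    sen: float
    spe: float
    acc: float
    mcc: float
    auc: float | None = None
    mcc_degenerate: bool = False

    def as_dict(self) -> dict[str, float]:
        d = {
            "Sen": round(self.sen, 4),
            "Spe": round(self.spe, 4),
            "Acc": round(self.acc, 4),
            "MCC": round(self.mcc, 4),
        }
        if self.auc is not None:
            d["AUC"] = round(self.auc, 4)
        return d


def chou_metrics(counts: ConfusionCounts, auc: float | None = None) -> MetricSet:
    """Sen/Spe/Acc/MCC from class-total confusion counts.

    When the MCC denominator vanishes (the predictor assigned every sample
    to one class) MCC is reported as 0 with ``mcc_degenerate=True``.
    """
    np_, nm = counts.n_plus, counts.n_minus
    fn, fp = counts.fn, counts.fp
    sen = 1.0 - fn / np_
    spe = 1.0 - fp / nm
    acc = 1.0 - (fn + fp) / (np_ + nm)
    denom_sq = (1.0 + (fp - fn) / np_) * (1.0 + (fn - fp) / nm)
    degenerate = denom_sq <= 0 or math.isclose(denom_sq, 0.0, abs_tol=1e-15)
    if degenerate:
        mcc = 0.0
    else:
        mcc = (1.0 - (fn / np_ + fp / nm)) / math.sqrt(denom_sq)
    return MetricSet(sen=sen, spe=spe, acc=acc, mcc=mcc, auc=auc,
                     mcc_degenerate=degenerate)


def roc_auc(
    labels: Sequence[bool] | np.ndarray, scores: Sequence[float] | np.ndarray
) -> tuple[float, np.ndarray]:
    """AUC and empirical ROC curve from real-valued decision scores.

    Returns ``(auc, curve)`` where ``curve`` is an (n_points, 2) array of
    (FPR, TPR) pairs. The AUC equals the Mann–Whitney statistic
    P(score⁺ > score⁻) + ½·P(tie), and is invariant under strictly
    monotone transforms of the scores.
    """
    y = np.asarray(labels, dtype=bool)
    s = np.asarray(scores, dtype=float)
    if y.shape != s.shape:
        raise ValidationError("labels and scores differ in length")
    if y.all() or (~y).all():
        raise ValidationError("ROC requires both classes present")
    if not np.isfinite(s).all():
        raise ValidationError("scores must be finite")
    auc = float(roc_auc_score(y, s))
    fpr, tpr, _ = roc_curve(y, s)
    return auc, np.column_stack([fpr, tpr])
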