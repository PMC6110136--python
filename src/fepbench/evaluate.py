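"""Truth tables, classification metrics and quantitative error metrics.

Censoring bookkeeping: an experimentally censored record (assay saturated,
so ΔΔG is a lower bound) is *included* in classification — it is resistant
by construction — but *excluded* from MUE/RMSE, whose arithmetic needs a
point value. Predictions are never censored; predictors return point values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

from .records import PredictionRecord
from .transform import RESISTANT, ClassificationThreshold, classify, cutoff_from_fold


@dataclass(frozen=True)
class TruthTable:
    """2x2 counts of predicted vs experimental resistance calls.

    Rows are the experimental class: tp/fn count truly resistant mutations
    (predicted resistant/susceptible), fp/tn truly susceptible ones.
    """

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("truth-table counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    def __add__(self, other: "TruthTable") -> "TruthTable":
        return TruthTable(
            self.tp + other.tp, self.fn + other.fn,
            self.fp + other.fp, self.tn + other.tn,
        )


def accuracy(table: TruthTable) -> float:
    """(tp + tn) / total."""
    if table.total == 0:
        raise ValueError("empty truth table")
    return (table.tp + table.tn) / table.total


def sensitivity(table: TruthTable) -> float | None:
    """tp / (tp + fn); None when there are no truly resistant records."""
    denom = table.tp + table.fn
    return table.tp / denom if denom else None


def specificity(table: TruthTable) -> float | None:
    """tn / (fp + tn); None when there are no truly susceptible records."""
    denom = table.fp + table.tn
    return table.tn / denom if denom else None


def _require_method(records: Sequence[PredictionRecord], method: str) -> None:
    missing = [r.key for r in records if method not in r.predictions]
    if missing:
        raise KeyError(f"method {method!r} missing on records: {missing}")


def build_truth_table(
    records: Sequence[PredictionRecord],
    method: str,
    threshold: ClassificationThreshold,
) -> TruthTable:
    """Cross-tabulate experimental vs predicted resistance calls.

    Experimentally censored records are included (classified resistant).
    """
    _require_method(records, method)
    tp = fn = fp = tn = 0
    for rec in records:
        exp_res = classify(rec.experimental, threshold) == RESISTANT
        pred_res = classify(rec.predictions[method], threshold) == RESISTANT
        if exp_res:
            tp += pred_res
            fn += not pred_res
        else:
            fp += pred_res
            tn += not pred_res
    return TruthTable(tp, fn, fp, tn)


def quantitative_records(
    records: Sequence[PredictionRecord], method: str
) -> list[PredictionRecord]:
    """The subset usable for MUE/RMSE: non-censored, with the method present."""
    _require_method(records, method)
    return [r for r in records if not r.experimental.censored]


def mue(records: Sequence[PredictionRecord], method: str) -> float:
    """Mean unsigned error of predictions vs experiment (kcal/mol)."""
    usable = quantitative_records(records, method)
    if not usable:
        raise ValueError("no non-censored records for quantitative metrics")
    return sum(
        abs(r.predictions[method].value - r.experimental.value) for r in usable
    ) / len(usable)


def rmse(records: Sequence[PredictionRecord], method: str) -> float:
    """Root-mean-square error of predictions vs experiment (kcal/mol)."""
    usable = quantitative_records(records, method)
    if not usable:
        raise ValueError("no non-censored records for quantitative metrics")
    return math.sqrt(
        sum(
            (r.predictions[method].value - r.experimental.value) ** 2 for r in usable
        ) / len(usable)
    )


def classification_metrics(table: TruthTable) -> dict[str, float | None]:
    return {
        "accuracy": accuracy(table),
        "sensitivity": sensitivity(table),
        "specificity": specificity(table),
    }


def threshold_sweep(
    records: Sequence[PredictionRecord],
    method: str,
    folds: Sequence[float],
    constants=None,
) -> Mapping[float, tuple[TruthTable, dict[str, float | None]]]:
    """Re-evaluate classification at several fold-change cutoffs.

    Both the experimental and the predicted class are re-thresholded at each
    fold, mirroring how a stricter resistance definition is applied to data
    and predictions alike.
    """
    if any(f <= 1 for f in folds):
        raise ValueError("folds must all exceed 1")
    out: dict[float, tuple[TruthTable, dict[str, float | None]]] = {}
    for fold in folds:
        threshold = cutoff_from_fold(fold, constants)
        table = build_truth_table(records, method, threshold)
        out[fold] = (table, classification_metrics(table))
    return out
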