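"""ROC curves by stepped cutoff sweep, the naive model, and consensus.

The ROC is built exactly the way the benchmark defines it: experimental
labels are fixed at the resistance threshold (1.36 kcal/mol for 10-fold),
then the *prediction* cutoff is swept from the minimum to the maximum
predicted ΔΔG in 0.001 kcal/mol steps, a point (FPR, TPR) recorded at each
cutoff, corner anchors (0,0)/(1,1) appended, and the area computed by the
trapezoidal rule. The anchoring makes the constant predictor score exactly
0.50.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .exceptions import DegenerateLabelsError
from .records import DeltaDeltaG, PredictionRecord, Provenance
from .transform import RESISTANT, ClassificationThreshold, classify


@dataclass(frozen=True)
class RocCurve:
    """Cutoffs, (FPR, TPR) points sorted by FPR, and trapezoidal AUC."""

    cutoffs: np.ndarray
    points: np.ndarray  # shape (k, 2): columns FPR, TPR
    auc: float


@dataclass(frozen=True)
class ScaleFit:
    """Least-squares-through-origin rescaling of a predictor."""

    method: str
    slope: float
    rmse: float  # RMSE of slope*pred vs experiment, on non-censored records


def roc_curve(
    records: Sequence[PredictionRecord],
    method: str,
    experimental_threshold: ClassificationThreshold,
    step: float = 0.001,
) -> RocCurve:
    """Stepped-cutoff ROC curve for one method.

    Predicted-resistant means prediction > cutoff (strict, matching the
    classification rule); censored experimental records count as resistant.
    """
    if step <= 0:
        raise ValueError(f"step must be positive, got {step}")
    labels = np.array(
        [classify(r.experimental, experimental_threshold) == RESISTANT
         for r in records]
    )
    preds = np.array([r.predictions[method].value for r in records])
    n_pos = int(labels.sum())
    n_neg = int(labels.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise DegenerateLabelsError(
            "ROC needs both experimental classes; got "
            f"{n_pos} resistant / {n_neg} susceptible"
        )
    lo, hi = float(preds.min()), float(preds.max())
    n_steps = int(round((hi - lo) / step))
    cutoffs = lo + step * np.arange(n_steps + 1)
    # counts of predictions strictly above each cutoff, via sorted search
    pos_sorted = np.sort(preds[labels])
    neg_sorted = np.sort(preds[~labels])
    tp = n_pos - np.searchsorted(pos_sorted, cutoffs, side="right")
    fp = n_neg - np.searchsorted(neg_sorted, cutoffs, side="right")
    tpr = tp / n_pos
    fpr = fp / n_neg
    points = np.column_stack([fpr, tpr])
    points = np.vstack([points, [0.0, 0.0], [1.0, 1.0]])
    order = np.lexsort((points[:, 1], points[:, 0]))
    points = points[order]
    auc = float(np.trapezoid(points[:, 1], points[:, 0]))
    return RocCurve(cutoffs=cutoffs, points=points, auc=auc)


def naive_predictions(records: Sequence[PredictionRecord]) -> list[DeltaDeltaG]:
    """The naive model: every mutation predicted at 0.00 kcal/mol exactly."""
    return [
        DeltaDeltaG(0.0, 0.0, False, Provenance.NAIVE) for _ in records
    ]


def add_method(
    records: Sequence[PredictionRecord],
    name: str,
    predictions: Sequence[DeltaDeltaG],
) -> list[PredictionRecord]:
    """Attach a derived prediction set to records under a new method name."""
    if len(records) != len(predictions):
        raise ValueError("records and predictions differ in length")
    return [r.with_prediction(name, p) for r, p in zip(records, predictions)]


def fit_scale(records: Sequence[PredictionRecord], method: str) -> ScaleFit:
    """Slope minimizing RMSE(s·pred, exp) over non-censored records.

    Only the slope is optimized, so the least-squares solution is
    s* = Σ(pred·exp)/Σ(pred²) — regression through the origin.
    """
    usable = [r for r in records if not r.experimental.censored]
    if len(usable) < 2:
        raise ValueError("need at least 2 non-censored records to fit a slope")
    pred = np.array([r.predictions[method].value for r in usable])
    exp = np.array([r.experimental.value for r in usable])
    denom = float(np.sum(pred**2))
    if denom == 0.0:
        raise ValueError(f"all {method!r} predictions are zero; slope undefined")
    slope = float(np.sum(pred * exp) / denom)
    rmse = float(np.sqrt(np.mean((slope * pred - exp) ** 2)))
    return ScaleFit(method, slope, rmse)


def consensus(
    records: Sequence[PredictionRecord],
    method_a: str,
    method_b: str,
    per_record_weights: bool = False,
) -> list[DeltaDeltaG]:
    """Inverse-variance weighted average of two rescaled predictors.

    Each method is first slope-rescaled against experiment; its minimized
    RMSE then serves as the (global) standard deviation in the
    inverse-variance weights, so the weights are identical across records.
    With ``per_record_weights=True`` the per-record sigmas of the scaled
    predictions are used instead (records with zero sigma on both methods
    fall back to the global weights).
    """
    fit_a = fit_scale(records, method_a)
    fit_b = fit_scale(records, method_b)
    if fit_a.rmse == 0.0 and fit_b.rmse == 0.0:
        warnings.warn(
            "both methods have zero scaled RMSE; falling back to the "
            "unweighted mean",
            RuntimeWarning,
            stacklevel=2,
        )
        wa = wb = 0.5
    else:
        # a zero-RMSE method gets all the weight via a guarded large precision
        pa = 1.0 / fit_a.rmse**2 if fit_a.rmse > 0 else np.inf
        pb = 1.0 / fit_b.rmse**2 if fit_b.rmse > 0 else np.inf
        if np.isinf(pa) or np.isinf(pb):
            wa = 1.0 if np.isinf(pa) else 0.0
            wb = 1.0 - wa
        else:
            wa, wb = pa / (pa + pb), pb / (pa + pb)
    out: list[DeltaDeltaG] = []
    for rec in records:
        a = fit_a.slope * rec.predictions[method_a].value
        b = fit_b.slope * rec.predictions[method_b].value
        if per_record_weights:
            sa = fit_a.slope * rec.predictions[method_a].sigma
            sb = fit_b.slope * rec.predictions[method_b].sigma
            if sa > 0 or sb > 0:
                qa = 1.0 / sa**2 if sa > 0 else np.inf
                qb = 1.0 / sb**2 if sb > 0 else np.inf
                if np.isinf(qa) or np.isinf(qb):
                    ra = 1.0 if np.isinf(qa) else 0.0
                    rb = 1.0 - ra
                else:
                    ra, rb = qa / (qa + qb), qb / (qa + qb)
                value = ra * a + rb * b
                sigma = (1.0 / (qa + qb)) ** 0.5 if not (np.isinf(qa) or np.isinf(qb)) else 0.0
                out.append(DeltaDeltaG(value, sigma, False, Provenance.CONSENSUS))
                continue
        out.append(DeltaDeltaG(wa * a + wb * b, 0.0, False, Provenance.CONSENSUS))
    return out
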