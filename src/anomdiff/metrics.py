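"""Scoring of task predictions: headline metrics and the changepoint
detection analysis.

Headline metrics: MAE for exponent inference (T1/T3), micro-averaged F1
for model classification (T2/T3), RMSE for changepoint localization (T3)
and MRR to combine T3 ranks.  Additional diagnostics: exponent bias,
column-normalized confusion matrices, one-vs-rest ROC/AUC, and the
epsilon-margin TP/TN/FP/FN scheme with recall, false-positive rate,
Jaccard similarity and RMSE over true-positive pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn import metrics as _skm
from sklearn.preprocessing import label_binarize

from .models import MODELS, InvalidParameterError, Model

__all__ = [
    "mae",
    "exponent_bias",
    "micro_f1",
    "confusion_matrix",
    "roc_auc",
    "AucReport",
    "rmse_changepoint",
    "dummy_changepoint",
    "mrr",
    "changepoint_detection_stats",
    "ChangepointOutcome",
    "argmax_labels",
    "score_task1",
    "score_task2",
    "score_task3",
]

_N_MODELS = len(MODELS)


def _check_lengths(a, b) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise InvalidParameterError(f"length mismatch: {a.shape} vs {b.shape}")
    if a.size == 0:
        raise InvalidParameterError("empty input")
    return a, b


def mae(alpha_pred, alpha_true) -> float:
    """Mean absolute error of the anomalous-exponent predictions."""
    p, t = _check_lengths(alpha_pred, alpha_true)
    return float(np.mean(np.abs(p - t)))


def exponent_bias(alpha_pred, alpha_true) -> float:
    """Signed mean error theta; negative means systematic underestimation."""
    p, t = _check_lengths(alpha_pred, alpha_true)
    return float(np.mean(p - t))


def _as_indices(labels) -> np.ndarray:
    out = np.array(
        [l.value if isinstance(l, Model) else int(l) for l in labels], dtype=int
    )
    if out.size == 0:
        raise InvalidParameterError("empty input")
    if np.any((out < 0) | (out >= _N_MODELS)):
        raise InvalidParameterError("labels must index the 5-model alphabet")
    return out


def argmax_labels(probabilities) -> np.ndarray:
    """Hard labels from probability rows; ties broken by the fixed model order."""
    probs = np.atleast_2d(np.asarray(probabilities, dtype=float))
    return np.argmax(probs, axis=1)  # first maximum = lowest model index


def micro_f1(pred_labels, true_labels) -> float:
    """Micro-averaged F1 = 2TP / (2TP + FP + FN) pooled over the 5 classes.

    For complete single-label predictions this equals the overall accuracy.
    """
    p = _as_indices(pred_labels)
    t = _as_indices(true_labels)
    if p.shape != t.shape:
        raise InvalidParameterError("length mismatch")
    return float(_skm.f1_score(t, p, average="micro"))


def confusion_matrix(pred_labels, true_labels) -> np.ndarray:
    """Column-normalized confusion matrix in percent.

    Entry (i, j) is the percentage of ground-truth class-j trajectories
    predicted as class i, so every column with support sums to 100; columns
    of absent ground-truth classes are NaN.
    """
    p = _as_indices(pred_labels)
    t = _as_indices(true_labels)
    counts = _skm.confusion_matrix(t, p, labels=np.arange(_N_MODELS)).T.astype(float)
    support = counts.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = 100.0 * counts / support
    out[:, support == 0] = np.nan
    return out


@dataclass
class AucReport:
    """One-vs-rest areas under the ROC curve."""

    per_class: dict[Model, float] = field(default_factory=dict)
    micro: float = float("nan")
    macro: float = float("nan")


def roc_auc(probabilities, true_labels) -> AucReport:
    """Per-class one-vs-rest, micro (pooled) and macro (class-mean) AUC.

    Rows with non-negative mass are renormalized to sum to 1; classes absent
    from the ground truth get NaN and are excluded from the macro average.
    """
    probs = np.atleast_2d(np.asarray(probabilities, dtype=float))
    if probs.shape[1] != _N_MODELS:
        raise InvalidParameterError(f"need {_N_MODELS} probability columns")
    if np.any(probs < 0):
        raise InvalidParameterError("negative probabilities")
    row_sums = probs.sum(axis=1, keepdims=True)
    if np.any(row_sums == 0):
        raise InvalidParameterError("all-zero probability row")
    probs = probs / row_sums
    t = _as_indices(true_labels)
    binary = label_binarize(t, classes=np.arange(_N_MODELS))
    report = AucReport()
    per = []
    for m in MODELS:
        col = binary[:, m.value]
        if col.min() == col.max():
            report.per_class[m] = float("nan")
            continue
        auc = float(_skm.roc_auc_score(col, probs[:, m.value]))
        report.per_class[m] = auc
        per.append(auc)
    if per:
        report.macro = float(np.mean(per))
    if binary.ravel().min() != binary.ravel().max():
        report.micro = float(_skm.roc_auc_score(binary.ravel(), probs.ravel()))
    return report


def dummy_changepoint(t: float, length: int = 200) -> float:
    """Dummy index for a trajectory without an internal changepoint.

    The nearer of {1, L-1} to the reported position (the benchmark uses
    index 1 or 199 for L = 200).
    """
    return 1.0 if abs(t - 1) <= abs(t - (length - 1)) else float(length - 1)


def rmse_changepoint(t_pred, t_true) -> float:
    """Root mean squared changepoint localization error."""
    p, t = _check_lengths(t_pred, t_true)
    return float(np.sqrt(np.mean((p - t) ** 2)))


def mrr(rank_mae: int, rank_f1: int, rank_rmse: int) -> float:
    """Mean reciprocal rank combining the three task-3 rankings."""
    ranks = (rank_mae, rank_f1, rank_rmse)
    if any((not float(r).is_integer()) or r < 1 for r in ranks):
        raise InvalidParameterError("ranks must be integers >= 1")
    return float(np.mean([1.0 / r for r in ranks]))


@dataclass
class ChangepointOutcome:
    """epsilon-margin classification of changepoint predictions.

    A position within ``epsilon`` of either end counts as "no changepoint";
    the four cases compare where prediction and ground truth fall.  recall,
    FPR and JSC follow from the counts; ``rmse_tp`` is the localization
    RMSE over true-positive pairs only.  Ratios with empty denominators are
    ``None`` (not applicable).
    """

    tp: int
    tn: int
    fp: int
    fn: int
    epsilon: float
    rmse_tp: float | None

    @property
    def recall(self) -> float | None:
        d = self.tp + self.fn
        return self.tp / d if d else None

    @property
    def fpr(self) -> float | None:
        d = self.fp + self.tn
        return self.fp / d if d else None

    @property
    def jsc(self) -> float | None:
        d = self.tp + self.fp + self.fn
        return self.tp / d if d else None


def changepoint_detection_stats(
    t_pred, t_true, length: int = 200, epsilon: float = 20
) -> ChangepointOutcome:
    """Classify prediction/truth pairs by the epsilon-margin internal window.

    A position t is internal when epsilon < t < L - epsilon.  TP: both
    internal; TN: neither; FP: only the prediction; FN: only the truth.
    """
    if not (0 < epsilon < length / 2):
        raise InvalidParameterError("epsilon must lie in (0, L/2)")
    p, t = _check_lengths(t_pred, t_true)
    p_in = (p > epsilon) & (p < length - epsilon)
    t_in = (t > epsilon) & (t < length - epsilon)
    tp_mask = p_in & t_in
    tp = int(np.sum(tp_mask))
    tn = int(np.sum(~p_in & ~t_in))
    fp = int(np.sum(p_in & ~t_in))
    fn = int(np.sum(~p_in & t_in))
    rmse_tp = (
        float(np.sqrt(np.mean((p[tp_mask] - t[tp_mask]) ** 2))) if tp else None
    )
    return ChangepointOutcome(tp, tn, fp, fn, epsilon, rmse_tp)


# ---------------------------------------------------------------------------
# task-level scoring


def score_task1(alpha_pred, alpha_true) -> dict:
    """T1 report: MAE (headline metric) and the exponent bias."""
    return {
        "mae": mae(alpha_pred, alpha_true),
        "bias": exponent_bias(alpha_pred, alpha_true),
        "n": int(np.asarray(alpha_pred).size),
    }


def score_task2(probabilities, true_labels) -> dict:
    """T2 report: micro-F1 on the argmax labels, AUCs and the confusion matrix."""
    pred = argmax_labels(probabilities)
    auc = roc_auc(probabilities, true_labels)
    return {
        "f1": micro_f1(pred, true_labels),
        "auc_micro": auc.micro,
        "auc_macro": auc.macro,
        "auc_per_class": {m.name: v for m, v in auc.per_class.items()},
        "confusion_matrix": confusion_matrix(pred, true_labels).tolist(),
        "n": int(len(pred)),
    }


def score_task3(predictions, truths, length: int = 200, epsilon: float = 20) -> dict:
    """T3 report: changepoint RMSE, segment-averaged MAE and F1, detection stats.

    ``predictions``/``truths`` are sequences of records with fields
    (changepoint, alpha_1, model_1, alpha_2, model_2); segments are paired
    by position (first with first, second with second), each segment scored
    as an individual trajectory and the two segment scores averaged.
    """
    if len(predictions) != len(truths):
        raise InvalidParameterError("length mismatch")
    if not predictions:
        raise InvalidParameterError("empty input")

    def fields(rec, name):
        return np.array([getattr(r, name) for r in rec])

    t_p = fields(predictions, "changepoint").astype(float)
    t_t = fields(truths, "changepoint").astype(float)
    seg_mae = float(
        np.mean(
            [
                mae(fields(predictions, f"alpha_{k}"), fields(truths, f"alpha_{k}"))
                for k in (1, 2)
            ]
        )
    )
    seg_f1 = float(
        np.mean(
            [
                micro_f1(fields(predictions, f"model_{k}"), fields(truths, f"model_{k}"))
                for k in (1, 2)
            ]
        )
    )
    det = changepoint_detection_stats(t_p, t_t, length=length, epsilon=epsilon)
    return {
        "rmse": rmse_changepoint(t_p, t_t),
        "mae": seg_mae,
        "f1": seg_f1,
        "tp": det.tp,
        "tn": det.tn,
        "fp": det.fp,
        "fn": det.fn,
        "recall": det.recall,
        "fpr": det.fpr,
        "jsc": det.jsc,
        "rmse_tp": det.rmse_tp,
        "n": int(len(predictions)),
    }
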