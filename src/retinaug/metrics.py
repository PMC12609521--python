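"""Evaluation framework for imbalanced multi-class segmentation.

Lesion pixels occupy under 5% of a fundus image, so no single number
characterizes a segmentation.  Seven metrics are computed per class in
one-vs-rest fashion from a multi-class confusion matrix: accuracy,
IoU (Jaccard), precision, recall, F1, AUC-ROC and AUC-PR.  The two AUCs
use explicit trapezoid sums over the distinct observed score thresholds:

    AUC-ROC = Σ_i (FPR_i − FPR_{i−1}) (TPR_i + TPR_{i−1}) / 2
    AUC-PR  = Σ_i (r_i − r_{i−1}) (P_i + P_{i−1}) / 2

with ROC points ordered by increasing FPR from (0,0) to (1,1), and the PR
curve's left endpoint extending the precision at the highest threshold
horizontally to recall 0.  AUC-ROC is retained for comparability but can be
misleadingly high under heavy class imbalance; AUC-PR is the informative
one for rare lesions.

Macro means over the four lesion classes (MA, HE, EX, CWS) are reported
separately from all-class means — the lesion mean is the headline figure
for diabetic-retinopathy segmentation.  Uncertainty comes from a seeded
percentile bootstrap over per-image metric values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .labels import LESION_NAMES, ClassSchema, LabelMap
from .losses import ScoreMap

__all__ = [
    "ConfusionMatrix",
    "CurvePoints",
    "MetricReport",
    "confusion_matrix",
    "basic_metrics",
    "roc_auc",
    "pr_auc",
    "bootstrap_ci",
    "evaluate",
]

BASIC_METRIC_NAMES = ("accuracy", "iou", "precision", "recall", "f1")


@dataclass
class ConfusionMatrix:
    """C×C pixel counts; rows index ground truth, columns prediction."""

    counts: np.ndarray
    schema: ClassSchema

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        C = self.schema.n_classes
        if self.counts.shape != (C, C):
            raise ValueError(f"counts must be {C}×{C} for schema {self.schema.name!r}")
        if (self.counts < 0).any():
            raise ValueError("counts must be nonnegative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def one_vs_rest(self, class_id: int) -> tuple[int, int, int, int]:
        """(TP, FP, FN, TN) for one class against all others."""
        tp = int(self.counts[class_id, class_id])
        fp = int(self.counts[:, class_id].sum()) - tp
        fn = int(self.counts[class_id, :].sum()) - tp
        tn = self.total - tp - fp - fn
        return tp, fp, fn, tn


@dataclass
class CurvePoints:
    """An ROC or PR curve sampled at the distinct score thresholds."""

    thresholds: np.ndarray  # descending
    x: np.ndarray           # FPR (ROC) or recall (PR)
    y: np.ndarray           # TPR (ROC) or precision (PR)


@dataclass
class MetricReport:
    """Per-class and macro-averaged metrics, with optional bootstrap CIs."""

    schema: ClassSchema
    per_class: dict[str, dict[str, float]]
    lesion_mean: dict[str, float]
    all_class_mean: dict[str, float]
    degenerate: dict[str, list[str]] = field(default_factory=dict)
    intervals: dict[str, tuple[float, float]] | None = None

    def to_dict(self) -> dict:
        out = {
            "schema": self.schema.name,
            "per_class": self.per_class,
            "lesion_mean": self.lesion_mean,
            "all_class_mean": self.all_class_mean,
            "degenerate": self.degenerate,
        }
        if self.intervals is not None:
            out["intervals"] = {k: list(v) for k, v in self.intervals.items()}
        return out


def confusion_matrix(pred: LabelMap, truth: LabelMap) -> ConfusionMatrix:
    """Count pixels by (truth id, predicted id)."""
    if pred.schema.classes != truth.schema.classes:
        raise ValueError("prediction and truth use different schemas")
    if pred.shape != truth.shape:
        raise ValueError("prediction and truth shapes disagree")
    C = truth.schema.n_classes
    idx = truth.grid.ravel() * C + pred.grid.ravel()
    counts = np.bincount(idx, minlength=C * C).reshape(C, C)
    return ConfusionMatrix(counts, truth.schema)


def _safe_div(num: float, den: float) -> tuple[float, bool]:
    """0/0 → (0.0, flagged); otherwise the quotient."""
    if den == 0:
        return 0.0, True
    return num / den, False


def basic_metrics(cm: ConfusionMatrix) -> tuple[dict[str, dict[str, float]], dict[str, list[str]]]:
    """Accuracy, IoU, precision, recall and F1 per class (one-vs-rest).

    Undefined 0/0 ratios are reported as 0 and flagged in the second return
    value (class name → list of degenerate metric names) — silent NaNs are
    never emitted.
    """
    per_class: dict[str, dict[str, float]] = {}
    degenerate: dict[str, list[str]] = {}
    for cid, cname in enumerate(cm.schema.classes):
        tp, fp, fn, tn = cm.one_vs_rest(cid)
        flags: list[str] = []
        acc, d = _safe_div(tp + tn, tp + tn + fp + fn)
        if d:
            flags.append("accuracy")
        iou, d = _safe_div(tp, tp + fp + fn)
        if d:
            flags.append("iou")
        prec, d = _safe_div(tp, tp + fp)
        if d:
            flags.append("precision")
        rec, d = _safe_div(tp, tp + fn)
        if d:
            flags.append("recall")
        f1, d = _safe_div(2 * prec * rec, prec + rec)
        if d:
            flags.append("f1")
        per_class[cname] = {
            "accuracy": acc, "iou": iou, "precision": prec, "recall": rec, "f1": f1
        }
        if flags:
            degenerate[cname] = flags
    return per_class, degenerate


def _binary_counts(scores: np.ndarray, truth: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Cumulative TP/FP at each distinct threshold, descending."""
    scores = np.asarray(scores, dtype=np.float64).ravel()
    truth = np.asarray(truth).astype(bool).ravel()
    if scores.shape != truth.shape:
        raise ValueError("scores and truth shapes disagree")
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    t = truth[order]
    # collapse ties: keep the last index of each distinct score value
    distinct = np.flatnonzero(np.diff(s) != 0)
    last = np.concatenate([distinct, [s.size - 1]])
    tp = np.cumsum(t)[last].astype(np.float64)
    fp = np.cumsum(~t)[last].astype(np.float64)
    return s[last], tp, fp


def roc_auc(scores: np.ndarray, truth: np.ndarray) -> tuple[CurvePoints, float]:
    """ROC curve over the distinct thresholds and its trapezoid area.

    Requires at least one positive and one negative pixel; a single-class
    ground truth leaves the AUC undefined and raises ``ValueError``.
    """
    truth_arr = np.asarray(truth).astype(bool).ravel()
    P = int(truth_arr.sum())
    N = truth_arr.size - P
    if P == 0 or N == 0:
        raise ValueError("AUC-ROC undefined: ground truth contains a single class")
    thr, tp, fp = _binary_counts(scores, truth_arr)
    tpr = np.concatenate([[0.0], tp / P])
    fpr = np.concatenate([[0.0], fp / N])
    thresholds = np.concatenate([[np.inf], thr])
    auc = float(np.sum(np.diff(fpr) * (tpr[1:] + tpr[:-1]) / 2.0))
    return CurvePoints(thresholds, fpr, tpr), auc


def pr_auc(scores: np.ndarray, truth: np.ndarray) -> tuple[CurvePoints, float]:
    """Precision–recall curve and its trapezoid area.

    Recall ascends as the threshold descends.  The left endpoint extends
    the precision at the highest threshold horizontally to recall 0, fixing
    the first trapezoid.  Requires at least one positive pixel.
    """
    truth_arr = np.asarray(truth).astype(bool).ravel()
    P = int(truth_arr.sum())
    if P == 0:
        raise ValueError("AUC-PR undefined: no positive pixels in ground truth")
    thr, tp, fp = _binary_counts(scores, truth_arr)
    recall = tp / P
    precision = tp / (tp + fp)
    # left endpoint: horizontal extension to recall 0
    recall = np.concatenate([[0.0], recall])
    precision = np.concatenate([[precision[0]], precision])
    thresholds = np.concatenate([[np.inf], thr])
    auc = float(np.sum(np.diff(recall) * (precision[1:] + precision[:-1]) / 2.0))
    return CurvePoints(thresholds, recall, precision), auc


def bootstrap_ci(
    per_image_values: list[float] | np.ndarray,
    n_boot: int = 10_000,
    level: float = 0.95,
    seed: int | np.random.Generator = 0,
) -> tuple[float, float]:
    """Seeded percentile bootstrap interval for the mean of per-image values."""
    values = np.asarray(per_image_values, dtype=np.float64)
    if values.size < 2:
        raise ValueError("bootstrap needs at least 2 values")
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx = rng.integers(0, values.size, size=(n_boot, values.size))
    means = values[idx].mean(axis=1)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(means, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def evaluate(pred_scores: ScoreMap, truth: LabelMap) -> MetricReport:
    """Full seven-metric report for one scored prediction.

    Hard metrics come from the argmax label map; the AUCs from the
    per-class score planes one-vs-rest, pooled over this image's pixels.
    Macro means over the four lesion classes are reported separately from
    the all-class means.  AUCs for classes absent from the ground truth
    are reported as 0 and flagged degenerate.
    """
    if pred_scores.n_classes != truth.schema.n_classes:
        raise ValueError("score channels do not match schema class count")
    if pred_scores.tensor.shape[:2] != truth.shape:
        raise ValueError("score and truth shapes disagree")

    pred_labels = pred_scores.argmax_labels(truth.schema)
    cm = confusion_matrix(pred_labels, truth)
    per_class, degenerate = basic_metrics(cm)

    for cid, cname in enumerate(truth.schema.classes):
        mask = truth.grid == cid
        plane = pred_scores.tensor[:, :, cid]
        try:
            _, auc_roc = roc_auc(plane, mask)
        except ValueError:
            auc_roc = 0.0
            degenerate.setdefault(cname, []).append("auc_roc")
        try:
            _, auc_pr = pr_auc(plane, mask)
        except ValueError:
            auc_pr = 0.0
            degenerate.setdefault(cname, []).append("auc_pr")
        per_class[cname]["auc_roc"] = auc_roc
        per_class[cname]["auc_pr"] = auc_pr

    metric_names = BASIC_METRIC_NAMES + ("auc_roc", "auc_pr")
    lesions = [c for c in LESION_NAMES if c in truth.schema.classes]
    lesion_mean = {
        m: float(np.mean([per_class[c][m] for c in lesions])) if lesions else 0.0
        for m in metric_names
    }
    all_mean = {
        m: float(np.mean([per_class[c][m] for c in truth.schema.classes]))
        for m in metric_names
    }
    return MetricReport(
        schema=truth.schema,
        per_class=per_class,
        lesion_mean=lesion_mean,
        all_class_mean=all_mean,
        degenerate=degenerate,
    )
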