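"""Two-stage loss framework for imbalanced lesion segmentation.

Lesion pixels typically make up well under 5% of a fundus image, so
training proceeds in two stages: first a (optionally class-weighted)
cross-entropy stage that maximizes per-pixel likelihood and captures all
lesions at the cost of false positives, then a generalized Tversky-loss
stage that optimizes region overlap and re-weights the false-positive /
false-negative trade-off through its α and β parameters.

The Tversky index for class c over M pixels,

    TI_c = Σ Y_c T_c / (Σ Y_c T_c + α Σ Y_c (1−T_c) + β Σ (1−Y_c) T_c),

reduces to the Dice coefficient at α = β = 0.5 and to the Jaccard index at
α = β = 1.  The loss is L = Σ_c (1 − TI_c).  The soft formulation (real-
valued probabilities Y) is used here, as required for gradient training;
hard 0/1 masks are a special case and are what evaluation reports use.

Only pure loss/schedule functions live here — the segmentation network
itself is a pluggable external component.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .labels import LabelMap

__all__ = [
    "ScoreMap",
    "ClassWeights",
    "TverskyParams",
    "TwoStageConfig",
    "weighted_cross_entropy",
    "tversky_index",
    "tversky_loss",
    "compute_class_weights",
    "select_stage_loss",
]

_LOG_EPS = 1e-12
_SIMPLEX_TOL = 1e-6


@dataclass
class ScoreMap:
    """H×W×C per-pixel class scores, optionally on the probability simplex."""

    tensor: np.ndarray
    simplex: bool = True

    def __post_init__(self) -> None:
        self.tensor = np.asarray(self.tensor, dtype=np.float64)
        if self.tensor.ndim != 3:
            raise ValueError("score tensor must be H×W×C")
        if (self.tensor < 0).any() or (self.tensor > 1 + _SIMPLEX_TOL).any():
            raise ValueError("scores must lie in [0, 1]")
        if self.simplex:
            sums = self.tensor.sum(axis=2)
            if not np.allclose(sums, 1.0, atol=_SIMPLEX_TOL):
                raise ValueError("simplex scores must sum to 1 per pixel")

    @property
    def n_classes(self) -> int:
        return self.tensor.shape[2]

    def argmax_labels(self, schema) -> LabelMap:
        return LabelMap(np.argmax(self.tensor, axis=2).astype(np.int64), schema)


@dataclass(frozen=True)
class ClassWeights:
    """Per-class nonnegative weights for the cross-entropy stage."""

    w: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.w, dtype=np.float64)
        if w.ndim != 1 or (w < 0).any() or not (w > 0).any():
            raise ValueError("weights must be a 1-D nonnegative vector, not all zero")
        object.__setattr__(self, "w", w)


@dataclass(frozen=True)
class TverskyParams:
    """False-positive weight α, false-negative weight β, smoothing constant."""

    alpha: float = 0.7
    beta: float = 0.3
    smooth: float = 1e-6

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be >= 0")
        if self.smooth <= 0:
            raise ValueError("smooth must be > 0")


@dataclass(frozen=True)
class TwoStageConfig:
    """Schedule and optimizer defaults for two-stage training."""

    stage1_epochs: int = 300
    stage2_epochs: int = 100
    learning_rate: float = 0.001
    momentum: float = 0.90
    batch_size: int = 6

    def __post_init__(self) -> None:
        if self.stage1_epochs <= 0 or self.stage2_epochs <= 0:
            raise ValueError("epoch counts must be positive")


def _check_shapes(pred: ScoreMap, target: np.ndarray) -> np.ndarray:
    target = np.asarray(target, dtype=np.float64)
    if target.shape != pred.tensor.shape:
        raise ValueError(
            f"target shape {target.shape} does not match scores {pred.tensor.shape}"
        )
    return target


def weighted_cross_entropy(
    pred: ScoreMap, target: np.ndarray, weights: ClassWeights | None = None
) -> float:
    """Class-weighted negative log-likelihood, averaged over all pixels.

    ``loss = −(1/N) Σ_pixels Σ_classes w_i · t_i · ln y_i`` with predictions
    clamped to [1e-12, 1] before the log.  Nonnegative; zero exactly when
    the prediction is the one-hot target.
    """
    if not pred.simplex:
        raise ValueError("cross-entropy requires simplex (softmax) scores")
    target = _check_shapes(pred, target)
    C = pred.n_classes
    w = weights.w if weights is not None else np.ones(C)
    if w.shape != (C,):
        raise ValueError(f"weights length {w.shape[0]} != {C} classes")
    logp = np.log(np.clip(pred.tensor, _LOG_EPS, 1.0))
    n_pix = pred.tensor.shape[0] * pred.tensor.shape[1]
    return float(-(w[None, None, :] * target * logp).sum() / n_pix)


def tversky_index(pred: ScoreMap, target: np.ndarray, params: TverskyParams) -> np.ndarray:
    """Per-class soft Tversky index TI_c ∈ (0, 1].

    Smoothing keeps the index defined (= 1) for classes absent from both
    prediction and ground truth, which is routine for rare lesions in
    per-image batches.
    """
    target = _check_shapes(pred, target)
    Y = pred.tensor
    T = target
    tp = (Y * T).sum(axis=(0, 1))
    fp = (Y * (1.0 - T)).sum(axis=(0, 1))
    fn = ((1.0 - Y) * T).sum(axis=(0, 1))
    s = params.smooth
    return (tp + s) / (tp + params.alpha * fp + params.beta * fn + s)


def tversky_loss(pred: ScoreMap, target: np.ndarray, params: TverskyParams) -> float:
    """Overall loss L = Σ_c (1 − TI_c); range [0, C)."""
    return float((1.0 - tversky_index(pred, target, params)).sum())


def compute_class_weights(
    labelmaps: list[LabelMap], scheme: str = "inverse_frequency"
) -> ClassWeights:
    """Derive per-class weights from observed label frequencies.

    ``uniform`` → all ones; ``inverse_frequency`` → w_i ∝ 1/freq_i
    normalized to mean 1; ``median_frequency`` → w_i = median(freq)/freq_i.
    Inverse schemes reject unobserved classes rather than emitting
    infinities.
    """
    if not labelmaps:
        raise ValueError("labelmaps list is empty")
    C = labelmaps[0].schema.n_classes
    counts = np.zeros(C, dtype=np.float64)
    for lm in labelmaps:
        if lm.schema.n_classes != C:
            raise ValueError("all label maps must share one schema")
        counts += np.bincount(lm.grid.ravel(), minlength=C)
    freq = counts / counts.sum()

    if scheme == "uniform":
        return ClassWeights(np.ones(C))
    if scheme not in ("inverse_frequency", "median_frequency"):
        raise ValueError(f"unknown weighting scheme {scheme!r}")
    if (freq == 0).any():
        missing = np.flatnonzero(freq == 0).tolist()
        raise ValueError(
            f"classes {missing} unobserved; use scheme='uniform' or supply "
            "maps covering every class"
        )
    if scheme == "inverse_frequency":
        w = 1.0 / freq
        return ClassWeights(w / w.mean())
    return ClassWeights(np.median(freq) / freq)


def select_stage_loss(config: TwoStageConfig, epoch: int) -> str:
    """Which loss applies at a (0-based) epoch of the two-stage schedule."""
    if epoch < 0:
        raise ValueError("epoch must be >= 0")
    if epoch < config.stage1_epochs:
        return "cross_entropy"
    if epoch < config.stage1_epochs + config.stage2_epochs:
        return "tversky"
    raise ValueError(
        f"epoch {epoch} beyond schedule end "
        f"({config.stage1_epochs + config.stage2_epochs} epochs total)"
    )
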