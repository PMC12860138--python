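"""Losses and evaluation metrics for the segmentation model.

The training objective combines the soft Dice loss

    L_Dice = 1 − (2 Σ p·g + ε) / (Σ p + Σ g + ε)

with a class-weighted cross-entropy whose weights default to the inverse
class frequency of the batch.  The generalized Dice score (GDS) weights each
class by w_c = 1/(Σ g_c)², so rare classes carry proportional influence.

`soft_dice_loss`, `weighted_cross_entropy` and `total_loss` accept either
plain numpy arrays (evaluation) or autodiff tensors (training); everything
else is numpy-only.  Probability maps are channel-last (H×W×C or N×H×W×C);
per-pixel probabilities sum to one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats

from ._autodiff import Tensor

__all__ = [
    "LossConfig",
    "MetricsReport",
    "TTestResult",
    "soft_dice_loss",
    "dice_coefficient",
    "generalized_dice",
    "weighted_cross_entropy",
    "total_loss",
    "segmentation_metrics",
    "boundary_dice",
    "aggregate_runs",
    "paired_t_test",
]

_CLIP = 1e-7  # probability clipping bound inside the cross-entropy


@dataclass
class LossConfig:
    epsilon: float = 1e-6
    class_weights: np.ndarray | None = None  # None -> inverse frequency per batch
    dice_weight: float = 1.0
    ce_weight: float = 1.0

    def __post_init__(self):
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")
        if self.class_weights is not None:
            w = np.asarray(self.class_weights, dtype=float)
            if np.any(w < 0) or not np.any(w > 0):
                raise ValueError("need nonnegative weights with at least one positive")
            self.class_weights = w


def _is_tensor(x) -> bool:
    return isinstance(x, Tensor)


def _sum(x, axis=None):
    return x.sum(axis=axis) if _is_tensor(x) else np.sum(x, axis=axis)


def _check_shapes(p, g):
    if tuple(p.shape) != tuple(np.shape(g)):
        raise ValueError(f"shape mismatch: {tuple(p.shape)} vs {np.shape(g)}")


# ---------------------------------------------------------------------------
# Losses
# ---------------------------------------------------------------------------

def soft_dice_loss(p, g, epsilon: float = 1e-6):
    """1 − smoothed Dice overlap; differentiable in p."""
    _check_shapes(p, g)
    g = np.asarray(g, dtype=float)
    numerator = 2.0 * _sum(p * g) + epsilon
    denominator = _sum(p) + float(g.sum()) + epsilon
    return 1.0 - numerator / denominator


def dice_coefficient(p, g, epsilon: float = 1e-6) -> float:
    """Smoothed (soft) Dice overlap of a probability map and a binary mask."""
    g = np.asarray(g, dtype=float)
    p = np.asarray(p.data if _is_tensor(p) else p, dtype=float)
    return float((2.0 * (p * g).sum() + epsilon) / (p.sum() + g.sum() + epsilon))


def generalized_dice(
    probs: np.ndarray, g_onehot: np.ndarray, weights: np.ndarray | None = None
) -> float:
    """Class-weighted Dice with default w_c = 1/(Σ g_c)²; empty classes are
    excluded (their default weight would be infinite and their overlap zero)."""
    probs = np.asarray(probs, dtype=float)
    g_onehot = np.asarray(g_onehot, dtype=float)
    _check_shapes(probs, g_onehot)
    n_classes = probs.shape[-1]
    flat_p = probs.reshape(-1, n_classes)
    flat_g = g_onehot.reshape(-1, n_classes)
    support = flat_g.sum(axis=0)
    present = support > 0
    if not present.any():
        raise ValueError("all classes empty in ground truth")
    if weights is None:
        weights = np.zeros(n_classes)
        weights[present] = 1.0 / support[present] ** 2
    else:
        weights = np.asarray(weights, dtype=float) * present
    intersect = (flat_p * flat_g).sum(axis=0)
    total = flat_p.sum(axis=0) + support
    return float(2.0 * (weights * intersect).sum() / (weights * total).sum())


def _one_hot(labels: np.ndarray, n_classes: int) -> np.ndarray:
    return np.eye(n_classes)[labels]


def inverse_frequency_weights(labels: np.ndarray, n_classes: int) -> np.ndarray:
    """Class weights proportional to inverse class frequency, normalized to
    mean 1 over the classes present."""
    counts = np.bincount(np.asarray(labels).ravel(), minlength=n_classes).astype(float)
    weights = np.zeros(n_classes)
    present = counts > 0
    weights[present] = counts[present].sum() / (counts[present] * present.sum())
    return weights


def weighted_cross_entropy(p, g: np.ndarray, class_weights: np.ndarray | None = None):
    """Mean over pixels of −w_{g(x)} · log p_{g(x)}(x); p is channel-last."""
    g = np.asarray(g)
    n_classes = p.shape[-1]
    if class_weights is None:
        class_weights = inverse_frequency_weights(g, n_classes)
    class_weights = np.asarray(class_weights, dtype=float)
    onehot = _one_hot(g, n_classes)
    wmap = class_weights[g]
    if _is_tensor(p):
        logp = p.clip(_CLIP, 1.0 - _CLIP).log()
        return -((logp * onehot).sum(axis=-1) * wmap).mean()
    logp = np.log(np.clip(p, _CLIP, 1.0 - _CLIP))
    return -float((((logp * onehot).sum(axis=-1)) * wmap).mean())


def total_loss(p, g: np.ndarray, config: LossConfig | None = None):
    """dice_weight · soft-Dice (foreground channel) + ce_weight · weighted CE.

    For more than two classes the Dice term is the mean of the per-class
    soft Dice losses over the non-background classes.
    """
    config = config or LossConfig()
    g = np.asarray(g)
    n_classes = p.shape[-1]
    dice_terms = []
    for cls in range(1, n_classes):
        p_c = p[..., cls] if not _is_tensor(p) else _channel(p, cls)
        dice_terms.append(soft_dice_loss(p_c, (g == cls).astype(float), config.epsilon))
    dice = dice_terms[0] if len(dice_terms) == 1 else sum(dice_terms) * (1.0 / len(dice_terms))
    ce = weighted_cross_entropy(p, g, config.class_weights)
    return config.dice_weight * dice + config.ce_weight * ce


def _channel(p: Tensor, cls: int) -> Tensor:
    """Select one trailing-axis channel of a tensor via a one-hot contraction."""
    onehot = np.zeros(p.shape[-1])
    onehot[cls] = 1.0
    return (p * onehot).sum(axis=-1)


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

@dataclass
class MetricsReport:
    dice: float
    iou: float
    accuracy: float
    precision: float
    recall: float
    f1: float
    auc: float  # nan when probabilities were not supplied
    boundary_dice: float
    confusion: np.ndarray = field(repr=False, default=None)

    def to_dict(self) -> dict:
        out = {
            k: float(getattr(self, k))
            for k in ("dice", "iou", "accuracy", "precision", "recall", "f1", "auc", "boundary_dice")
        }
        if self.confusion is not None:
            out["confusion"] = self.confusion.tolist()
        return out


def _binary_counts(pred: np.ndarray, truth: np.ndarray, cls: int):
    tp = int(np.sum((pred == cls) & (truth == cls)))
    fp = int(np.sum((pred == cls) & (truth != cls)))
    fn = int(np.sum((pred != cls) & (truth == cls)))
    return tp, fp, fn


def segmentation_metrics(pred, truth, probs: np.ndarray | None = None) -> MetricsReport:
    """Pixel-level metrics.  Binary tasks use the malignant-positive
    convention (class 1); multiclass tasks report macro averages.  AUC is the
    pixel-level ROC area from `probs` and is nan when probs are absent."""
    pred_arr = np.asarray(getattr(pred, "labels", pred))
    truth_arr = np.asarray(getattr(truth, "labels", truth))
    if pred_arr.shape != truth_arr.shape:
        raise ValueError("prediction and truth dimensions differ")
    n_classes = int(max(pred_arr.max(initial=0), truth_arr.max(initial=0))) + 1
    n_classes = max(n_classes, 2)
    if probs is not None:
        n_classes = max(n_classes, probs.shape[-1])

    confusion = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(confusion, (truth_arr.ravel(), pred_arr.ravel()), 1)
    accuracy = float(np.trace(confusion) / confusion.sum())

    classes = [1] if n_classes == 2 else list(range(n_classes))
    precisions, recalls, f1s, dices, ious = [], [], [], [], []
    for cls in classes:
        tp, fp, fn = _binary_counts(pred_arr, truth_arr, cls)
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
        dice = 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else 1.0
        iou = tp / (tp + fp + fn) if tp + fp + fn else 1.0
        precisions.append(prec)
        recalls.append(rec)
        f1s.append(f1)
        dices.append(dice)
        ious.append(iou)

    auc = float("nan")
    if probs is not None:
        from sklearn.metrics import roc_auc_score

        flat = probs.reshape(-1, probs.shape[-1])
        y = truth_arr.ravel()
        try:
            if n_classes == 2:
                auc = float(roc_auc_score(y, flat[:, 1]))
            else:
                auc = float(roc_auc_score(y, flat, multi_class="ovr", average="macro"))
        except ValueError:  # a single class present: ROC undefined
            auc = float("nan")

    bdice = boundary_dice((pred_arr > 0).astype(np.uint8), (truth_arr > 0).astype(np.uint8))
    return MetricsReport(
        dice=float(np.mean(dices)),
        iou=float(np.mean(ious)),
        accuracy=accuracy,
        precision=float(np.mean(precisions)),
        recall=float(np.mean(recalls)),
        f1=float(np.mean(f1s)),
        auc=auc,
        boundary_dice=bdice,
        confusion=confusion,
    )


def boundary_dice(pred: np.ndarray, truth: np.ndarray, tolerance: int = 2) -> float:
    """Surface Dice of two binary masks: the fraction of boundary pixels of
    each mask lying within `tolerance` pixels of the other mask's boundary
    (morphological gradient bands).  A contour shifted by no more than the
    tolerance scores 1.  Both masks empty → 1; exactly one empty → 0."""
    pred = np.asarray(getattr(pred, "labels", pred)).astype(bool)
    truth = np.asarray(getattr(truth, "labels", truth)).astype(bool)
    if pred.shape != truth.shape:
        raise ValueError("mask dimensions differ")
    if pred.ndim == 3:  # a stack of masks: average the per-image values
        return float(
            np.mean([boundary_dice(p, t, tolerance) for p, t in zip(pred, truth)])
        )
    if not pred.any() and not truth.any():
        return 1.0
    if not pred.any() or not truth.any():
        return 0.0
    struct = np.ones((3, 3), dtype=bool)

    def gradient(mask):
        return ndimage.binary_dilation(mask, struct) ^ ndimage.binary_erosion(mask, struct)

    def widen(band):
        if tolerance > 0:
            return ndimage.binary_dilation(band, struct, iterations=tolerance)
        return band

    bp, bt = gradient(pred), gradient(truth)
    denom = bp.sum() + bt.sum()
    if denom == 0:
        return 1.0
    agree = np.sum(bp & widen(bt)) + np.sum(bt & widen(bp))
    return float(agree / denom)


# ---------------------------------------------------------------------------
# Statistical aggregation
# ---------------------------------------------------------------------------

@dataclass
class TTestResult:
    t: float
    p: float
    degenerate: bool = False


def aggregate_runs(per_run: list[dict], confidence: float = 0.95) -> dict:
    """Mean, sd (ddof=1) and Student-t confidence interval per metric."""
    if len(per_run) < 1:
        raise ValueError("need at least one run")
    keys = [k for k in per_run[0] if isinstance(per_run[0][k], (int, float))]
    out = {}
    n = len(per_run)
    for k in keys:
        vals = np.array([r[k] for r in per_run], dtype=float)
        mean = float(np.nanmean(vals))
        sd = float(np.nanstd(vals, ddof=1)) if n > 1 else 0.0
        if n > 1 and sd > 0:
            half = float(stats.t.ppf(0.5 + confidence / 2, n - 1) * sd / np.sqrt(n))
        else:
            half = 0.0
        out[k] = {"mean": mean, "sd": sd, "ci_low": mean - half, "ci_high": mean + half, "n": n}
    return out


def paired_t_test(metrics_a, metrics_b) -> TTestResult:
    """Two-tailed paired t-test.  Identical samples report (t=0, p=1);
    a zero-variance nonzero difference is flagged degenerate with p=0."""
    a = np.asarray(metrics_a, dtype=float)
    b = np.asarray(metrics_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("unequal run counts for paired test")
    if a.size < 2:
        raise ValueError("need at least two paired runs")
    d = a - b
    if np.allclose(d.std(ddof=1), 0.0):
        if np.allclose(d, 0.0):
            return TTestResult(t=0.0, p=1.0, degenerate=True)
        return TTestResult(t=float(np.sign(d.mean()) * np.inf), p=0.0, degenerate=True)
    res = stats.ttest_rel(a, b)
    return TTestResult(t=float(res.statistic), p=float(res.pvalue), degenerate=False)
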