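"""Training loop, cross-validation and cross-dataset evaluation.

The protocol: SGD with momentum 0.9, learning rate 0.001 and weight decay
1e-4 as the primary optimizer; when the validation Dice plateaus for
`switch_patience` epochs the optimizer permanently switches to Adam
(lr 1e-4, β₁ = 0.9, β₂ = 0.999).  Mini-batches of 16 are class-balanced
(minority class resampled with replacement each epoch), augmentation is
applied on the fly, the objective is soft Dice + class-weighted
cross-entropy, and training early-stops when the validation Dice has not
improved for `patience` epochs, returning the parameters of the best
validation epoch.  Runs are bit-reproducible for a fixed seed on one CPU
thread.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import losses, network, preprocessing
from ._autodiff import Adam, SGD, Tensor
from .imaging_io import (
    LabelMap,
    ManifestRecord,
    RgbImage,
    kfold_split,
    read_image,
    read_mask,
)
from .losses import LossConfig, MetricsReport, aggregate_runs, segmentation_metrics
from .preprocessing import (
    AugmentConfig,
    ClaheParams,
    StainMatrix,
    augment_pair,
    preprocess_for_model,
    resize_nearest,
)

__all__ = [
    "TrainConfig",
    "TrainHistory",
    "balanced_batches",
    "train",
    "train_classifier",
    "evaluate",
    "cross_validate",
    "evaluate_cross_dataset",
]


@dataclass
class TrainConfig:
    input_size: int = 224
    sgd_lr: float = 0.001
    momentum: float = 0.9
    adam_lr: float = 1e-4
    beta1: float = 0.9
    beta2: float = 0.999
    weight_decay: float = 1e-4
    batch_size: int = 16
    max_epochs: int = 100
    patience: int = 10
    switch_patience: int = 5
    dropout: float = 0.3
    seeds: tuple[int, ...] = (0, 1, 2, 3, 4)
    width_multiplier: float = 1.0
    num_classes: int = 2
    augment: AugmentConfig = field(default_factory=AugmentConfig)
    stains: StainMatrix = field(default_factory=StainMatrix)
    clahe: ClaheParams = field(default_factory=ClaheParams)

    def __post_init__(self):
        if min(self.sgd_lr, self.adam_lr, self.weight_decay) < 0:
            raise ValueError("rates must be ≥ 0")
        if self.patience < 1:
            raise ValueError("patience must be ≥ 1")


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    val_dice: list[float] = field(default_factory=list)
    optimizer_phase: list[str] = field(default_factory=list)
    best_epoch: int = 0
    stopping_reason: str = ""

    @property
    def best_val_dice(self) -> float:
        return max(self.val_dice) if self.val_dice else float("nan")


def _derived_seed(*parts: int) -> int:
    h = 0
    for p in parts:
        h = (h * 1000003 + int(p)) % (2**31 - 1)
    return h


def balanced_batches(
    records: list[ManifestRecord], batch_size: int, seed: int
) -> list[list[int]]:
    """Class-balanced batch indices: ⌈B/2⌉ of the majority class and ⌊B/2⌋
    of the minority per batch, the minority resampled with replacement."""
    classes = sorted({r.class_label for r in records})
    if len(classes) == 1:
        # single-class data degenerates to plain shuffled batching
        rng = np.random.default_rng(seed)
        order = rng.permutation(len(records))
        return [list(order[i : i + batch_size]) for i in range(0, len(order), batch_size)]
    if len(classes) != 2:
        raise ValueError("balanced batching expects one or two classes")
    idx_by_class = {c: [i for i, r in enumerate(records) if r.class_label == c] for c in classes}
    if any(len(v) == 0 for v in idx_by_class.values()):
        raise ValueError("a class has zero records")
    rng = np.random.default_rng(seed)
    major, minor = sorted(classes, key=lambda c: -len(idx_by_class[c]))
    n_major = math.ceil(batch_size / 2)
    n_minor = batch_size // 2
    n_batches = math.ceil(len(idx_by_class[major]) / n_major)

    def drawn(pool: list[int], total: int) -> np.ndarray:
        base = rng.permutation(pool)
        if total <= len(base):
            return base[:total]
        extra = rng.choice(pool, size=total - len(base), replace=True)
        return np.concatenate([base, extra])

    major_seq = drawn(idx_by_class[major], n_batches * n_major)
    minor_seq = drawn(idx_by_class[minor], n_batches * n_minor)
    batches = []
    for b in range(n_batches):
        batch = np.concatenate(
            [major_seq[b * n_major : (b + 1) * n_major], minor_seq[b * n_minor : (b + 1) * n_minor]]
        )
        batches.append(list(rng.permutation(batch)))
    return batches


# ---------------------------------------------------------------------------
# Sample loading and preparation
# ---------------------------------------------------------------------------

def _load_pair(record: ManifestRecord) -> tuple[RgbImage, LabelMap]:
    image = read_image(record.image_path)
    if record.mask_path:
        mask = read_mask(record.mask_path)
        if mask.num_classes < 2:
            mask = LabelMap(mask.labels, ["background", "malignant"])
    else:
        mask = LabelMap(
            np.zeros(image.pixels.shape[:2], dtype=np.uint8), ["background", "malignant"]
        )
    return image, mask


def _prepare(
    image: RgbImage, mask: LabelMap, config: TrainConfig
) -> tuple[np.ndarray, np.ndarray]:
    x = preprocess_for_model(image, config.stains, config.clahe, size=config.input_size)
    y = resize_nearest(mask.labels, config.input_size, config.input_size)
    return x.astype(np.float32), y


def _validation_dice(model, val_data, config: TrainConfig) -> float:
    """Pooled foreground Dice over the validation set (evaluation mode)."""
    inter = 0.0
    total = 0.0
    for start in range(0, len(val_data), config.batch_size):
        chunk = val_data[start : start + config.batch_size]
        xb = np.stack([x for x, _ in chunk])
        yb = np.stack([y for _, y in chunk])
        probs = network.segment(model, xb)
        pred = probs.argmax(axis=-1)
        inter += float(np.sum((pred > 0) & (yb > 0)))
        total += float(np.sum(pred > 0) + np.sum(yb > 0))
    return 2.0 * inter / total if total > 0 else 1.0


def train(
    model: network.SegModel,
    train_records: list[ManifestRecord],
    val_records: list[ManifestRecord],
    config: TrainConfig | None = None,
    loss_config: LossConfig | None = None,
    seed: int = 0,
) -> tuple[network.SegModel, TrainHistory]:
    """Run the full optimization protocol; returns the model loaded with the
    best-validation-epoch parameters and the epoch-level history."""
    config = config or TrainConfig()
    loss_config = loss_config or LossConfig()
    if not train_records or not val_records:
        raise ValueError("training and validation partitions must be nonempty")

    train_pairs = [_load_pair(r) for r in train_records]
    val_data = [_prepare(img, msk, config) for img, msk in (_load_pair(r) for r in val_records)]

    optimizer = SGD(
        model.parameters(), config.sgd_lr, momentum=config.momentum, weight_decay=config.weight_decay
    )
    phase = "sgd"
    history = TrainHistory()
    best_dice = -np.inf
    best_state = model.state_dict()
    since_improve = 0

    for epoch in range(1, config.max_epochs + 1):
        model.train()
        batches = balanced_batches(train_records, config.batch_size, _derived_seed(seed, epoch))
        epoch_loss = 0.0
        for bi, batch in enumerate(batches):
            xs, ys = [], []
            for pos, ri in enumerate(batch):
                img, msk = train_pairs[ri]
                aug_seed = _derived_seed(seed, epoch, bi, pos)
                img_a, msk_a = augment_pair(img, msk, config.augment, aug_seed, config.stains)
                x, y = _prepare(img_a, msk_a, config)
                xs.append(x)
                ys.append(y)
            xb = Tensor(np.stack(xs).transpose(0, 3, 1, 2))
            yb = np.stack(ys)
            probs = model.forward_probs(xb).transpose((0, 2, 3, 1))
            loss = losses.total_loss(probs, yb, loss_config)
            value = float(loss.data)
            if not np.isfinite(value):
                raise FloatingPointError(f"non-finite loss at epoch {epoch}, batch {bi}")
            model.zero_grad()
            loss.backward()
            optimizer.step()
            epoch_loss += value
        epoch_loss /= max(len(batches), 1)

        val_dice = _validation_dice(model, val_data, config)
        history.train_loss.append(epoch_loss)
        history.val_dice.append(val_dice)
        history.optimizer_phase.append(phase)

        if val_dice > best_dice:
            best_dice = val_dice
            best_state = model.state_dict()
            history.best_epoch = epoch
            since_improve = 0
        else:
            since_improve += 1
            if phase == "sgd" and since_improve >= config.switch_patience:
                optimizer = Adam(
                    model.parameters(),
                    config.adam_lr,
                    beta1=config.beta1,
                    beta2=config.beta2,
                    weight_decay=config.weight_decay,
                )
                phase = "adam"
            if since_improve >= config.patience:
                history.stopping_reason = f"no improvement for {config.patience} epochs"
                break
    else:
        history.stopping_reason = "max_epochs reached"

    model.load_state_dict(best_state)
    return model, history


def train_classifier(
    model: network.SegModel,
    records: list[ManifestRecord],
    config: TrainConfig | None = None,
    epochs: int = 10,
    lr: float = 1e-3,
    seed: int = 0,
    head_only: bool = True,
) -> network.SegModel:
    """Fit the benign/malignant head with cross-entropy.

    Classification follows segmentation in this pipeline: the head consumes
    the globally pooled bottleneck of the (already trained) encoder.  By
    default only the fully connected head is optimized, on bottleneck
    features precomputed in evaluation mode; ``head_only=False`` trains the
    whole network jointly instead."""
    config = config or TrainConfig()
    pairs = [_load_pair(r) for r in records]
    labels = np.array(
        [model.image_classes.index(r.class_label) for r in records], dtype=int
    )
    data = [
        preprocess_for_model(img, config.stains, config.clahe, size=config.input_size).astype(
            np.float32
        )
        for img, _ in pairs
    ]
    equal_w = np.ones(len(model.image_classes))
    if head_only:
        model.eval()
        feats = []
        for start in range(0, len(data), config.batch_size):
            xb = Tensor(np.stack(data[start : start + config.batch_size]).transpose(0, 3, 1, 2))
            bottleneck, _ = model.encode(xb)
            feats.append(bottleneck.data.mean(axis=(2, 3)))
        feats = np.concatenate(feats)
        head_params = [
            model.fc_hidden.weight,
            model.fc_hidden.bias,
            model.fc_out.weight,
            model.fc_out.bias,
        ]
        optimizer = Adam(head_params, lr)
        for epoch in range(1, epochs + 1):
            batches = balanced_batches(records, config.batch_size, _derived_seed(seed, epoch))
            for batch in batches:
                xb = Tensor(feats[list(batch)])
                scores = model.fc_out(model.fc_hidden(xb).relu())
                probs = network.softmax_channel(scores, axis=1)
                loss = losses.weighted_cross_entropy(probs, labels[list(batch)], equal_w)
                for p in head_params:
                    p.grad = None
                loss.backward()
                optimizer.step()
        return model
    optimizer = Adam(model.parameters(), lr)
    for epoch in range(1, epochs + 1):
        model.train()
        batches = balanced_batches(records, config.batch_size, _derived_seed(seed, epoch))
        for batch in batches:
            xb = Tensor(np.stack([data[i] for i in batch]).transpose(0, 3, 1, 2))
            yb = labels[list(batch)]
            scores = model.forward_class_scores(xb)
            probs = network.softmax_channel(scores, axis=1)
            loss = losses.weighted_cross_entropy(probs, yb, equal_w)
            model.zero_grad()
            loss.backward()
            optimizer.step()
    return model


def evaluate(
    model: network.SegModel, records: list[ManifestRecord], config: TrainConfig | None = None
) -> MetricsReport:
    """Inference + pooled pixel metrics over a manifest (no fitting)."""
    config = config or TrainConfig()
    if not records:
        raise ValueError("empty manifest")
    preds, truths, probs_all = [], [], []
    data = [_prepare(img, msk, config) for img, msk in (_load_pair(r) for r in records)]
    for start in range(0, len(data), config.batch_size):
        chunk = data[start : start + config.batch_size]
        xb = np.stack([x for x, _ in chunk])
        probs = network.segment(model, xb)
        preds.append(probs.argmax(axis=-1))
        probs_all.append(probs)
        truths.append(np.stack([y for _, y in chunk]))
    return segmentation_metrics(
        np.concatenate(preds), np.concatenate(truths), np.concatenate(probs_all)
    )


def cross_validate(
    records: list[ManifestRecord],
    n_folds: int = 5,
    config: TrainConfig | None = None,
    loss_config: LossConfig | None = None,
    seeds: tuple[int, ...] | None = None,
) -> dict:
    """K-fold patient-grouped cross-validation repeated over seeds.

    Trains one model per (fold, seed); reports per-fold metric dicts and the
    aggregate mean ± sd with confidence intervals."""
    config = config or TrainConfig()
    seeds = tuple(seeds if seeds is not None else config.seeds)
    split = kfold_split(records, n_folds, seed=seeds[0])
    per_run = []
    for fold in range(n_folds):
        val_idx = set(split.indices(fold).tolist())
        train_recs = [r for i, r in enumerate(records) if i not in val_idx]
        val_recs = [r for i, r in enumerate(records) if i in val_idx]
        train_patients = {r.patient_id for r in train_recs}
        assert not train_patients & {r.patient_id for r in val_recs}, "patient leakage"
        for s in seeds:
            model = network.build_model(
                network.EncoderConfig(
                    input_size=config.input_size, width_multiplier=config.width_multiplier
                ),
                num_classes=config.num_classes,
                dropout=config.dropout,
                seed=s,
            )
            model, history = train(model, train_recs, val_recs, config, loss_config, seed=s)
            report = evaluate(model, val_recs, config)
            row = report.to_dict()
            row.pop("confusion", None)
            row.update({"fold": fold, "seed": s, "best_epoch": history.best_epoch})
            per_run.append(row)
    metric_rows = [
        {k: v for k, v in row.items() if k not in ("fold", "seed", "best_epoch")}
        for row in per_run
    ]
    return {"per_run": per_run, "aggregate": aggregate_runs(metric_rows)}


def evaluate_cross_dataset(
    model: network.SegModel,
    records_b: list[ManifestRecord],
    config: TrainConfig | None = None,
    in_domain_report: MetricsReport | None = None,
) -> dict:
    """Evaluate a trained model on a second manifest without any fitting;
    records the domain-shift delta against an in-domain report if given."""
    if not records_b:
        raise ValueError("empty manifest")
    known = set(model.class_names)
    classes_b = {r.class_label for r in records_b}
    if not classes_b <= {"benign", "malignant"} | known:
        raise ValueError(f"class vocabulary mismatch: {sorted(classes_b)}")
    report = evaluate(model, records_b, config)
    out = {"report": report}
    if in_domain_report is not None:
        out["dice_drop"] = in_domain_report.dice - report.dice
    return out
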