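"""Depthwise-separable encoder with a U-Net decoder.

The encoder follows the familiar inverted-residual stage table (channels
32, 16, 24, 32, 64, 96, 160, 320 and a final 1280-channel 1×1 convolution;
strides 2, 1, 2, 2, 2, 1, 2, 1), so a 224×224 input is condensed to a 7×7
bottleneck.  Each inverted residual expands channels pointwise by a factor
t, filters spatially with a per-channel (depthwise) 3×3 convolution, and
projects pointwise back down, with a shortcut when stride is 1 and shapes
match.  The decoder up-samples bilinearly in four steps, concatenating the
encoder features tapped at strides 2, 4, 8 and 16, and ends in a 1×1
convolution to per-pixel class scores at input resolution.  A small
classification head (global average pooling over the bottleneck, one hidden
layer) predicts benign vs. malignant, and Grad-CAM exposes which regions
drive that prediction.

`width_multiplier` scales every channel count so a tiny variant can be
trained on a CPU; the default of 1.0 reproduces the stage table exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import _autodiff as ad
from ._autodiff import (
    Adam,  # noqa: F401  (re-exported for the training loop)
    Module,
    Parameter,
    Tensor,
    bilinear_resize,
    concat,
    softmax_channel,
)

__all__ = [
    "EncoderConfig",
    "SegModel",
    "InvertedResidual",
    "depthwise_conv",
    "pointwise_conv",
    "build_model",
    "segment",
    "classify",
    "grad_cam",
    "count_parameters",
    "save_model",
    "load_model",
]

#: (operator, expansion t, out channels c, repeats n, stride s)
DEFAULT_STAGES: tuple = (
    ("conv", None, 32, 1, 2),
    ("bottleneck", 1, 16, 1, 1),
    ("bottleneck", 6, 24, 2, 2),
    ("bottleneck", 6, 32, 3, 2),
    ("bottleneck", 6, 64, 4, 2),
    ("bottleneck", 6, 96, 3, 1),
    ("bottleneck", 6, 160, 3, 2),
    ("bottleneck", 6, 320, 1, 1),
    ("conv1x1", None, 1280, 1, 1),
)

DECODER_WIDTHS = (256, 128, 64, 32)


@dataclass
class EncoderConfig:
    stages: tuple = DEFAULT_STAGES
    input_size: int = 224
    width_multiplier: float = 1.0

    def __post_init__(self):
        if self.width_multiplier <= 0:
            raise ValueError("width_multiplier must be > 0")

    def scaled(self, channels: int) -> int:
        return max(1, int(round(channels * self.width_multiplier)))

    def spatial_trace(self) -> list[int]:
        """Feature-map side length after each stage for `input_size` input."""
        size = self.input_size
        trace = []
        for _, _, _, n, s in self.stages:
            for rep in range(n):
                stride = s if rep == 0 else 1
                size = (size + stride - 1) // stride if stride > 1 else size
            trace.append(size)
        return trace


# ---------------------------------------------------------------------------
# Functional operators (plain numpy, channel-last; these share the im2col
# machinery used by the autodiff layers)
# ---------------------------------------------------------------------------

def depthwise_conv(
    feature: np.ndarray, kernels: np.ndarray, stride: int = 1, padding: int = 0
) -> np.ndarray:
    """Per-channel spatial convolution: channel c of the output depends on
    channel c of the input only.  feature is H×W×C; kernels are k×k×C."""
    feature = np.asarray(feature, dtype=float)
    kernels = np.asarray(kernels, dtype=float)
    if feature.ndim != 3 or kernels.ndim != 3:
        raise ValueError("feature must be H×W×C and kernels k×k×C")
    if kernels.shape[2] != feature.shape[2]:
        raise ValueError(
            f"kernel/channel mismatch: {kernels.shape[2]} kernels for {feature.shape[2]} channels"
        )
    x = feature.transpose(2, 0, 1)[None]  # 1,C,H,W
    w = kernels.transpose(2, 0, 1)  # C,k,k
    out = ad.depthwise_conv2d_raw(x, w, stride, padding)
    return out[0].transpose(1, 2, 0)


def pointwise_conv(feature: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """1×1 convolution: output channel k = Σ_c W(k,c) · input_c per pixel."""
    feature = np.asarray(feature, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if weights.ndim != 2 or weights.shape[1] != feature.shape[-1]:
        raise ValueError(
            f"weights must be K×C with C={feature.shape[-1]}, got {weights.shape}"
        )
    return feature @ weights.T


# ---------------------------------------------------------------------------
# Layers
# ---------------------------------------------------------------------------

class ConvBNAct(Module):
    def __init__(self, in_ch, out_ch, kernel, stride, rng, act="relu6"):
        super().__init__()
        self.conv = ad.Conv2d(in_ch, out_ch, kernel, stride, pad=kernel // 2, bias=False, rng=rng)
        self.bn = ad.BatchNorm2d(out_ch)
        self.act = act

    def __call__(self, x: Tensor) -> Tensor:
        out = self.bn(self.conv(x))
        if self.act == "relu6":
            return out.relu6()
        if self.act == "relu":
            return out.relu()
        return out


class InvertedResidual(Module):
    """Pointwise expand (×t) → depthwise 3×3 (stride s) → pointwise project."""

    def __init__(self, in_ch: int, expansion: int, out_ch: int, stride: int, rng=None):
        super().__init__()
        if expansion < 1:
            raise ValueError("expansion must be ≥ 1")
        rng = rng or np.random.default_rng(0)
        hidden = in_ch * expansion
        self.expand = ConvBNAct(in_ch, hidden, 1, 1, rng) if expansion > 1 else None
        self.depthwise = ad.DepthwiseConv2d(hidden, 3, stride, pad=1, rng=rng)
        self.dw_bn = ad.BatchNorm2d(hidden)
        self.project = ad.Conv2d(hidden, out_ch, 1, 1, pad=0, bias=False, rng=rng)
        self.proj_bn = ad.BatchNorm2d(out_ch)
        self.use_residual = stride == 1 and in_ch == out_ch

    def __call__(self, x: Tensor) -> Tensor:
        h = self.expand(x) if self.expand is not None else x
        h = self.dw_bn(self.depthwise(h)).relu6()
        h = self.proj_bn(self.project(h))
        return h + x if self.use_residual else h

    def parameter_count(self) -> int:
        return sum(p.data.size for p in self.parameters())


class DecoderBlock(Module):
    """Bilinear ×2 up-sample, concat the skip, two 3×3 convs, dropout."""

    def __init__(self, in_ch, skip_ch, out_ch, dropout, rng):
        super().__init__()
        self.conv1 = ConvBNAct(in_ch + skip_ch, out_ch, 3, 1, rng, act="relu")
        self.conv2 = ConvBNAct(out_ch, out_ch, 3, 1, rng, act="relu")
        self.dropout = ad.Dropout(dropout)

    def __call__(self, x: Tensor, skip: Tensor) -> Tensor:
        up = bilinear_resize(x, skip.shape[2], skip.shape[3])
        h = self.conv1(concat([up, skip], axis=1))
        h = self.conv2(h)
        return self.dropout(h)


class SegModel(Module):
    """Encoder + U-Net decoder + segmentation and classification heads."""

    def __init__(
        self,
        config: EncoderConfig | None = None,
        num_classes: int = 2,
        dropout: float = 0.3,
        class_names: tuple[str, ...] | None = None,
        image_classes: tuple[str, ...] = ("benign", "malignant"),
        hidden_units: int = 256,
        seed: int = 0,
    ):
        super().__init__()
        self.config = config or EncoderConfig()
        self.num_classes = num_classes
        self.class_names = tuple(class_names or [f"class{i}" for i in range(num_classes)])
        self.image_classes = image_classes
        rng = np.random.default_rng(seed)

        blocks: list[Module] = []
        block_strides: list[int] = []
        in_ch = 3
        current_stride = 1
        for op, t, c, n, s in self.config.stages:
            out_ch = self.config.scaled(c)
            for rep in range(n):
                stride = s if rep == 0 else 1
                if op == "conv":
                    blocks.append(ConvBNAct(in_ch, out_ch, 3, stride, rng))
                elif op == "conv1x1":
                    blocks.append(ConvBNAct(in_ch, out_ch, 1, stride, rng))
                elif op == "bottleneck":
                    blocks.append(InvertedResidual(in_ch, t, out_ch, stride, rng))
                else:
                    raise ValueError(f"unknown operator {op!r}")
                current_stride *= stride
                block_strides.append(current_stride)
                in_ch = out_ch
        self.encoder_blocks = blocks
        self._block_strides = block_strides
        self.bottleneck_channels = in_ch

        # skip taps: last block at each of strides 2, 4, 8, 16
        self._skip_idx = {}
        for i, s in enumerate(block_strides):
            if s in (2, 4, 8, 16):
                self._skip_idx[s] = i
        skip_channels = {
            s: self._out_channels(i) for s, i in self._skip_idx.items()
        }

        widths = [max(1, int(round(wch * self.config.width_multiplier))) for wch in DECODER_WIDTHS]
        self.decoder_blocks = [
            DecoderBlock(in_ch, skip_channels[16], widths[0], dropout, rng),
            DecoderBlock(widths[0], skip_channels[8], widths[1], dropout, rng),
            DecoderBlock(widths[1], skip_channels[4], widths[2], dropout, rng),
            DecoderBlock(widths[2], skip_channels[2], widths[3], dropout, rng),
        ]
        self.head = ad.Conv2d(widths[3], num_classes, 1, 1, pad=0, bias=True, rng=rng)
        self.fc_hidden = ad.Linear(self.bottleneck_channels, hidden_units, rng=rng)
        self.fc_out = ad.Linear(hidden_units, len(image_classes), rng=rng)
        self._last_bottleneck: Tensor | None = None

    def _out_channels(self, block_index: int) -> int:
        block = self.encoder_blocks[block_index]
        if isinstance(block, InvertedResidual):
            return block.project.weight.data.shape[0]
        return block.conv.weight.data.shape[0]

    # -- forward passes -------------------------------------------------------
    def encode(self, x: Tensor) -> tuple[Tensor, dict[int, Tensor]]:
        h, w = x.shape[2], x.shape[3]
        if h % 32 or w % 32:
            raise ValueError(f"input size {h}×{w} not divisible by 32")
        skips: dict[int, Tensor] = {}
        out = x
        for i, block in enumerate(self.encoder_blocks):
            out = block(out)
            for s, idx in self._skip_idx.items():
                if idx == i:
                    skips[s] = out
        self._last_bottleneck = out
        return out, skips

    def forward_scores(self, x: Tensor) -> Tensor:
        """Per-pixel class scores (N, C, H, W) at input resolution."""
        bottleneck, skips = self.encode(x)
        h = bottleneck
        for block, stride in zip(self.decoder_blocks, (16, 8, 4, 2)):
            h = block(h, skips[stride])
        h = bilinear_resize(h, x.shape[2], x.shape[3])
        return self.head(h)

    def forward_probs(self, x: Tensor) -> Tensor:
        return softmax_channel(self.forward_scores(x), axis=1)

    def forward_class_scores(self, x: Tensor) -> Tensor:
        bottleneck, _ = self.encode(x)
        pooled = bottleneck.mean(axis=(2, 3))
        return self.fc_out(self.fc_hidden(pooled).relu())


def build_model(
    config: EncoderConfig | None = None,
    num_classes: int = 2,
    dropout: float = 0.3,
    seed: int = 0,
    **kwargs,
) -> SegModel:
    return SegModel(config, num_classes=num_classes, dropout=dropout, seed=seed, **kwargs)


def _to_batch(images: np.ndarray) -> Tensor:
    arr = np.asarray(images, dtype=np.float32)
    if arr.ndim == 3:
        arr = arr[None]
    return Tensor(arr.transpose(0, 3, 1, 2))


def segment(model: SegModel, images: np.ndarray) -> np.ndarray:
    """Per-pixel softmax probabilities (N, H, W, C) in evaluation mode."""
    was_training = model.training
    model.eval()
    probs = model.forward_probs(_to_batch(images)).data.transpose(0, 2, 3, 1)
    if was_training:
        model.train()
    return probs.astype(np.float64)


def classify(model: SegModel, image: np.ndarray) -> np.ndarray:
    """Softmax class probabilities over the image-level classes."""
    was_training = model.training
    model.eval()
    scores = model.forward_class_scores(_to_batch(image))
    probs = softmax_channel(scores, axis=1).data[0]
    if was_training:
        model.train()
    return probs.astype(np.float64)


def grad_cam(model: SegModel, image: np.ndarray, target: int) -> np.ndarray:
    """Gradient-weighted class activation map in [0, 1] at input resolution.

    Channel weights are the spatially pooled gradients of the target class
    score with respect to the deepest encoder activation; the rectified
    weighted activation sum is up-sampled bilinearly and min-max normalized
    (an all-zero map stays all-zero)."""
    if not 0 <= target < len(model.image_classes):
        raise ValueError(f"undefined class id {target}")
    was_training = model.training
    model.eval()
    model.zero_grad()
    x = _to_batch(image)
    scores = model.forward_class_scores(x)
    onehot = np.zeros(scores.shape)
    onehot[:, target] = 1.0
    (scores * onehot).sum().backward()
    activation = model._last_bottleneck
    grads = activation.grad
    if was_training:
        model.train()
    if grads is None:
        return np.zeros(image.shape[:2] if image.ndim == 3 else image.shape[1:3])
    weights = grads.mean(axis=(2, 3), keepdims=True)
    cam = np.maximum((weights * activation.data).sum(axis=1), 0.0)[0]
    cam_t = Tensor(cam[None, None])
    h, w = x.shape[2], x.shape[3]
    cam_up = ad.bilinear_resize(cam_t, h, w).data[0, 0].astype(np.float64)
    lo, hi = cam_up.min(), cam_up.max()
    if hi - lo < 1e-12:
        return np.zeros_like(cam_up)
    model.zero_grad()
    return (cam_up - lo) / (hi - lo)


def count_parameters(model: Module) -> int:
    return int(sum(p.data.size for p in model.parameters()))


# ---------------------------------------------------------------------------
# Checkpoints: native .npz weights plus a JSON sidecar with the config
# ---------------------------------------------------------------------------

def save_model(model: SegModel, path: str | Path) -> None:
    path = Path(path)
    state = model.state_dict()
    np.savez(path.with_suffix(".npz"), **state)
    sidecar = {
        "stages": [list(s) for s in model.config.stages],
        "input_size": model.config.input_size,
        "width_multiplier": model.config.width_multiplier,
        "num_classes": model.num_classes,
        "class_names": list(model.class_names),
        "image_classes": list(model.image_classes),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_model(path: str | Path) -> SegModel:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    config = EncoderConfig(
        stages=tuple(tuple(s) for s in meta["stages"]),
        input_size=meta["input_size"],
        width_multiplier=meta["width_multiplier"],
    )
    model = SegModel(
        config,
        num_classes=meta["num_classes"],
        class_names=tuple(meta["class_names"]),
        image_classes=tuple(meta["image_classes"]),
    )
    with np.load(path.with_suffix(".npz")) as data:
        model.load_state_dict({k: data[k] for k in data.files})
    return model
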