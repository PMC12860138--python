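"""Graph-based label propagation refinement of probability maps.

Each pixel is a node of an 8-connected graph; edge weights combine a color
and a spatial Gaussian kernel,

    w_ij = exp(−‖I_i − I_j‖² / 2σ_I²) · exp(−‖x_i − x_j‖² / 2σ_x²),

and labels diffuse over the symmetrically normalized affinity
S = D^{−1/2} W D^{−1/2} by iterating

    F(t+1) = α S F(t) + (1 − α) Y,

which converges (spectral radius of αS < 1) to the closed-form fixed point
F* = (1 − α)(I − αS)^{−1} Y.  Seeds Y come from confident network
predictions (or from a ground-truth mask); propagation spreads that
certainty to neighbouring pixels, cleaning salt-and-pepper errors and
smoothing region boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import spsolve

from .imaging_io import LabelMap, RgbImage

__all__ = [
    "LPConfig",
    "AffinityGraph",
    "PropagationState",
    "SeedError",
    "build_graph",
    "seed_labels",
    "propagate",
    "closed_form",
    "refine_mask",
]

_NEIGHBOR_OFFSETS = ((0, 1), (1, 0), (1, 1), (1, -1))  # + symmetric partners


class SeedError(ValueError):
    """Raised when the confidence thresholds produce no seed for a class
    that is present in the prediction."""


@dataclass
class LPConfig:
    alpha: float = 0.9
    sigma_i: float = 0.1
    sigma_x: float = 2.0
    connectivity: int = 8
    seed_high: float = 0.9
    seed_low: float = 0.1
    max_iter: int = 200
    tol: float = 1e-6
    tile_size: int = 128
    tile_stride: int = 96

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.sigma_i <= 0 or self.sigma_x <= 0:
            raise ValueError("sigma_i and sigma_x must be > 0")
        if self.connectivity != 8:
            raise ValueError("only 8-connectivity is supported")
        if self.seed_high <= self.seed_low:
            raise ValueError("seed_high must exceed seed_low")


@dataclass
class AffinityGraph:
    """Sparse pixel graph: W (symmetric, zero diagonal), degrees D_ii and the
    normalized affinity S = D^{−1/2} W D^{−1/2}."""

    weights: sp.csr_matrix
    degrees: np.ndarray
    normalized: sp.csr_matrix
    shape: tuple[int, int]

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]


@dataclass
class PropagationState:
    scores: np.ndarray  # F, N×C
    iterations: int
    residual: float


def build_graph(features: np.ndarray, config: LPConfig | None = None) -> AffinityGraph:
    """Build the 8-connected affinity graph from per-pixel feature vectors."""
    config = config or LPConfig()
    features = np.asarray(features, dtype=float)
    if features.ndim == 2:
        features = features[:, :, None]
    h, w, _ = features.shape
    if h == 0 or w == 0:
        raise ValueError("empty image")
    n = h * w
    idx = np.arange(n).reshape(h, w)
    rows, cols, vals = [], [], []
    for dr, dc in _NEIGHBOR_OFFSETS:
        r0 = slice(max(0, -dr), h - max(0, dr))
        c0 = slice(max(0, -dc), w - max(0, dc))
        r1 = slice(max(0, dr), h + min(0, dr))
        c1 = slice(max(0, dc), w + min(0, dc))
        i = idx[r0, c0].ravel()
        j = idx[r1, c1].ravel()
        diff = features[r0, c0] - features[r1, c1]
        color = np.exp(-np.sum(diff * diff, axis=-1).ravel() / (2 * config.sigma_i**2))
        spatial = np.exp(-(dr * dr + dc * dc) / (2 * config.sigma_x**2))
        wij = color * spatial
        rows.extend((i, j))
        cols.extend((j, i))
        vals.extend((wij, wij))
    weights = sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))), shape=(n, n)
    ).tocsr()
    degrees = np.maximum(np.asarray(weights.sum(axis=1)).ravel(), 1e-12)
    d_inv_sqrt = sp.diags(1.0 / np.sqrt(degrees))
    normalized = (d_inv_sqrt @ weights @ d_inv_sqrt).tocsr()
    return AffinityGraph(weights, degrees, normalized, (h, w))


def seed_labels(
    probs: np.ndarray,
    config: LPConfig | None = None,
    ground_truth: np.ndarray | None = None,
    strict: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Initial label matrix Y (N×C) and boolean mask of unlabeled pixels.

    Pixels whose maximum class probability reaches ``seed_high`` become
    one-hot seeds; pixels whose foreground probability is at most
    ``seed_low`` become background seeds; the rest stay unlabeled.  When a
    ground-truth mask is given it replaces the thresholding entirely.  In
    non-strict mode a class present in the prediction but left seedless gets
    its single most-confident pixel as seed instead of raising.
    """
    config = config or LPConfig()
    probs = np.asarray(probs, dtype=float)
    h, w, c = probs.shape
    n = h * w
    flat = probs.reshape(n, c)
    if ground_truth is not None:
        labels = np.asarray(ground_truth).reshape(n)
        y = np.eye(c)[labels]
        return y, np.zeros(n, dtype=bool)

    y = np.zeros((n, c))
    argmax = flat.argmax(axis=1)
    confident = flat.max(axis=1) >= config.seed_high
    y[confident] = np.eye(c)[argmax[confident]]
    background = (1.0 - flat[:, 0]) <= config.seed_low
    y[background & ~confident, :] = 0.0
    y[background & ~confident, 0] = 1.0

    seeded = y.sum(axis=1) > 0
    for cls in np.unique(argmax):
        present_pixels = argmax == cls
        if not np.any(seeded & (y[:, cls] > 0)):
            if strict:
                raise SeedError(
                    f"thresholds seed_high={config.seed_high}, seed_low={config.seed_low} "
                    f"leave zero seeds for present class {cls}"
                )
            best = np.flatnonzero(present_pixels)[np.argmax(flat[present_pixels, cls])]
            y[best] = 0.0
            y[best, cls] = 1.0
            seeded[best] = True
    return y, ~seeded


def propagate(
    graph: AffinityGraph,
    y: np.ndarray,
    alpha: float = 0.9,
    max_iter: int = 200,
    tol: float = 1e-6,
) -> PropagationState:
    """Iterate F(t+1) = αSF(t) + (1−α)Y from F(0) = Y until the maximum
    absolute per-sweep change falls below `tol`."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("Y contains non-finite values")
    s = graph.normalized
    f = y.copy()
    base = (1.0 - alpha) * y
    residual = np.inf
    iterations = 0
    for iterations in range(1, max_iter + 1):
        f_new = alpha * (s @ f) + base
        residual = float(np.abs(f_new - f).max())
        f = f_new
        if not np.all(np.isfinite(f)):
            raise FloatingPointError("propagation produced non-finite values")
        if residual < tol:
            break
    return PropagationState(scores=f, iterations=iterations, residual=residual)


def closed_form(graph: AffinityGraph, y: np.ndarray, alpha: float = 0.9) -> np.ndarray:
    """Exact fixed point F* = (1−α)(I−αS)^{−1}Y (test-scale linear solve)."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    y = np.asarray(y, dtype=float)
    n = graph.n_nodes
    system = sp.eye(n, format="csc") - alpha * graph.normalized.tocsc()
    out = spsolve(system, (1.0 - alpha) * y)
    if out.ndim == 1:
        out = out[:, None]
    return np.asarray(out)


def _renormalize(f: np.ndarray) -> np.ndarray:
    rows = np.maximum(f.sum(axis=1, keepdims=True), 1e-12)
    return f / rows


def refine_mask(
    image: RgbImage,
    probs: np.ndarray,
    config: LPConfig | None = None,
    class_names: list[str] | None = None,
) -> tuple[LabelMap, np.ndarray]:
    """Refine a probability map by label propagation over the image graph.

    Inputs larger than ``config.tile_size`` are processed in overlapping
    square windows (stride ``config.tile_stride``) and the propagated scores
    are averaged in the overlaps.  Returns the refined label map (argmax of
    row-renormalized scores, ties resolved toward background) and the
    refined probability map.
    """
    config = config or LPConfig()
    probs = np.asarray(probs, dtype=float)
    h, w, c = probs.shape
    if image.pixels.shape[:2] != (h, w):
        raise ValueError("image and probability map dimensions differ")
    features = image.pixels.astype(float) / 255.0

    f_sum = np.zeros((h, w, c))
    counts = np.zeros((h, w, 1))
    ts, stride = config.tile_size, config.tile_stride
    row_starts = [0] if h <= ts else list(range(0, h - ts, stride)) + [h - ts]
    col_starts = [0] if w <= ts else list(range(0, w - ts, stride)) + [w - ts]
    for r0 in row_starts:
        for c0 in col_starts:
            r1, c1 = min(r0 + ts, h), min(c0 + ts, w)
            sub_feat = features[r0:r1, c0:c1]
            sub_probs = probs[r0:r1, c0:c1]
            graph = build_graph(sub_feat, config)
            y, _ = seed_labels(sub_probs, config, strict=False)
            state = propagate(graph, y, config.alpha, config.max_iter, config.tol)
            f_sum[r0:r1, c0:c1] += state.scores.reshape(r1 - r0, c1 - c0, c)
            counts[r0:r1, c0:c1] += 1.0
    f = f_sum / counts
    refined_probs = _renormalize(f.reshape(-1, c)).reshape(h, w, c)
    labels = refined_probs.argmax(axis=2).astype(np.uint8)
    names = class_names or [f"class{i}" for i in range(c)]
    if names:
        names = list(names)
        names[0] = names[0] if class_names else "background"
    return LabelMap(labels, names), refined_probs
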