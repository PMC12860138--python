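"""Preprocessing for H&E histology patches.

The pipeline mirrors common digital-pathology practice: bicubic resizing to
the network input size, luminance grayscale conversion, contrast-limited
adaptive histogram equalization (CLAHE), Beer–Lambert optical-density
transform ``OD = −log10(I/I0)``, least-squares stain separation against a
reference H&E stain matrix, and the on-the-fly augmentation set used during
training (rotations, flips, crops, scale jitter, brightness/contrast and
multiplicative stain jitter).

All stochastic operations are pure functions of (input, seed).  Pixel
coordinates are (row, col), origin top-left.  Bicubic interpolation uses the
Catmull-Rom kernel (a = −0.5) with replicated edges and half-pixel-centre
coordinate mapping.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .imaging_io import LabelMap, RgbImage

__all__ = [
    "ClaheParams",
    "StainMatrix",
    "AugmentConfig",
    "GRAY_WEIGHTS",
    "resize_bicubic",
    "resize_nearest",
    "to_grayscale",
    "apply_clahe",
    "rgb_to_od",
    "od_to_rgb",
    "stain_deconvolve",
    "stain_jitter",
    "augment_pair",
    "preprocess_for_model",
]

#: Luminance weights of the grayscale transform (they sum to 1).
GRAY_WEIGHTS = np.array([0.299, 0.587, 0.114])

#: Ruifrok–Johnston H&E optical-density vectors (rows: hematoxylin, eosin).
_RUIFROK_HE = np.array(
    [
        [0.650, 0.704, 0.286],
        [0.072, 0.990, 0.105],
    ]
)


@dataclass
class ClaheParams:
    """clip_limit is relative: each histogram bin is capped at
    clip_limit × (pixels per tile); the excess is redistributed uniformly."""

    clip_limit: float = 0.01
    tile_grid: tuple[int, int] = (8, 8)

    def __post_init__(self):
        if self.clip_limit <= 0:
            raise ValueError("clip_limit must be > 0")
        if self.tile_grid[0] < 1 or self.tile_grid[1] < 1:
            raise ValueError("tile grid entries must be ≥ 1")


@dataclass
class StainMatrix:
    """Reference stain matrix: unit OD vectors (hematoxylin, eosin) and the
    background (unstained) intensity I0 per channel."""

    od_vectors: np.ndarray = field(default_factory=lambda: _RUIFROK_HE.copy())
    background_intensity: float | np.ndarray = 240.0

    def __post_init__(self):
        self.od_vectors = np.asarray(self.od_vectors, dtype=float)
        if self.od_vectors.shape != (2, 3):
            raise ValueError("od_vectors must be 2×3 (H and E rows)")
        norms = np.linalg.norm(self.od_vectors, axis=1)
        if np.any(norms == 0):
            raise ValueError("stain vectors must be nonzero")
        self.od_vectors = self.od_vectors / norms[:, None]
        if np.linalg.matrix_rank(self.od_vectors) < 2:
            raise ValueError("stain vectors must be linearly independent")
        i0 = np.asarray(self.background_intensity, dtype=float)
        if np.any(i0 <= 0) or np.any(i0 > 255):
            raise ValueError("background intensity must lie in (0, 255]")
        self.background_intensity = i0


@dataclass
class AugmentConfig:
    rotation_choices: tuple[int, ...] = (0, 90, -90)
    flip_horizontal: bool = True
    flip_vertical: bool = True
    max_crop_fraction: float = 0.10
    scale_range: tuple[float, float] = (0.9, 1.1)
    brightness_delta: float = 20.0  # additive, intensity levels
    contrast_range: tuple[float, float] = (0.9, 1.1)
    stain_jitter_sd: float = 0.05

    def __post_init__(self):
        if not 0 <= self.max_crop_fraction <= 0.10:
            raise ValueError("max_crop_fraction must be within [0, 0.10]")
        if self.stain_jitter_sd < 0:
            raise ValueError("stain_jitter_sd must be ≥ 0")

    @classmethod
    def disabled(cls) -> "AugmentConfig":
        return cls(
            rotation_choices=(0,),
            flip_horizontal=False,
            flip_vertical=False,
            max_crop_fraction=0.0,
            scale_range=(1.0, 1.0),
            brightness_delta=0.0,
            contrast_range=(1.0, 1.0),
            stain_jitter_sd=0.0,
        )


# ---------------------------------------------------------------------------
# Bicubic resize (Catmull-Rom, a = -0.5)
# ---------------------------------------------------------------------------

def cubic_kernel(t: np.ndarray, a: float = -0.5) -> np.ndarray:
    """Keys cubic convolution kernel with parameter a."""
    at = np.abs(np.asarray(t, dtype=float))
    w = np.zeros_like(at)
    near = at <= 1
    far = (at > 1) & (at < 2)
    w[near] = (a + 2) * at[near] ** 3 - (a + 3) * at[near] ** 2 + 1
    w[far] = a * at[far] ** 3 - 5 * a * at[far] ** 2 + 8 * a * at[far] - 4 * a
    return w


def _bicubic_axis(n_out: int, n_in: int):
    """4-tap source indices (clipped = replicate edges) and kernel weights."""
    coords = (np.arange(n_out) + 0.5) * (n_in / n_out) - 0.5
    base = np.floor(coords).astype(int)
    idx = base[:, None] + np.arange(-1, 3)[None, :]
    weights = cubic_kernel(coords[:, None] - idx)
    idx = np.clip(idx, 0, n_in - 1)
    return idx, weights


def resize_bicubic(image: RgbImage, target_h: int, target_w: int) -> RgbImage:
    """Separable bicubic resize; identity when dims are unchanged."""
    if target_h < 1 or target_w < 1:
        raise ValueError("target dimensions must be ≥ 1")
    if (target_h, target_w) == (image.height, image.width):
        return RgbImage(image.pixels.copy())
    arr = image.pixels.astype(float)
    out = _resize_bicubic_array(arr, target_h, target_w)
    return RgbImage(np.clip(np.round(out), 0, 255).astype(np.uint8))


def _resize_bicubic_array(arr: np.ndarray, target_h: int, target_w: int) -> np.ndarray:
    ri, rw = _bicubic_axis(target_h, arr.shape[0])
    ci, cw = _bicubic_axis(target_w, arr.shape[1])
    tmp = np.einsum("rkwc,rk->rwc", arr[ri], rw, optimize=True)  # rows
    return np.einsum("rwkc,wk->rwc", tmp[:, ci], cw, optimize=True)  # cols


def resize_nearest(labels: np.ndarray, target_h: int, target_w: int) -> np.ndarray:
    """Nearest-neighbour resize, used for label masks only."""
    h, w = labels.shape[:2]
    ri = np.clip(np.floor((np.arange(target_h) + 0.5) * h / target_h), 0, h - 1).astype(int)
    ci = np.clip(np.floor((np.arange(target_w) + 0.5) * w / target_w), 0, w - 1).astype(int)
    return labels[np.ix_(ri, ci)]


# ---------------------------------------------------------------------------
# Grayscale and CLAHE
# ---------------------------------------------------------------------------

def to_grayscale(image: RgbImage | np.ndarray) -> np.ndarray:
    """Luminance map 0.299·R + 0.587·G + 0.114·B, kept real-valued."""
    arr = image.pixels if isinstance(image, RgbImage) else np.asarray(image)
    return arr[..., :3].astype(float) @ GRAY_WEIGHTS


def _tile_mapping(hist: np.ndarray, clip_count: float) -> np.ndarray:
    """Clipped-histogram equalization LUT for one tile (0..255 → 0..255)."""
    hist = hist.astype(float)
    excess = np.maximum(hist - clip_count, 0.0)
    hist = np.minimum(hist, clip_count) + excess.sum() / hist.size
    cdf = np.cumsum(hist)
    total = cdf[-1]
    if total == 0:
        return np.arange(256, dtype=float)
    return cdf / total * 255.0


def apply_clahe(gray: np.ndarray, params: ClaheParams) -> np.ndarray:
    """Tile-wise clipped histogram equalization with bilinear blending.

    Input values must lie in [0, 255]; the histogram uses 256 integer bins.
    Tile mappings are monotone; pixels between tile centres blend the four
    surrounding mappings bilinearly (replicated at the borders).
    """
    gray = np.asarray(gray, dtype=float)
    if gray.min(initial=0) < 0 or gray.max(initial=0) > 255:
        raise ValueError("CLAHE input must be within [0, 255]")
    h, w = gray.shape
    rows, cols = params.tile_grid
    if rows > h or cols > w:
        raise ValueError("tile grid larger than image")
    levels = np.clip(np.round(gray).astype(int), 0, 255)

    row_edges = np.linspace(0, h, rows + 1).astype(int)
    col_edges = np.linspace(0, w, cols + 1).astype(int)
    luts = np.empty((rows, cols, 256))
    centers_r = (row_edges[:-1] + row_edges[1:]) / 2.0
    centers_c = (col_edges[:-1] + col_edges[1:]) / 2.0
    for ti in range(rows):
        for tj in range(cols):
            tile = levels[row_edges[ti] : row_edges[ti + 1], col_edges[tj] : col_edges[tj + 1]]
            hist = np.bincount(tile.ravel(), minlength=256)
            clip_count = max(params.clip_limit * tile.size, 1.0)
            luts[ti, tj] = _tile_mapping(hist, clip_count)

    # bilinear blending between tile centres
    yy = np.arange(h) + 0.5
    xx = np.arange(w) + 0.5
    r1 = np.clip(np.searchsorted(centers_r, yy), 0, rows - 1)
    r0 = np.clip(r1 - 1, 0, rows - 1)
    c1 = np.clip(np.searchsorted(centers_c, xx), 0, cols - 1)
    c0 = np.clip(c1 - 1, 0, cols - 1)
    denom_r = np.where(r1 > r0, centers_r[r1] - centers_r[r0], 1.0)
    fr = np.clip((yy - centers_r[r0]) / denom_r, 0.0, 1.0)
    denom_c = np.where(c1 > c0, centers_c[c1] - centers_c[c0], 1.0)
    fc = np.clip((xx - centers_c[c0]) / denom_c, 0.0, 1.0)

    r0g, c0g = np.meshgrid(r0, c0, indexing="ij")
    r1g, c1g = np.meshgrid(r1, c1, indexing="ij")
    frg, fcg = np.meshgrid(fr, fc, indexing="ij")
    v00 = luts[r0g, c0g, levels]
    v01 = luts[r0g, c1g, levels]
    v10 = luts[r1g, c0g, levels]
    v11 = luts[r1g, c1g, levels]
    top = v00 * (1 - fcg) + v01 * fcg
    bot = v10 * (1 - fcg) + v11 * fcg
    return top * (1 - frg) + bot * frg


# ---------------------------------------------------------------------------
# Beer–Lambert optical density and stain separation
# ---------------------------------------------------------------------------

def rgb_to_od(image: RgbImage | np.ndarray, i0: float | np.ndarray = 240.0) -> np.ndarray:
    """OD = −log10(I/I0); zero intensities are floored at 1 before the log."""
    i0 = np.asarray(i0, dtype=float)
    if np.any(i0 <= 0):
        raise ValueError("I0 must be positive")
    arr = image.pixels if isinstance(image, RgbImage) else np.asarray(image)
    intensity = np.maximum(arr.astype(float), 1.0)
    return -np.log10(intensity / i0)


def od_to_rgb(od: np.ndarray, i0: float | np.ndarray = 240.0) -> RgbImage:
    """Inverse Beer–Lambert map I = I0·10^(−OD), rounded into [0, 255]."""
    i0 = np.asarray(i0, dtype=float)
    intensity = i0 * np.power(10.0, -np.asarray(od, dtype=float))
    return RgbImage(np.clip(np.round(intensity), 0, 255).astype(np.uint8))


def _unclipped_concentrations(od: np.ndarray, stains: StainMatrix) -> np.ndarray:
    m = stains.od_vectors
    gram = m @ m.T
    if abs(np.linalg.det(gram)) < 1e-12:
        raise ValueError("singular stain matrix")
    # least squares: c = OD · Mᵀ (M Mᵀ)⁻¹
    return od @ m.T @ np.linalg.inv(gram)


def stain_deconvolve(od: np.ndarray, stains: StainMatrix) -> np.ndarray:
    """Per-pixel least-squares solve of OD ≈ c · M; concentrations ≥ 0."""
    return np.maximum(_unclipped_concentrations(od, stains), 0.0)


def stain_jitter(
    image: RgbImage, stains: StainMatrix, sd: float, seed: int
) -> RgbImage:
    """Multiply each stain concentration by exp(N(0, sd²)), one draw per stain.

    The OD component orthogonal to the stain subspace is preserved, so sd = 0
    reproduces the input up to rounding.
    """
    if sd < 0:
        raise ValueError("sd must be ≥ 0")
    rng = np.random.default_rng(seed)
    factors = np.exp(rng.normal(0.0, sd, size=2)) if sd > 0 else np.ones(2)
    od = rgb_to_od(image, stains.background_intensity)
    conc = _unclipped_concentrations(od, stains)
    residual = od - conc @ stains.od_vectors
    od_new = (conc * factors) @ stains.od_vectors + residual
    return od_to_rgb(od_new, stains.background_intensity)


# ---------------------------------------------------------------------------
# Augmentation
# ---------------------------------------------------------------------------

def _zoom(image: np.ndarray, mask: np.ndarray, scale: float):
    """Scale jitter with unchanged canvas: <1 zooms out (replicate-pad),
    >1 zooms in (centre crop); resampling back happens in augment_pair."""
    h, w = mask.shape
    if abs(scale - 1.0) < 1e-9:
        return image, mask
    if scale > 1.0:
        nh, nw = max(1, int(round(h / scale))), max(1, int(round(w / scale)))
        r0, c0 = (h - nh) // 2, (w - nw) // 2
        return image[r0 : r0 + nh, c0 : c0 + nw], mask[r0 : r0 + nh, c0 : c0 + nw]
    nh, nw = int(round(h / scale)), int(round(w / scale))
    pr, pc = nh - h, nw - w
    pad_img = ((pr // 2, pr - pr // 2), (pc // 2, pc - pc // 2), (0, 0))
    pad_msk = pad_img[:2]
    return np.pad(image, pad_img, mode="edge"), np.pad(mask, pad_msk, mode="edge")


def augment_pair(
    image: RgbImage,
    mask: LabelMap,
    config: AugmentConfig,
    seed: int,
    stains: StainMatrix | None = None,
) -> tuple[RgbImage, LabelMap]:
    """Apply one random augmentation draw identically to image and mask.

    Geometric transforms (rotation, flips, crop, scale) move image and mask
    together (mask resampled nearest-neighbour); photometric transforms
    (brightness, contrast, stain jitter) touch the image only.  The output is
    resized back to the input dimensions.
    """
    if image.pixels.shape[:2] != mask.labels.shape:
        raise ValueError("image and mask dimensions differ")
    rng = np.random.default_rng(seed)
    h, w = mask.labels.shape
    img = image.pixels.copy()
    msk = mask.labels.copy()

    # rotation by 0 / +90 / -90
    angle = int(rng.choice(np.asarray(config.rotation_choices)))
    if angle:
        k = 1 if angle == 90 else 3
        img = np.rot90(img, k=k)
        msk = np.rot90(msk, k=k)
    if config.flip_horizontal and rng.random() < 0.5:
        img, msk = img[:, ::-1], msk[:, ::-1]
    if config.flip_vertical and rng.random() < 0.5:
        img, msk = img[::-1], msk[::-1]

    # random crop of up to max_crop_fraction in each axis
    if config.max_crop_fraction > 0:
        fh = rng.uniform(0, config.max_crop_fraction)
        fw = rng.uniform(0, config.max_crop_fraction)
        ch, cw = max(1, int(round(img.shape[0] * (1 - fh)))), max(
            1, int(round(img.shape[1] * (1 - fw)))
        )
        r0 = rng.integers(0, img.shape[0] - ch + 1)
        c0 = rng.integers(0, img.shape[1] - cw + 1)
        img = img[r0 : r0 + ch, c0 : c0 + cw]
        msk = msk[r0 : r0 + ch, c0 : c0 + cw]

    lo, hi = config.scale_range
    scale = rng.uniform(lo, hi) if hi > lo else lo
    img, msk = _zoom(img, msk, scale)

    # back to the input canvas
    if img.shape[:2] != (h, w):
        img = np.clip(
            np.round(_resize_bicubic_array(img.astype(float), h, w)), 0, 255
        ).astype(np.uint8)
        msk = resize_nearest(msk, h, w)

    # photometric (image only)
    out = img.astype(float)
    if config.brightness_delta > 0:
        out = out + rng.uniform(-config.brightness_delta, config.brightness_delta)
    clo, chi = config.contrast_range
    if chi > clo or clo != 1.0:
        factor = rng.uniform(clo, chi) if chi > clo else clo
        out = (out - 128.0) * factor + 128.0
    result = RgbImage(np.clip(np.round(out), 0, 255).astype(np.uint8))
    if config.stain_jitter_sd > 0:
        result = stain_jitter(
            result,
            stains or StainMatrix(),
            config.stain_jitter_sd,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
    return result, LabelMap(np.ascontiguousarray(msk), mask.class_names)


# ---------------------------------------------------------------------------
# Model-input pipeline
# ---------------------------------------------------------------------------

def preprocess_for_model(
    image: RgbImage,
    stains: StainMatrix | None = None,
    clahe: ClaheParams | None = None,
    size: int = 224,
) -> np.ndarray:
    """Resize → stain-normalize → CLAHE on luminance → standardize.

    Stain normalization projects the optical densities onto the reference
    stain subspace (nonnegative concentrations recomposed through the
    reference matrix).  CLAHE runs on the luminance channel and the RGB
    channels are rescaled by the enhancement ratio.  Each channel is finally
    standardized to zero mean and unit variance per image (sd floored at
    1e-8, so a constant channel maps to zeros).  Returns H×W×3 float.
    """
    stains = stains or StainMatrix()
    clahe = clahe or ClaheParams()
    img = resize_bicubic(image, size, size)
    od = rgb_to_od(img, stains.background_intensity)
    conc = stain_deconvolve(od, stains)
    norm = od_to_rgb(conc @ stains.od_vectors, stains.background_intensity)

    gray = to_grayscale(norm)
    rows = min(clahe.tile_grid[0], size)
    cols = min(clahe.tile_grid[1], size)
    enhanced = apply_clahe(gray, ClaheParams(clahe.clip_limit, (rows, cols)))
    ratio = enhanced / np.maximum(gray, 1e-6)
    rgb = np.clip(norm.pixels.astype(float) * ratio[:, :, None], 0, 255)

    mean = rgb.mean(axis=(0, 1))
    sd = rgb.std(axis=(0, 1))
    out = (rgb - mean) / np.maximum(sd, 1e-8)
    out[:, :, sd < 1e-8] = 0.0  # degenerate constant channel
    return out
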