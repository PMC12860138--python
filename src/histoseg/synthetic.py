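"""Synthetic H&E-like patch generator with paired ground-truth masks.

Patches are composed in stain-concentration space and rendered through the
same Beer–Lambert inverse used by the preprocessing module: an
eosin-dominant stroma background with smooth spatial variation, elliptical
hematoxylin-dominant nuclei, and — for malignant samples — dense irregular
nucleus clusters rendered as basophilic tumor-cell sheets whose footprints
form the positive mask.  A linear
illumination gradient and Gaussian optical-density noise emulate the
acquisition nuisances real slides show.  Benign patches carry sparse,
rounder nuclei and an all-zero mask.

Every sample is a pure function of (params, class_label, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .imaging_io import (
    LabelMap,
    ManifestRecord,
    RgbImage,
    write_image,
    write_manifest,
)
from .preprocessing import StainMatrix, od_to_rgb

__all__ = [
    "SyntheticParams",
    "SyntheticSample",
    "generate_sample",
    "generate_dataset",
    "corrupt_probability_map",
]

CLASS_NAMES = ("background", "malignant")


@dataclass
class SyntheticParams:
    image_size: int = 128
    # nuclei per pixel: sparse everywhere, dense inside malignant clusters
    benign_density: float = 6e-4
    malignant_density: float = 8e-3
    benign_radius: tuple[float, float] = (3.0, 5.0)
    malignant_radius: tuple[float, float] = (2.5, 6.0)
    benign_eccentricity: tuple[float, float] = (1.0, 1.3)
    malignant_eccentricity: tuple[float, float] = (1.2, 2.5)
    cluster_count: tuple[int, int] = (1, 3)
    cluster_spread: tuple[float, float] = (18.0, 32.0)
    stain_matrix: StainMatrix = field(default_factory=StainMatrix)
    illumination_amplitude: float = 0.05  # ≤ 0.10, fraction of OD
    noise_sd: float = 0.02  # OD units
    stroma_variation: float = 0.15  # relative low-frequency eosin variation
    stroma_hematoxylin: float = 0.05
    stroma_eosin: float = 0.35
    nucleus_hematoxylin: float = 0.9
    nucleus_eosin: float = 0.10
    # malignant foci are sheets of tumor cells: the cytoplasm between nuclei
    # is markedly more basophilic than stroma, not plain pink
    tumor_hematoxylin: float = 0.30
    tumor_eosin: float = 0.22

    def __post_init__(self):
        if self.benign_density <= 0 or self.malignant_density <= 0:
            raise ValueError("densities must be > 0")
        if self.malignant_density <= self.benign_density:
            raise ValueError("malignant density must exceed benign density")
        if min(self.benign_radius) <= 0 or min(self.malignant_radius) <= 0:
            raise ValueError("degenerate nucleus radius")
        if not 0 <= self.illumination_amplitude <= 0.10:
            raise ValueError("illumination amplitude must be within [0, 0.10]")


@dataclass
class SyntheticSample:
    image: RgbImage
    mask: LabelMap
    class_label: str
    patient_id: str
    seed: int
    nucleus_count: int


def _ellipse_mask(size: int, center, radii, angle: float) -> np.ndarray:
    rr, cc = np.mgrid[0:size, 0:size]
    dy = rr - center[0]
    dx = cc - center[1]
    ca, sa = np.cos(angle), np.sin(angle)
    u = dy * ca + dx * sa
    v = -dy * sa + dx * ca
    return (u / radii[0]) ** 2 + (v / radii[1]) ** 2 <= 1.0


def _smooth_field(rng, size: int, amplitude: float, grid: int = 4) -> np.ndarray:
    """Low-frequency multiplicative variation of the stroma."""
    coarse = rng.normal(0.0, 1.0, (grid, grid))
    zoom = size / grid
    field_ = ndimage.zoom(coarse, zoom, order=1, mode="nearest")[:size, :size]
    return 1.0 + amplitude * field_ / max(np.abs(field_).max(), 1e-9)


def _place_nuclei(rng, c_h, c_e, params, n, radius_range, ecc_range, region=None):
    """Stamp `n` elliptical nuclei; positions restricted to `region` if given."""
    size = c_h.shape[0]
    if region is not None:
        candidates = np.argwhere(region)
        if len(candidates) == 0:
            return 0
    for _ in range(n):
        if region is None:
            center = rng.uniform(0, size, 2)
        else:
            center = candidates[rng.integers(0, len(candidates))] + rng.uniform(-0.5, 0.5, 2)
        r = rng.uniform(*radius_range)
        ecc = rng.uniform(*ecc_range)
        angle = rng.uniform(0, np.pi)
        ell = _ellipse_mask(size, center, (r, r / ecc), angle)
        c_h[ell] = params.nucleus_hematoxylin * rng.uniform(0.85, 1.15)
        c_e[ell] = params.nucleus_eosin
    return n


def generate_sample(
    params: SyntheticParams, class_label: str, seed: int
) -> SyntheticSample:
    """Render one labelled patch; malignant patches contain ≥1 positive pixel."""
    if class_label not in ("benign", "malignant"):
        raise ValueError(f"unknown class label {class_label!r}")
    rng = np.random.default_rng(seed)
    size = params.image_size
    area = size * size

    c_h = np.full((size, size), params.stroma_hematoxylin)
    c_e = np.full((size, size), params.stroma_eosin) * _smooth_field(
        rng, size, params.stroma_variation
    )
    mask = np.zeros((size, size), dtype=np.uint8)

    # sparse background nuclei in every patch
    n_bg = int(rng.poisson(params.benign_density * area))
    count = _place_nuclei(
        rng, c_h, c_e, params, n_bg, params.benign_radius, params.benign_eccentricity
    )

    if class_label == "malignant":
        n_clusters = int(rng.integers(params.cluster_count[0], params.cluster_count[1] + 1))
        region = np.zeros((size, size), dtype=bool)
        for _ in range(n_clusters):
            spread = rng.uniform(*params.cluster_spread)
            center = rng.uniform(0.2 * size, 0.8 * size, 2)
            ecc = rng.uniform(1.0, 1.6)
            angle = rng.uniform(0, np.pi)
            region |= _ellipse_mask(size, center, (spread, spread / ecc), angle)
        c_h[region] = params.tumor_hematoxylin
        c_e[region] = params.tumor_eosin
        n_in = max(1, int(rng.poisson(params.malignant_density * region.sum())))
        count += _place_nuclei(
            rng,
            c_h,
            c_e,
            params,
            n_in,
            params.malignant_radius,
            params.malignant_eccentricity,
            region=region,
        )
        mask[region] = 1

    od = (
        c_h[:, :, None] * params.stain_matrix.od_vectors[0]
        + c_e[:, :, None] * params.stain_matrix.od_vectors[1]
    )
    ramp = 1.0 + params.illumination_amplitude * (
        np.linspace(-1.0, 1.0, size)[None, :, None]
    )
    od = od * ramp
    if params.noise_sd > 0:
        od = od + rng.normal(0.0, params.noise_sd, od.shape)
    od = np.maximum(od, 0.0)
    image = od_to_rgb(od, params.stain_matrix.background_intensity)
    return SyntheticSample(
        image=image,
        mask=LabelMap(mask, list(CLASS_NAMES)),
        class_label=class_label,
        patient_id="unassigned",
        seed=seed,
        nucleus_count=count,
    )


def generate_dataset(
    params: SyntheticParams,
    n_per_class: int,
    seed: int,
    out_dir: str | Path,
    images_per_patient: int = 5,
) -> list[ManifestRecord]:
    """Write a balanced synthetic dataset (images, masks, manifest CSV).

    Files use the ``grouped`` manifest layout ``<class>/<patient>/<name>.png``
    with masks alongside as ``<name>_mask.png``.  Regeneration with the same
    (params, n, seed) is byte-identical.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be ≥ 1")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records = []
    for ci, cls in enumerate(("benign", "malignant")):
        for i in range(n_per_class):
            patient = f"{cls[0]}{i // images_per_patient + 1:03d}"
            sample = generate_sample(params, cls, seed=seed + 2 * i + ci * 2 * n_per_class)
            pdir = out_dir / cls / patient
            pdir.mkdir(parents=True, exist_ok=True)
            img_path = pdir / f"{cls}_{i:04d}.png"
            mask_path = pdir / f"{cls}_{i:04d}_mask.png"
            write_image(sample.image, img_path)
            write_image(sample.mask, mask_path)
            records.append(
                ManifestRecord(
                    image_path=str(img_path),
                    class_label=cls,
                    patient_id=patient,
                    magnification="none",
                    mask_path=str(mask_path),
                )
            )
    records.sort(key=lambda r: r.image_path)
    write_manifest(records, out_dir / "manifest.csv")
    return records


def corrupt_probability_map(
    mask: LabelMap | np.ndarray,
    flip_rate: float,
    blur_sd: float,
    seed: int,
    n_classes: int | None = None,
) -> np.ndarray:
    """Degrade a ground-truth mask into a noisy probability map.

    The one-hot mask gets Gaussian boundary blur (sd `blur_sd` pixels per
    channel) and a fraction `flip_rate` of pixels flipped to a confident
    wrong class, then rows are renormalized.  Deterministic given seed.
    """
    if not 0 <= flip_rate <= 1:
        raise ValueError("flip_rate must lie in [0, 1]")
    labels = np.asarray(getattr(mask, "labels", mask)).astype(int)
    c = n_classes or max(int(labels.max()) + 1, 2)
    rng = np.random.default_rng(seed)
    probs = np.eye(c)[labels].astype(float)
    if blur_sd > 0:
        for k in range(c):
            probs[:, :, k] = ndimage.gaussian_filter(probs[:, :, k], blur_sd)
    if flip_rate > 0:
        flip = rng.random(labels.shape) < flip_rate
        wrong = (labels + rng.integers(1, c, labels.shape)) % c
        onehot_wrong = np.eye(c)[wrong]
        probs[flip] = onehot_wrong[flip]
    total = np.maximum(probs.sum(axis=2, keepdims=True), 1e-12)
    return probs / total
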