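"""Raster and manifest I/O plus patient-grouped stratified splitting.

Images are 8-bit RGB PNG/TIFF; label masks are single-channel PNG with raw
class ids.  Manifests are CSV files with columns
``image_path,class_label,patient_id,magnification`` and splits are CSV with
``image_path,fold``.  Splits are always *patient-grouped*: all images of one
patient land on the same side of every partition, so no patient leaks
between training and validation folds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

__all__ = [
    "RgbImage",
    "LabelMap",
    "ManifestRecord",
    "FoldSplit",
    "read_image",
    "read_mask",
    "write_image",
    "build_manifest",
    "write_manifest",
    "read_manifest",
    "stratified_group_split",
    "kfold_split",
    "write_split",
]

IMAGE_SUFFIXES = {".png", ".tif", ".tiff"}
MAGNIFICATIONS = {"40x", "100x", "200x", "400x", "none"}


@dataclass
class RgbImage:
    """An 8-bit RGB raster (H, W, 3) with values in [0, 255]."""

    pixels: np.ndarray

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError(f"expected H×W×3 pixels, got shape {self.pixels.shape}")
        if self.pixels.dtype != np.uint8:
            if self.pixels.min() < 0 or self.pixels.max() > 255:
                raise ValueError("channel values outside [0, 255]")
            self.pixels = self.pixels.astype(np.uint8)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass
class LabelMap:
    """Integer class labels per pixel, values in {0..C-1}."""

    labels: np.ndarray
    class_names: list[str] = field(default_factory=lambda: ["background", "malignant"])

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("labels must be H×W")
        self.labels = self.labels.astype(np.uint8)
        if self.labels.max(initial=0) >= len(self.class_names):
            raise ValueError("pixel label outside class vocabulary")

    @property
    def num_classes(self) -> int:
        return len(self.class_names)


@dataclass
class ManifestRecord:
    image_path: str
    class_label: str
    patient_id: str
    magnification: str = "none"
    mask_path: str | None = None

    def __post_init__(self):
        if not self.patient_id:
            raise ValueError("patient_id must be non-empty")
        if self.magnification not in MAGNIFICATIONS:
            raise ValueError(f"unknown magnification {self.magnification!r}")


@dataclass
class FoldSplit:
    """record index -> fold id in {0..K-1}; K=2 means train(0)/validation(1)."""

    fold_assignments: np.ndarray
    n_folds: int

    def indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_assignments == fold)


# ---------------------------------------------------------------------------
# Raster I/O
# ---------------------------------------------------------------------------

def read_image(path: str | Path) -> RgbImage:
    """Read an 8-bit PNG/TIFF as RGB; grayscale sources are replicated."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with Image.open(path) as im:
        if im.mode in ("I;16", "I;16B", "I;16L", "I", "F"):
            raise ValueError(f"unsupported bit depth (mode {im.mode}) in {path}")
        if im.mode not in ("RGB", "L"):
            im = im.convert("RGB")
        arr = np.asarray(im)
    if arr.ndim == 2:
        arr = np.repeat(arr[:, :, None], 3, axis=2)
    return RgbImage(arr)


def read_mask(path: str | Path, class_names: list[str] | None = None) -> LabelMap:
    """Read a single-channel PNG of raw class ids."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with Image.open(path) as im:
        if im.mode != "L":
            raise ValueError(f"mask {path} is not single-channel 8-bit")
        arr = np.asarray(im)
    if class_names is None:
        class_names = [f"class{i}" for i in range(int(arr.max()) + 1)]
        if len(class_names) == 1:
            class_names.append("class1")
        class_names[0] = "background"
    return LabelMap(arr, class_names)


def write_image(image: RgbImage | LabelMap, path: str | Path) -> None:
    """Losslessly encode an image (RGB PNG/TIFF) or mask (grayscale PNG)."""
    path = Path(path)
    if not path.parent.exists():
        raise FileNotFoundError(f"parent directory {path.parent} does not exist")
    if isinstance(image, LabelMap):
        Image.fromarray(image.labels, mode="L").save(path)
    elif isinstance(image, RgbImage):
        Image.fromarray(image.pixels, mode="RGB").save(path)
    else:
        raise TypeError(f"cannot write object of type {type(image).__name__}")


# ---------------------------------------------------------------------------
# Manifests
# ---------------------------------------------------------------------------

def _parse_breakhis(path: Path, root: Path) -> tuple[str, str, str]:
    """BreakHis-style layout: .../{benign|malignant}/.../<slide-id>/<mag>/img.png.

    The patient id is the slide-id path segment (e.g. ``SOB_B_A_14-22549AB``)
    and the magnification the ``40X``-style directory when present.
    """
    parts = path.relative_to(root).parts
    cls = next((p for p in parts if p.lower() in ("benign", "malignant")), None)
    if cls is None:
        raise ValueError(f"file {path} matches no class rule for dialect 'breakhis'")
    mag = "none"
    patient = None
    for p in parts[:-1]:
        if p.lower() in ("40x", "100x", "200x", "400x"):
            mag = p.lower()
        if p.upper().startswith("SOB") or "-" in p:
            patient = p
    if patient is None:
        patient = parts[-2] if len(parts) >= 2 else path.stem
    return cls.lower(), patient, mag


def build_manifest(root: str | Path, layout: str = "grouped") -> list[ManifestRecord]:
    """Scan a directory tree into manifest records.

    Layouts:
      * ``grouped``:  root/<class>/<patient>/<image>
      * ``flat``:     root/<class>/<image>  (patient id = filename stem)
      * ``breakhis``: BreakHis-style benign|malignant trees with slide-id
        segments and magnification directories
    """
    root = Path(root)
    if not root.exists():
        raise FileNotFoundError(root)
    if layout not in ("grouped", "flat", "breakhis"):
        raise ValueError(f"unknown layout dialect {layout!r}")
    records = []
    files = sorted(
        p for p in root.rglob("*")
        if p.suffix.lower() in IMAGE_SUFFIXES and p.is_file()
        and not p.stem.endswith("_mask")
    )
    for path in files:
        rel = path.relative_to(root).parts
        if layout == "breakhis":
            cls, patient, mag = _parse_breakhis(path, root)
        elif layout == "grouped":
            if len(rel) < 3:
                raise ValueError(f"file {path} matches no class rule for dialect 'grouped'")
            cls, patient, mag = rel[0], rel[1], "none"
        else:  # flat
            if len(rel) < 2:
                raise ValueError(f"file {path} matches no class rule for dialect 'flat'")
            cls, patient, mag = rel[0], path.stem, "none"
        mask = path.with_name(path.stem + "_mask.png")
        records.append(
            ManifestRecord(
                image_path=str(path),
                class_label=cls,
                patient_id=patient,
                magnification=mag,
                mask_path=str(mask) if mask.exists() else None,
            )
        )
    return records


def write_manifest(records: list[ManifestRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "image_path": [r.image_path for r in records],
            "class_label": [r.class_label for r in records],
            "patient_id": [r.patient_id for r in records],
            "magnification": [r.magnification for r in records],
            "mask_path": [r.mask_path or "" for r in records],
        }
    )
    df.to_csv(path, index=False)


def read_manifest(path: str | Path) -> list[ManifestRecord]:
    df = pd.read_csv(path, dtype=str).fillna("")
    return [
        ManifestRecord(
            image_path=row.image_path,
            class_label=row.class_label,
            patient_id=row.patient_id,
            magnification=row.magnification or "none",
            mask_path=row.mask_path or None,
        )
        for row in df.itertuples()
    ]


# ---------------------------------------------------------------------------
# Patient-grouped stratified splitting
# ---------------------------------------------------------------------------

def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def _patient_groups(records: list[ManifestRecord]) -> dict[str, list[int]]:
    groups: dict[str, list[int]] = {}
    for i, r in enumerate(records):
        groups.setdefault(r.patient_id, []).append(i)
    return groups


def stratified_group_split(
    records: list[ManifestRecord], train_fraction: float, seed: int
) -> FoldSplit:
    """Two-way (train=fold 0 / validation=fold 1) patient-grouped split.

    Per class, the training side targets round(train_fraction × class size),
    rounding half away from zero, met as closely as whole-patient assignment
    allows (exactly when each record is its own patient).
    """
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    classes = sorted({r.class_label for r in records})
    if not classes:
        raise ValueError("no records to split")
    rng = np.random.default_rng(seed)
    assignment = np.full(len(records), -1, dtype=np.int64)

    # patients are split units; a patient's class is its majority class
    groups = _patient_groups(records)
    by_class: dict[str, list[tuple[str, list[int]]]] = {c: [] for c in classes}
    for pid in sorted(groups):
        idx = groups[pid]
        labels = [records[i].class_label for i in idx]
        major = max(sorted(set(labels)), key=labels.count)
        by_class[major].append((pid, idx))

    for cls in classes:
        cls_groups = by_class[cls]
        n_cls = sum(len(idx) for _, idx in cls_groups)
        if n_cls == 0:
            raise ValueError(f"class {cls!r} has zero records")
        target = _round_half_away(train_fraction * n_cls)
        if target <= 0 or target >= n_cls:
            raise ValueError(
                f"train_fraction {train_fraction} produces an empty partition for class {cls!r}"
            )
        order = rng.permutation(len(cls_groups))
        n_train = 0
        for gi in order:
            _, idx = cls_groups[gi]
            # take the group iff it brings the train count strictly closer to target
            if abs(n_train + len(idx) - target) < abs(n_train - target):
                assignment[idx] = 0
                n_train += len(idx)
            else:
                assignment[idx] = 1
        if (assignment[[i for _, idx in cls_groups for i in idx]] == 1).sum() == 0:
            raise ValueError(f"validation partition empty for class {cls!r}")
    return FoldSplit(assignment, 2)


def kfold_split(records: list[ManifestRecord], n_folds: int, seed: int) -> FoldSplit:
    """K patient-disjoint folds, class-balanced to within one patient group."""
    if n_folds < 2:
        raise ValueError("n_folds must be ≥ 2")
    classes = sorted({r.class_label for r in records})
    rng = np.random.default_rng(seed)
    assignment = np.full(len(records), -1, dtype=np.int64)

    groups = _patient_groups(records)
    by_class: dict[str, list[list[int]]] = {c: [] for c in classes}
    for pid in sorted(groups):
        idx = groups[pid]
        labels = [records[i].class_label for i in idx]
        major = max(sorted(set(labels)), key=labels.count)
        by_class[major].append(idx)

    for cls in classes:
        cls_groups = by_class[cls]
        if len(cls_groups) < n_folds:
            raise ValueError(
                f"class {cls!r} has {len(cls_groups)} patient groups, fewer than K={n_folds}"
            )
        order = rng.permutation(len(cls_groups))
        # largest groups first onto the lightest fold keeps folds balanced
        order = sorted(order, key=lambda gi: -len(cls_groups[gi]))
        fold_load = np.zeros(n_folds, dtype=np.int64)
        fold_count = np.zeros(n_folds, dtype=np.int64)  # groups per fold
        for gi in order:
            # fewest records; tie-break on fewest groups keeps ≥1 group per fold
            f = int(np.lexsort((fold_count, fold_load))[0])
            assignment[cls_groups[gi]] = f
            fold_load[f] += len(cls_groups[gi])
            fold_count[f] += 1
    return FoldSplit(assignment, n_folds)


def write_split(records: list[ManifestRecord], split: FoldSplit, path: str | Path) -> None:
    pd.DataFrame(
        {
            "image_path": [r.image_path for r in records],
            "fold": split.fold_assignments,
        }
    ).to_csv(path, index=False)
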