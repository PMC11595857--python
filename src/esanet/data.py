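"""Dataset ingestion, the augmentation pipeline, and a seeded synthetic
image generator.

Two on-disk layouts are supported for real data: the public crop
pest/disease release's JSON annotation dialect (an array of objects, each
holding an image identifier and an integer disease class in [0, 61)), and a
generic directory-per-class tree. Classes are treated as opaque integers
throughout.

Augmentation follows the published recipe: resize the shorter side to 256,
center-crop 224×224, random horizontal flip (training only, p = 0.5), scale
to [0, 1] and channel-normalize with the ImageNet statistics.

The synthetic generator draws, for every class, a distinct parametric
"lesion" pattern — a class-specific number of colored elliptical blobs on a
leaf-green background plus pixel noise — so that classes are separable by
design and every test can run without downloads. Generation is byte-exact
for equal seeds.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from collections import Counter
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from PIL import Image

from .training import ArrayDataset

IMAGENET_MEAN = np.array([0.485, 0.456, 0.406], dtype=np.float32)
IMAGENET_SD = np.array([0.229, 0.224, 0.225], dtype=np.float32)

NUM_DISEASE_CLASSES = 61


# ---------------------------------------------------------------------------
# Annotations
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AnnotationRecord:
    image_path: str
    disease_class: int


def read_annotations(annotation_file, num_classes: int = NUM_DISEASE_CLASSES,
                     check_paths: bool = False) -> list[AnnotationRecord]:
    """Parse a JSON annotation list into records.

    Accepts the public release's key names (``image_id``/``disease_class``)
    as well as ``image_path``/``label``. The class histogram is logged via a
    warning-free print hook only when imbalance is extreme; callers can
    recompute it with :func:`class_histogram`.
    """
    path = Path(annotation_file)
    entries = json.loads(path.read_text())
    if not isinstance(entries, list):
        raise ValueError(f"{path} must contain a JSON array of objects")
    records = []
    for i, e in enumerate(entries):
        if not isinstance(e, dict):
            raise ValueError(f"entry {i} is not an object")
        img = e.get("image_id", e.get("image_path"))
        cls = e.get("disease_class", e.get("label"))
        if img is None or cls is None:
            raise ValueError(f"entry {i} is missing an image id or class field")
        cls = int(cls)
        if not 0 <= cls < num_classes:
            raise ValueError(
                f"entry {i}: class {cls} outside [0, {num_classes})")
        if check_paths and not (path.parent / img).exists():
            raise FileNotFoundError(f"entry {i}: image {img} not found")
        records.append(AnnotationRecord(str(img), cls))
    return records


def class_histogram(records) -> dict[int, int]:
    return dict(sorted(Counter(r.disease_class for r in records).items()))


def read_image_folder(root) -> list[AnnotationRecord]:
    """Directory-per-class fallback reader: ``root/<class>/<image>``."""
    root = Path(root)
    records = []
    for cls_dir in sorted(root.iterdir()):
        if not cls_dir.is_dir():
            continue
        cls = int(cls_dir.name)
        for img in sorted(cls_dir.iterdir()):
            records.append(AnnotationRecord(
                str(img.relative_to(root)), cls))
    return records


# ---------------------------------------------------------------------------
# Transforms
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TransformConfig:
    resize_shorter: int = 256
    crop_size: int = 224
    mean: tuple[float, float, float] = tuple(IMAGENET_MEAN.tolist())
    sd: tuple[float, float, float] = tuple(IMAGENET_SD.tolist())


def _to_rgb(image: Image.Image) -> Image.Image:
    if image.mode != "RGB":
        warnings.warn(f"converting {image.mode} image to RGB", stacklevel=3)
        return image.convert("RGB")
    return image


def _resize_shorter(image: Image.Image, target: int) -> Image.Image:
    w, h = image.size
    if min(w, h) < target:
        warnings.warn("image smaller than the crop recipe; upscaling",
                      stacklevel=3)
    scale = target / min(w, h)
    return image.resize((max(1, round(w * scale)), max(1, round(h * scale))),
                        Image.BILINEAR)


def _center_crop(arr: np.ndarray, size: int) -> np.ndarray:
    h, w = arr.shape[:2]
    top = (h - size) // 2
    left = (w - size) // 2
    return arr[top:top + size, left:left + size]


def _normalize(arr: np.ndarray, cfg: TransformConfig) -> np.ndarray:
    x = arr.astype(np.float32) / 255.0
    x = (x - np.asarray(cfg.mean, np.float32)) / np.asarray(cfg.sd, np.float32)
    return np.transpose(x, (2, 0, 1)).astype(np.float32)  # HWC → CHW


def eval_transform(image: Image.Image,
                   cfg: TransformConfig = TransformConfig()) -> np.ndarray:
    """Deterministic pipeline: resize → center-crop → scale → normalize."""
    image = _to_rgb(image)
    image = _resize_shorter(image, cfg.resize_shorter)
    arr = _center_crop(np.asarray(image), cfg.crop_size)
    return _normalize(arr, cfg)


def train_transform(image: Image.Image, rng: np.random.Generator,
                    cfg: TransformConfig = TransformConfig()) -> np.ndarray:
    """Training pipeline: as :func:`eval_transform` plus a horizontal flip
    with probability 0.5 drawn from ``rng``."""
    image = _to_rgb(image)
    image = _resize_shorter(image, cfg.resize_shorter)
    arr = _center_crop(np.asarray(image), cfg.crop_size)
    if rng.random() < 0.5:
        arr = arr[:, ::-1]
    return _normalize(arr, cfg)


def denormalize(tensor: np.ndarray,
                cfg: TransformConfig = TransformConfig()) -> np.ndarray:
    """Invert :func:`_normalize`: CHW normalized tensor → HWC uint8 pixels."""
    x = np.transpose(tensor, (1, 2, 0))
    x = x * np.asarray(cfg.sd, np.float32) + np.asarray(cfg.mean, np.float32)
    return np.clip(np.round(x * 255.0), 0, 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# Synthetic data
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BlobParams:
    """Per-class lesion description: blob count, radius range, mean color."""

    count: int
    radius_range: tuple[float, float]
    rgb_mean: tuple[int, int, int]


def default_blob_params(num_classes: int) -> list[BlobParams]:
    """Deterministic, pairwise-distinct lesion parameters per class.

    Colors are spread around the hue circle and blob counts/radii cycle, so
    any two classes differ in at least the mean color.
    """
    params = []
    for c in range(num_classes):
        hue = (c * 360.0 / max(num_classes, 1)) % 360.0
        rgb = _hsv_to_rgb(hue, 0.85, 0.9)
        params.append(BlobParams(
            count=2 + (c % 4),
            radius_range=(0.06 + 0.02 * (c % 3), 0.12 + 0.03 * (c % 3)),
            rgb_mean=rgb))
    return params


def _hsv_to_rgb(h: float, s: float, v: float) -> tuple[int, int, int]:
    hh = (h / 60.0) % 6
    i = int(hh)
    f = hh - i
    p, q, t = v * (1 - s), v * (1 - s * f), v * (1 - s * (1 - f))
    r, g, b = [(v, t, p), (q, v, p), (p, v, t),
               (p, q, v), (t, p, v), (v, p, q)][i]
    return tuple(int(round(255 * x)) for x in (r, g, b))


@dataclass
class SyntheticDatasetSpec:
    num_classes: int = 5
    samples_per_class: int = 40
    image_size: int = 32
    blob_params: list[BlobParams] = field(default_factory=list)
    noise_sd: float = 12.0
    seed: int = 2022

    def __post_init__(self):
        if self.num_classes < 1 or self.samples_per_class < 0:
            raise ValueError("num_classes >= 1 and samples_per_class >= 0 required")
        if not self.blob_params:
            self.blob_params = default_blob_params(self.num_classes)
        if len(self.blob_params) != self.num_classes:
            raise ValueError("need one BlobParams per class")
        if len({bp.rgb_mean for bp in self.blob_params}) != self.num_classes:
            raise ValueError("blob parameters must be distinct per class")

    def to_dict(self) -> dict:
        d = asdict(self)
        return d


_BACKGROUND = np.array([60, 110, 45], dtype=np.float64)  # leaf green


def _render_image(bp: BlobParams, size: int, noise_sd: float,
                  rng: np.random.Generator) -> np.ndarray:
    img = np.tile(_BACKGROUND, (size, size, 1))
    yy, xx = np.mgrid[0:size, 0:size]
    for _ in range(bp.count):
        cy, cx = rng.uniform(0.15 * size, 0.85 * size, size=2)
        r = rng.uniform(*bp.radius_range) * size
        ry, rx = r * rng.uniform(0.7, 1.3), r * rng.uniform(0.7, 1.3)
        mask = ((yy - cy) / max(ry, 1e-6)) ** 2 + ((xx - cx) / max(rx, 1e-6)) ** 2 <= 1.0
        jitter = rng.normal(0, 12, size=3)
        img[mask] = np.clip(np.asarray(bp.rgb_mean, np.float64) + jitter, 0, 255)
    if noise_sd > 0:
        img = img + rng.normal(0, noise_sd, size=img.shape)
    return np.clip(np.round(img), 0, 255).astype(np.uint8)


def synthetic_arrays(spec: SyntheticDatasetSpec) -> tuple[np.ndarray, np.ndarray]:
    """In-memory synthetic set: uint8 images (N, H, W, 3) and labels (N,).

    Deterministic for a given spec (including its seed): the per-image RNG
    stream is derived from ``(seed, class, sample index)``.
    """
    images, labels = [], []
    for c in range(spec.num_classes):
        for i in range(spec.samples_per_class):
            rng = np.random.default_rng([spec.seed, c, i])
            images.append(_render_image(spec.blob_params[c], spec.image_size,
                                        spec.noise_sd, rng))
            labels.append(c)
    if not images:
        return (np.zeros((0, spec.image_size, spec.image_size, 3), np.uint8),
                np.zeros(0, np.int64))
    return np.stack(images), np.asarray(labels, np.int64)


def synthetic_dataset(spec: SyntheticDatasetSpec,
                      normalize: bool = True) -> ArrayDataset:
    """Synthetic set as a training-ready :class:`ArrayDataset` (CHW float)."""
    imgs, labels = synthetic_arrays(spec)
    x = imgs.astype(np.float32) / 255.0
    x = np.transpose(x, (0, 3, 1, 2))
    if normalize:
        x = (x - 0.5) / 0.5
    return ArrayDataset(x, labels)


def generate_synthetic_dataset(spec: SyntheticDatasetSpec, out_dir):
    """Write the synthetic set to disk in both supported layouts.

    Emits ``images/<class>/<name>.png`` (directory-per-class),
    ``annotations.json`` (the JSON dialect, paths relative to ``out_dir``)
    and ``manifest.json`` (the spec plus per-file SHA-256 checksums).
    Returns the list of :class:`AnnotationRecord` written.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    imgs, labels = synthetic_arrays(spec)
    records, checksums = [], {}
    for c in range(spec.num_classes):
        (out / "images" / str(c)).mkdir(parents=True, exist_ok=True)
    for i, (img, c) in enumerate(zip(imgs, labels)):
        rel = f"images/{c}/{i:05d}.png"
        Image.fromarray(img).save(out / rel)
        checksums[rel] = hashlib.sha256((out / rel).read_bytes()).hexdigest()
        records.append(AnnotationRecord(rel, int(c)))
    (out / "annotations.json").write_text(json.dumps(
        [{"image_id": r.image_path, "disease_class": r.disease_class}
         for r in records], indent=1))
    (out / "manifest.json").write_text(json.dumps(
        {"spec": spec.to_dict(), "checksums": checksums}, indent=1))
    return records
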