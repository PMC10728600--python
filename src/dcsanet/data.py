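"""Dataset preprocessing: LabelMe polygon rasterization, random 512x512
cropping, the x5 augmentation expansion, and the 6:3:1 split.

Classes: 0 = background, 1 = soybean, 2 = graminoid weed, 3 = broadleaf
weed.  Images are H x W x 3 uint8; masks are H x W uint8 index maps stored
as single-channel PNG.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image, ImageDraw

__all__ = [
    "CLASS_NAMES",
    "CLASS_INDEX",
    "AnnotationRecord",
    "SegmentationSample",
    "DatasetSplit",
    "LabelingError",
    "rasterize_annotation",
    "random_crop",
    "augment_dataset",
    "split_dataset",
    "load_labelme_json",
    "read_mask_png",
    "write_mask_png",
    "write_split_manifest",
]

CLASS_NAMES = ("background", "soybean", "graminoid_weed", "broadleaf_weed")
CLASS_INDEX = {name: i for i, name in enumerate(CLASS_NAMES)}
NUM_CLASSES = len(CLASS_NAMES)


class LabelingError(ValueError):
    """Raised for annotations with unknown class names or malformed polygons."""


@dataclass
class AnnotationRecord:
    """One image's polygon annotations: (class_name, [(x, y), ...]) pairs."""

    image_path: str
    polygons: list  # list[(class_name, list[(x, y)])]

    def __post_init__(self):
        for name, points in self.polygons:
            if name not in CLASS_INDEX or name == "background":
                raise LabelingError(
                    f"unknown class {name!r} in {self.image_path} "
                    f"(expected one of {CLASS_NAMES[1:]})"
                )
            if len(points) < 3:
                raise LabelingError(
                    f"polygon for {name!r} in {self.image_path} has fewer than 3 vertices"
                )


@dataclass
class SegmentationSample:
    """RGB image paired with its integer label mask."""

    image: np.ndarray  # (H, W, 3) uint8
    mask: np.ndarray  # (H, W) uint8 in {0..3}
    provenance: str = "original"

    def __post_init__(self):
        if self.image.shape[:2] != self.mask.shape:
            raise ValueError(
                f"image {self.image.shape[:2]} and mask {self.mask.shape} shapes differ"
            )


@dataclass
class DatasetSplit:
    train: list
    val: list
    test: list
    seed: int

    def __iter__(self):
        yield from (self.train, self.val, self.test)


def rasterize_annotation(rec: AnnotationRecord, height: int, width: int) -> np.ndarray:
    """Fill polygon interiors with class indices; later polygons overwrite.

    The fill convention is PIL's: boundary pixels are included, so an
    axis-aligned square with corners (0,0) and (k,k) covers (k+1)^2 pixels.
    Vertices outside the canvas are effectively clipped by the raster.
    """
    canvas = Image.new("L", (width, height), 0)
    draw = ImageDraw.Draw(canvas)
    for name, points in rec.polygons:
        draw.polygon([(float(x), float(y)) for x, y in points], fill=CLASS_INDEX[name])
    return np.asarray(canvas, dtype=np.uint8)


def random_crop(sample: SegmentationSample, size: int, rng: np.random.Generator) -> SegmentationSample:
    """Crop a size x size window, uniform over valid positions, same window
    for image and mask."""
    h, w = sample.mask.shape
    if h < size or w < size:
        raise ValueError(f"source {h}x{w} smaller than crop size {size}")
    top = int(rng.integers(0, h - size + 1))
    left = int(rng.integers(0, w - size + 1))
    return SegmentationSample(
        image=sample.image[top : top + size, left : left + size].copy(),
        mask=sample.mask[top : top + size, left : left + size].copy(),
        provenance=f"{sample.provenance}+crop",
    )


# -- the four augmentation transforms ---------------------------------------


def _rotate(sample, rng):
    k = int(rng.choice([1, 2, 3]))  # 90, 180, 270 degrees
    return SegmentationSample(
        image=np.ascontiguousarray(np.rot90(sample.image, k)),
        mask=np.ascontiguousarray(np.rot90(sample.mask, k)),
        provenance="rotate",
    )


def _flip(sample, rng):
    axis = int(rng.choice([0, 1]))  # vertical or horizontal
    return SegmentationSample(
        image=np.ascontiguousarray(np.flip(sample.image, axis)),
        mask=np.ascontiguousarray(np.flip(sample.mask, axis)),
        provenance="flip",
    )


def _gaussian_noise(sample, rng, sigma=10.0):
    noisy = sample.image.astype(np.float32) + rng.normal(0, sigma, sample.image.shape)
    return SegmentationSample(
        image=np.clip(noisy, 0, 255).astype(np.uint8),
        mask=sample.mask.copy(),
        provenance="noise",
    )


def _contrast(sample, rng):
    gain = float(rng.uniform(1.1, 1.5))
    mean = sample.image.mean(axis=(0, 1), keepdims=True)
    adjusted = (sample.image.astype(np.float32) - mean) * gain + mean
    return SegmentationSample(
        image=np.clip(adjusted, 0, 255).astype(np.uint8),
        mask=sample.mask.copy(),
        provenance="contrast",
    )


def augment_dataset(samples, rng: np.random.Generator):
    """Each sample yields itself plus four derived samples (rotation, flip,
    Gaussian noise, contrast); geometric transforms are applied identically
    to the mask.  Expansion factor is exactly 5."""
    samples = list(samples)
    if not samples:
        raise ValueError("augment_dataset requires a nonempty input")
    out = []
    for s in samples:
        out.append(s)
        out.append(_rotate(s, rng))
        out.append(_flip(s, rng))
        out.append(_gaussian_noise(s, rng))
        out.append(_contrast(s, rng))
    return out


def split_dataset(samples, seed: int, ratios=(6, 3, 1)) -> DatasetSplit:
    """Shuffle by seed; first 60% train, next 30% val, remainder test.

    The first two cut points are floored; the test set takes the remainder.
    """
    samples = list(samples)
    n = len(samples)
    if n < 10:
        raise ValueError(f"need at least 10 samples to split, got {n}")
    total = sum(ratios)
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_train = n * ratios[0] // total
    n_val = n * ratios[1] // total
    train = [samples[i] for i in order[:n_train]]
    val = [samples[i] for i in order[n_train : n_train + n_val]]
    test = [samples[i] for i in order[n_train + n_val :]]
    return DatasetSplit(train=train, val=val, test=test, seed=seed)


# -- file formats ------------------------------------------------------------


def load_labelme_json(path) -> AnnotationRecord:
    """Read a LabelMe annotation file (fields imagePath, shapes[].label,
    shapes[].points)."""
    with open(path) as fh:
        payload = json.load(fh)
    polygons = [
        (shape["label"], [tuple(pt) for pt in shape["points"]])
        for shape in payload.get("shapes", [])
    ]
    return AnnotationRecord(image_path=payload.get("imagePath", str(path)), polygons=polygons)


def write_mask_png(mask: np.ndarray, path):
    Image.fromarray(mask.astype(np.uint8), mode="L").save(path)


def read_mask_png(path) -> np.ndarray:
    mask = np.asarray(Image.open(path).convert("L"), dtype=np.uint8)
    if mask.max() >= NUM_CLASSES:
        raise ValueError(f"mask {path} contains labels outside {{0..{NUM_CLASSES - 1}}}")
    return mask


def write_split_manifest(split: DatasetSplit, paths_by_subset, path):
    """CSV manifest: path, subset, provenance."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["path", "subset", "provenance"])
        for subset, (samples, paths) in paths_by_subset.items():
            for s, p in zip(samples, paths):
                writer.writerow([p, subset, s.provenance])
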