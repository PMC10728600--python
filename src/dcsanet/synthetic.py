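"""Synthetic field scenes with exact ground-truth masks.

Each scene emulates the structure of a nadir soybean-field photograph:

* a noise-textured brown soil background,
* soybean plants as clustered triplets of green ellipses (leaflet-like),
* graminoid weeds as thin curved strokes (2-5 px wide) that deliberately
  share the soybean hue, so the two classes separate by shape rather than
  by a trivial colour lookup,
* broadleaf weeds as broad lobed polygons in a distinct green.

The mask is the exact generator geometry (no annotation noise).  Objects
are placed until each class reaches its target pixel fraction; with a
positive ``occlusion_rate`` some objects are centred on already-occupied
pixels, and the later-drawn class owns the overlap.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image, ImageDraw
from scipy import ndimage

from .data import SegmentationSample, write_mask_png

__all__ = ["SceneSpec", "generate_scene", "generate_dataset", "write_dataset"]

# base colours (R, G, B); graminoid = soybean scaled (same hue, darker)
SOIL = np.array([118.0, 92.0, 62.0])
SOYBEAN = np.array([62.0, 134.0, 58.0])
GRAMINOID = SOYBEAN * 0.78
BROADLEAF = np.array([96.0, 156.0, 70.0])


@dataclass(frozen=True)
class SceneSpec:
    """Scene geometry and class-budget specification."""

    size: int = 512
    target_fractions: dict = field(
        default_factory=lambda: {"soybean": 0.22, "graminoid_weed": 0.08, "broadleaf_weed": 0.10}
    )
    occlusion_rate: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if self.size % 32:
            raise ValueError(f"size must be divisible by 32, got {self.size}")
        total = sum(self.target_fractions.values())
        if total > 1.0:
            raise ValueError(f"target fractions sum to {total:.3f} > 1")
        if not 0.0 <= self.occlusion_rate <= 1.0:
            raise ValueError("occlusion_rate must be in [0, 1]")


def _rotated_ellipse(draw, cx, cy, a, b, angle, value):
    t = np.linspace(0, 2 * np.pi, 24, endpoint=False)
    ca, sa = np.cos(angle), np.sin(angle)
    xs = cx + a * np.cos(t) * ca - b * np.sin(t) * sa
    ys = cy + a * np.cos(t) * sa + b * np.sin(t) * ca
    draw.polygon(list(zip(xs.tolist(), ys.tolist())), fill=value)


def _draw_soybean(draw, rng, cx, cy, scale):
    """Trifoliate plant: three ellipse leaflets around a centre."""
    base = rng.uniform(0, 2 * np.pi)
    for k in range(3):
        ang = base + k * 2 * np.pi / 3 + rng.normal(0, 0.15)
        r = scale * rng.uniform(0.7, 1.0)
        lx, ly = cx + r * np.cos(ang), cy + r * np.sin(ang)
        _rotated_ellipse(draw, lx, ly, r * 0.9, r * 0.5, ang, 1)


def _draw_graminoid(draw, rng, cx, cy, size):
    """Thin curved stroke: quadratic Bezier, width 2-5 px."""
    length = size * rng.uniform(0.2, 0.45)
    ang = rng.uniform(0, 2 * np.pi)
    x1 = cx + length * np.cos(ang)
    y1 = cy + length * np.sin(ang)
    # control point off the chord bends the blade
    mx = (cx + x1) / 2 + rng.normal(0, 0.25 * length)
    my = (cy + y1) / 2 + rng.normal(0, 0.25 * length)
    width = int(rng.integers(2, 6))
    t = np.linspace(0, 1, 24)
    xs = (1 - t) ** 2 * cx + 2 * (1 - t) * t * mx + t**2 * x1
    ys = (1 - t) ** 2 * cy + 2 * (1 - t) * t * my + t**2 * y1
    draw.line(list(zip(xs.tolist(), ys.tolist())), fill=2, width=width, joint="curve")


def _draw_broadleaf(draw, rng, cx, cy, scale):
    """Broad lobed blade: radial polygon r(theta) = R (1 + 0.35 sin k theta)."""
    k = int(rng.integers(4, 7))
    phase = rng.uniform(0, 2 * np.pi)
    t = np.linspace(0, 2 * np.pi, 48, endpoint=False)
    r = scale * (1 + 0.35 * np.sin(k * t + phase)) * rng.uniform(0.8, 1.0)
    xs = cx + r * np.cos(t)
    ys = cy + r * np.sin(t)
    draw.polygon(list(zip(xs.tolist(), ys.tolist())), fill=3)


_DRAWERS = {1: _draw_soybean, 2: _draw_graminoid, 3: _draw_broadleaf}
_FRACTION_KEYS = {1: "soybean", 2: "graminoid_weed", 3: "broadleaf_weed"}


def generate_scene(spec: SceneSpec) -> SegmentationSample:
    """Render one scene and its exact mask; deterministic in ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    size = spec.size
    canvas = Image.new("L", (size, size), 0)
    draw = ImageDraw.Draw(canvas)

    scale0 = size / 512.0
    # several passes: later classes overwrite earlier ones in overlaps, so
    # earlier classes are topped up in the next round until fractions settle
    for cls in (1, 2, 3) * 3:
        target = spec.target_fractions.get(_FRACTION_KEYS[cls], 0.0)
        if target <= 0:
            continue
        drawer = _DRAWERS[cls]
        for _ in range(400):
            mask_now = np.asarray(canvas)
            frac = (mask_now == cls).mean()
            if frac >= target * 0.98:
                break
            occlude = rng.uniform() < spec.occlusion_rate and (mask_now > 0).any()
            if occlude:
                ys, xs = np.nonzero(mask_now)
                j = int(rng.integers(len(xs)))
                cx, cy = float(xs[j]), float(ys[j])
            else:
                cx, cy = rng.uniform(0, size), rng.uniform(0, size)
            remaining = target - frac
            if cls == 2:
                drawer(draw, rng, cx, cy, size)
            else:
                # shrink objects as the budget runs out to avoid overshoot
                cap = max(6.0 * scale0, np.sqrt(remaining * size * size / 3.0))
                obj_scale = min(scale0 * rng.uniform(14, 30), cap)
                drawer(draw, rng, cx, cy, obj_scale)

    mask = np.asarray(canvas, dtype=np.uint8)

    # ---- paint the image ---------------------------------------------------
    image = np.empty((size, size, 3), dtype=np.float64)
    image[:] = SOIL
    # low-frequency soil mottling plus per-pixel grain
    coarse = ndimage.zoom(rng.normal(0, 14, (size // 16, size // 16)), 16, order=1)
    image += coarse[:size, :size, None]
    for cls, colour in ((1, SOYBEAN), (2, GRAMINOID), (3, BROADLEAF)):
        sel = mask == cls
        jitter = rng.normal(0, 7, (3,))
        image[sel] = colour + jitter
    image += rng.normal(0, 6, image.shape)
    # slight blur softens object boundaries (camera-like anti-aliasing);
    # the mask stays exact
    image = ndimage.gaussian_filter(image, sigma=(0.6, 0.6, 0))
    image = np.clip(image, 0, 255).astype(np.uint8)
    return SegmentationSample(image=image, mask=mask, provenance=f"synthetic:{spec.seed}")


def generate_dataset(n: int, spec: SceneSpec, seed: int):
    """Generate ``n`` scenes from independent seed streams.

    Returns (samples, manifest); the manifest records per-scene seeds and
    achieved class fractions and is identical across runs with the same
    (n, seed).
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    child_seeds = [int(s) for s in np.random.SeedSequence(seed).generate_state(n) % (2**31)]
    samples, entries = [], []
    for scene_seed in child_seeds:
        scene_spec = SceneSpec(
            size=spec.size,
            target_fractions=dict(spec.target_fractions),
            occlusion_rate=spec.occlusion_rate,
            seed=scene_seed,
        )
        sample = generate_scene(scene_spec)
        fractions = {
            name: float((sample.mask == cls).mean()) for cls, name in _FRACTION_KEYS.items()
        }
        fractions["background"] = float((sample.mask == 0).mean())
        samples.append(sample)
        entries.append({"seed": scene_seed, "fractions": fractions})
    manifest = {
        "n": n,
        "seed": seed,
        "spec": {
            "size": spec.size,
            "target_fractions": dict(spec.target_fractions),
            "occlusion_rate": spec.occlusion_rate,
        },
        "scenes": entries,
    }
    return samples, manifest


def write_dataset(samples, manifest, out_dir):
    """Write image/mask PNG pairs plus the JSON manifest."""
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(parents=True, exist_ok=True)
    for i, s in enumerate(samples):
        Image.fromarray(s.image).save(out / "images" / f"scene_{i:04d}.png")
        write_mask_png(s.mask, out / "masks" / f"scene_{i:04d}.png")
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return out / "manifest.json"
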