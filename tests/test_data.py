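"""Preprocessing pipeline: rasterization, cropping, augmentation, splitting."""

import json

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dcsanet import (
    AnnotationRecord,
    SegmentationSample,
    augment_dataset,
    random_crop,
    rasterize_annotation,
    split_dataset,
)
from dcsanet.data import LabelingError, load_labelme_json, read_mask_png, write_mask_png


def _sample(rng, size=32):
    image = rng.integers(0, 256, (size, size, 3), dtype=np.uint8)
    mask = rng.integers(0, 4, (size, size)).astype(np.uint8)
    return SegmentationSample(image=image, mask=mask)


# ---------------------------------------------------------------------------
# rasterization


def test_rasterize_empty_annotation_is_all_background():
    rec = AnnotationRecord(image_path="x.jpg", polygons=[])
    assert not rasterize_annotation(rec, 50, 50).any()


def test_rasterize_square_pixel_count():
    # axis-aligned square covering exactly 25% of a 100x100 image
    square = [(0, 0), (49, 0), (49, 49), (0, 49)]
    rec = AnnotationRecord(image_path="x.jpg", polygons=[("soybean", square)])
    mask = rasterize_annotation(rec, 100, 100)
    assert (mask == 1).sum() == 2500
    assert (mask == 0).sum() == 7500


def test_rasterize_square_matches_skimage_oracle():
    """Independent fill oracle on an axis-aligned polygon."""
    from skimage.draw import polygon as sk_polygon

    square = [(10, 5), (39, 5), (39, 24), (10, 24)]
    rec = AnnotationRecord(image_path="x.jpg", polygons=[("broadleaf_weed", square)])
    mask = rasterize_annotation(rec, 40, 50)
    rr, cc = sk_polygon([5, 5, 24, 24], [10, 39, 39, 10], shape=(40, 50))
    oracle = np.zeros((40, 50), dtype=np.uint8)
    oracle[rr, cc] = 3
    # conventions may differ on the one-pixel boundary band only
    disagree = mask != oracle
    interior = np.zeros_like(mask, dtype=bool)
    interior[7:23, 12:38] = True
    assert not disagree[interior].any()


def test_rasterize_later_polygon_overwrites():
    a = [(0, 0), (19, 0), (19, 19), (0, 19)]
    b = [(10, 10), (29, 10), (29, 29), (10, 29)]
    rec = AnnotationRecord(image_path="x.jpg", polygons=[("soybean", a), ("graminoid_weed", b)])
    mask = rasterize_annotation(rec, 40, 40)
    assert mask[15, 15] == 2  # overlap carries the later class
    assert mask[5, 5] == 1


def test_rasterize_unknown_class_is_labeling_error():
    with pytest.raises(LabelingError):
        AnnotationRecord(image_path="x.jpg", polygons=[("thistle", [(0, 0), (1, 0), (1, 1)])])


def test_rasterize_too_few_vertices():
    with pytest.raises(LabelingError):
        AnnotationRecord(image_path="x.jpg", polygons=[("soybean", [(0, 0), (1, 1)])])


def test_rasterize_flip_commutes_up_to_boundary(rng):
    """Rasterize-then-flip equals flip-vertices-then-rasterize away from
    a one-pixel boundary band."""
    from scipy import ndimage

    pts = [(5, 7), (40, 12), (33, 38), (12, 30)]
    rec = AnnotationRecord(image_path="x", polygons=[("soybean", pts)])
    mask = rasterize_annotation(rec, 48, 48)
    flipped_pts = [(47 - x, y) for x, y in pts]
    rec2 = AnnotationRecord(image_path="x", polygons=[("soybean", flipped_pts)])
    mask2 = rasterize_annotation(rec2, 48, 48)
    direct = mask[:, ::-1]
    disagree = direct != mask2
    # all disagreements must touch the polygon boundary (1-px tolerance band)
    edge = ndimage.binary_dilation(direct == 1, iterations=1) & ~ndimage.binary_erosion(
        direct == 1, iterations=1
    )
    assert not (disagree & ~edge).any()


# ---------------------------------------------------------------------------
# cropping


def test_random_crop_shape_and_pairing(rng):
    src = _sample(rng, size=64)
    out = random_crop(src, 32, rng)
    assert out.image.shape == (32, 32, 3) and out.mask.shape == (32, 32)


def test_random_crop_identity_when_exact(rng):
    src = _sample(rng, size=32)
    out = random_crop(src, 32, rng)
    assert np.array_equal(out.image, src.image) and np.array_equal(out.mask, src.mask)


def test_random_crop_window_consistency(rng):
    src = _sample(rng, size=64)
    src.image[:, :, 0] = src.mask * 60  # tie image to mask
    out = random_crop(src, 16, rng)
    assert np.array_equal(out.image[:, :, 0], out.mask * 60)


def test_random_crop_deterministic_per_seed(rng):
    src = _sample(rng, size=64)
    a = random_crop(src, 32, np.random.default_rng(5))
    b = random_crop(src, 32, np.random.default_rng(5))
    assert np.array_equal(a.image, b.image)


def test_random_crop_too_small_errors(rng):
    with pytest.raises(ValueError):
        random_crop(_sample(rng, size=16), 32, rng)


# ---------------------------------------------------------------------------
# augmentation


@pytest.mark.parametrize("n", [1, 7])
def test_augmentation_factor_exactly_five(rng, n):
    out = augment_dataset([_sample(rng) for _ in range(n)], rng)
    assert len(out) == 5 * n


def test_augmentation_482_to_2410(rng):
    samples = [_sample(rng, size=8) for _ in range(482)]
    assert len(augment_dataset(samples, rng)) == 2410


def test_augmentation_preserves_alphabet_and_pairing(rng):
    out = augment_dataset([_sample(rng)], rng)
    for s in out:
        assert s.image.shape[:2] == s.mask.shape
        assert s.image.dtype == np.uint8
        assert set(np.unique(s.mask)) <= {0, 1, 2, 3}


def test_augmentation_geometric_transforms_pair_mask(rng):
    src = _sample(rng)
    out = augment_dataset([src], rng)
    provs = [s.provenance for s in out]
    assert provs[0] == "original"
    flip = out[provs.index("flip")]
    assert np.array_equal(flip.mask, src.mask[::-1]) or np.array_equal(
        flip.mask, src.mask[:, ::-1]
    )
    noise = out[provs.index("noise")]
    assert np.array_equal(noise.mask, src.mask)  # photometric leaves mask alone


def test_augmentation_empty_input_errors(rng):
    with pytest.raises(ValueError):
        augment_dataset([], rng)


# ---------------------------------------------------------------------------
# splitting


def test_split_2410_gives_paper_sizes(rng):
    samples = list(range(2410))
    split = split_dataset(samples, seed=3)
    assert (len(split.train), len(split.val), len(split.test)) == (1446, 723, 241)


def test_split_ten_samples(rng):
    split = split_dataset(list(range(10)), seed=0)
    assert (len(split.train), len(split.val), len(split.test)) == (6, 3, 1)


def test_split_deterministic_and_disjoint():
    samples = list(range(100))
    a = split_dataset(samples, seed=9)
    b = split_dataset(samples, seed=9)
    assert a.train == b.train and a.val == b.val and a.test == b.test
    assert sorted(a.train + a.val + a.test) == samples


def test_split_too_few_errors():
    with pytest.raises(ValueError):
        split_dataset(list(range(9)), seed=0)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(10, 500), st.integers(0, 1000))
def test_split_sizes_follow_floor_rule(n, seed):
    split = split_dataset(list(range(n)), seed=seed)
    assert len(split.train) == n * 6 // 10
    assert len(split.val) == n * 3 // 10
    assert len(split.test) == n - len(split.train) - len(split.val)
    assert sorted(split.train + split.val + split.test) == list(range(n))


# ---------------------------------------------------------------------------
# file formats


def test_mask_png_roundtrip(tmp_path, rng):
    mask = rng.integers(0, 4, (16, 16)).astype(np.uint8)
    write_mask_png(mask, tmp_path / "m.png")
    assert np.array_equal(read_mask_png(tmp_path / "m.png"), mask)


def test_labelme_json_roundtrip(tmp_path):
    payload = {
        "imagePath": "field_001.jpg",
        "shapes": [
            {"label": "soybean", "points": [[0, 0], [10, 0], [10, 10]]},
            {"label": "broadleaf_weed", "points": [[5, 5], [20, 5], [20, 20], [5, 20]]},
        ],
    }
    path = tmp_path / "field_001.json"
    path.write_text(json.dumps(payload))
    rec = load_labelme_json(path)
    assert rec.image_path == "field_001.jpg"
    assert rec.polygons[0][0] == "soybean"
    assert len(rec.polygons) == 2
    mask = rasterize_annotation(rec, 30, 30)
    assert set(np.unique(mask)) == {0, 1, 3}
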