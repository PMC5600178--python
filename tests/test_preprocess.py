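import numpy as np
import pytest
from scipy import ndimage as ndi

import leafmorph as lm
from leafmorph.preprocess import (
    to_grayscale,
    segment,
    clean_and_crop,
    preprocess,
    trace_boundary,
    chain_perimeter,
)
from leafmorph.errors import InvalidInputError, EmptySegmentationError

from conftest import rect_mask


def uniform_rgb(r, g, b, size=32):
    img = np.zeros((size, size, 3), dtype=np.uint8)
    img[..., 0], img[..., 1], img[..., 2] = r, g, b
    return img


class TestToGrayscale:
    @pytest.mark.parametrize(
        "rgb,expected",
        [
            ((255, 255, 255), 255.0),
            ((0, 0, 0), 0.0),
            # luminance oracle: 0.2989*120 + 0.5870*60 + 0.1141*30
            ((120, 60, 30), 0.2989 * 120 + 0.5870 * 60 + 0.1141 * 30),
        ],
    )
    def test_uniform_images(self, rgb, expected):
        gray = to_grayscale(uniform_rgb(*rgb))
        assert gray.shape == (32, 32)
        assert np.allclose(gray, expected, atol=1e-10)

    def test_small_image_rejected(self):
        with pytest.raises(InvalidInputError):
            to_grayscale(np.zeros((4, 4, 3), dtype=np.uint8))

    def test_out_of_range_rejected(self):
        img = np.full((16, 16, 3), 300.0)
        with pytest.raises(InvalidInputError):
            to_grayscale(img)


class TestSegment:
    def test_dark_ellipse_recovered(self):
        yy, xx = np.mgrid[:120, :160]
        painted = ((xx - 80) / 50) ** 2 + ((yy - 60) / 30) ** 2 <= 1
        gray = np.where(painted, 40.0, 230.0)
        mask = segment(gray)
        assert abs(mask.sum() - painted.sum()) / painted.sum() < 0.05

    def test_constant_image_is_empty_segmentation(self):
        with pytest.raises(EmptySegmentationError) as exc:
            segment(np.full((64, 64), 128.0))
        assert "sigma" in str(exc.value)  # names the thresholds used

    def test_interior_speck_absorbed(self):
        yy, xx = np.mgrid[:120, :160]
        painted = ((xx - 80) / 50) ** 2 + ((yy - 60) / 30) ** 2 <= 1
        gray = np.where(painted, 40.0, 230.0)
        gray[60, 80] = 220.0  # 1-px bright speck inside the blade
        mask = segment(gray)
        holes = ndi.binary_fill_holes(mask) & ~mask
        assert holes.sum() == 0

    def test_bad_thresholds_rejected(self):
        with pytest.raises(InvalidInputError):
            segment(np.zeros((32, 32)), low=0.3, high=0.2)


class TestCleanAndCrop:
    def test_single_square(self):
        roi = clean_and_crop(rect_mask(50, 50))
        assert roi.mask.sum() == 2500
        # chain-code perimeter of an axis-aligned square: 4 * (side - 1)
        assert chain_perimeter(roi.contour) == 4 * 49

    def test_small_blob_removed(self):
        mask = rect_mask(40, 25, pad=6)  # 1000-px blob
        mask[1, 1:6] = True  # 5-px debris
        n_before = ndi.label(mask, structure=np.ones((3, 3)))[1]
        roi = clean_and_crop(mask)
        n_after = ndi.label(roi.mask, structure=np.ones((3, 3)))[1]
        assert (n_before, n_after) == (2, 1)
        assert roi.mask.sum() == 1000

    def test_equal_blobs_tie_break_topmost_leftmost(self):
        mask = np.zeros((60, 60), bool)
        mask[5:15, 5:15] = True  # topmost-leftmost
        mask[40:50, 40:50] = True  # equal area
        roi = clean_and_crop(mask)
        assert roi.mask.sum() == 100
        assert roi.offset == (3, 3)  # 5 - margin 2

    def test_empty_mask_rejected(self):
        with pytest.raises(EmptySegmentationError):
            clean_and_crop(np.zeros((10, 10), bool))


class TestPreprocess:
    def test_roi_area_close_to_ground_truth(self):
        img, gt = lm.generate_leaf(lm.LeafParams(), seed=11)
        roi = preprocess(img)
        assert abs(roi.area - gt.sum()) / gt.sum() < 0.05

    def test_deterministic(self):
        img, _ = lm.generate_leaf(lm.LeafParams(), seed=5)
        r1, r2 = preprocess(img), preprocess(img)
        assert np.array_equal(r1.mask, r2.mask)
        assert r1.offset == r2.offset
        assert np.array_equal(r1.contour, r2.contour)

    def test_tiny_image_rejected(self):
        with pytest.raises(InvalidInputError):
            preprocess(np.zeros((4, 4, 3), dtype=np.uint8))

    def test_idempotence_on_clean_silhouette(self):
        """Rendering an already-clean mask and re-running the pipeline
        recovers the same foreground up to the crop margin."""
        _, gt = lm.generate_leaf(lm.LeafParams(aspect=2.0), seed=9)
        render = np.where(gt, 40, 240).astype(np.uint8)
        rgb = np.stack([render] * 3, axis=-1)
        roi = preprocess(rgb)
        rows, cols = np.nonzero(gt)
        gt_crop = gt[
            max(rows.min() - 2, 0) : rows.max() + 3,
            max(cols.min() - 2, 0) : cols.max() + 3,
        ]
        assert roi.mask.shape == gt_crop.shape
        agree = (roi.mask == gt_crop).mean()
        assert agree > 0.99

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_single_component_and_hole_free(self, seed):
        img, _ = lm.generate_leaf(
            lm.LeafParams(lobe_count=4, lobe_depth=0.3, serration_amp=0.08),
            seed=seed,
        )
        roi = preprocess(img)
        n = ndi.label(roi.mask, structure=np.ones((3, 3)))[1]
        assert n == 1
        # flood fill from the border reaches every background pixel
        holes = ndi.binary_fill_holes(roi.mask) & ~roi.mask
        assert holes.sum() == 0


class TestBoundaryTrace:
    def test_closed_chain(self):
        contour = trace_boundary(rect_mask(10, 7))
        step = np.abs(contour[0] - contour[-1])
        assert step.max() <= 1  # closed: last pixel adjacent to first

    def test_ccw_orientation(self):
        contour = trace_boundary(rect_mask(10, 10))
        x = contour[:, 1].astype(float)
        y = -contour[:, 0].astype(float)
        signed2 = np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
        assert signed2 > 0

    def test_roundtrip_io(self, tmp_path):
        roi = clean_and_crop(rect_mask(12, 9))
        lm.save_roi(roi, tmp_path / "roi.png", lm.PreprocessConfig())
        back = lm.load_roi(tmp_path / "roi.png")
        assert np.array_equal(back.mask, roi.mask)
        assert tuple(back.offset) == roi.offset
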