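"""Segmentation and calibrated measurement of leaf silhouettes."""

import numpy as np
import pytest

from palmleaf import (
    LeafImage,
    LeafMask,
    SegmentationConfig,
    SyntheticLeafSpec,
    calibrate_scale,
    generate_leaf,
    measure_area,
    measure_descriptors,
    render_leaf,
    segment_leaf,
    shoelace_area,
)
from palmleaf.leaf_image import (
    DegenerateMaskError,
    MarkerNotFoundError,
    NoLeafFoundError,
)


def scene_with_rectangle(h=1000, w=1000, top=400, left=400, rh=100, rw=200):
    img = np.full((h, w), 255, dtype=np.uint8)
    img[top:top + rh, left:left + rw] = 0
    return img


class TestSegmentLeaf:
    def test_black_rectangle_exact_pixel_count(self):
        image = LeafImage(pixels=scene_with_rectangle(), ppcm=20)
        mask = segment_leaf(image)
        assert mask.n_foreground == 20_000

    def test_all_white_image_is_an_error(self):
        image = LeafImage(pixels=np.full((200, 200), 255, np.uint8), ppcm=20)
        with pytest.raises(NoLeafFoundError, match="no leaf found"):
            segment_leaf(image)

    def test_border_touching_clutter_ignored(self):
        img = scene_with_rectangle()
        img[:, :5] = 0  # a ruler strip along the left edge
        mask = segment_leaf(LeafImage(pixels=img, ppcm=20))
        assert mask.n_foreground == 20_000

    def test_holes_filled_by_default(self):
        img = scene_with_rectangle()
        img[440:460, 480:500] = 255  # insect damage
        mask = segment_leaf(LeafImage(pixels=img, ppcm=20))
        assert mask.n_foreground == 20_000

    def test_segmentation_inverts_rendering_exactly(self):
        """On a noise-free rendered scene the mask reproduces the
        renderer's own foreground pixel-for-pixel."""
        truth = generate_leaf(SyntheticLeafSpec(seed=1))
        img = render_leaf(truth, ppcm=20)
        rendered_fg = int((img.pixels < 128).sum())
        assert segment_leaf(img).n_foreground == rendered_fg

    def test_fixed_threshold_override(self):
        image = LeafImage(pixels=scene_with_rectangle(), ppcm=20)
        mask = segment_leaf(image, SegmentationConfig(threshold=100))
        assert mask.n_foreground == 20_000

    def test_invalid_scale_rejected(self):
        with pytest.raises(ValueError, match="ppcm"):
            LeafImage(pixels=scene_with_rectangle(), ppcm=0)


class TestMeasureArea:
    def test_pixel_count_over_ppcm_squared(self):
        mask = segment_leaf(LeafImage(pixels=scene_with_rectangle(), ppcm=20))
        assert measure_area(mask) == pytest.approx(50.0)  # 20000 / 400

    def test_disc_matches_analytic_area(self):
        yy, xx = np.mgrid[:500, :500]
        img = np.where((yy - 250) ** 2 + (xx - 250) ** 2 <= 100**2, 0, 255).astype(np.uint8)
        area = measure_area(segment_leaf(LeafImage(pixels=img, ppcm=20)))
        assert area == pytest.approx(np.pi * 25.0, rel=0.01)

    def test_polygon_area_matches_shoelace_oracle(self):
        truth = generate_leaf(SyntheticLeafSpec(seed=2))
        mask = segment_leaf(render_leaf(truth, ppcm=40))
        assert measure_area(mask) == pytest.approx(shoelace_area(truth.polygon), rel=0.02)

    def test_scale_consistency(self):
        """Doubling the resolution changes the measured physical area by
        well under 1%."""
        truth = generate_leaf(SyntheticLeafSpec(seed=3))
        a20 = measure_area(segment_leaf(render_leaf(truth, ppcm=20)))
        a40 = measure_area(segment_leaf(render_leaf(truth, ppcm=40)))
        assert abs(a20 - a40) / a40 < 0.01


def rotated_rectangle_mask(angle_deg, l_cm=10.0, w_cm=4.0, ppcm=25):
    """Rasterize an l×w rectangle rotated by angle_deg, via the renderer."""
    from dataclasses import replace

    spec = SyntheticLeafSpec(
        n_lobes=1, central_lobe_length=l_cm, lobe_width_ratio=w_cm / l_cm,
        shape_exponent=0.0, attachment_pad_fraction=0.0,
    )
    truth = generate_leaf(spec)
    th = np.radians(angle_deg)
    rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    # small offset keeps polygon edges off exact pixel-centre rows/columns
    truth = replace(truth, polygon=truth.polygon @ rot.T + [0.013, 0.007])
    return segment_leaf(render_leaf(truth, ppcm=ppcm))


class TestDescriptors:
    def test_axis_aligned_rectangle(self):
        mask = rotated_rectangle_mask(0.0)
        d = measure_descriptors(mask)
        tol = 1.0 / 25  # one pixel
        assert d.L == pytest.approx(10.0, abs=tol)
        assert d.W == pytest.approx(4.0, abs=tol)

    def test_rotation_invariance(self):
        d = measure_descriptors(rotated_rectangle_mask(37.0))
        assert d.L == pytest.approx(10.0, rel=0.02)
        assert d.W == pytest.approx(4.0, rel=0.02)

    def test_tip_based_matches_generator_truth(self):
        """Five-lobe palmate leaf: tip spans within 5% of the exact
        tip geometry."""
        truth = generate_leaf(SyntheticLeafSpec(seed=12))
        mask = segment_leaf(render_leaf(truth, ppcm=20))
        d = measure_descriptors(mask, method="tip-based")
        assert d.L == pytest.approx(truth.L, rel=0.05)
        assert d.W == pytest.approx(truth.W, rel=0.05)

    def test_degenerate_mask_rejected(self):
        mask = LeafMask(mask=np.ones((1, 50), bool), ppcm=10)
        with pytest.raises(DegenerateMaskError):
            measure_descriptors(mask)

    def test_unknown_method(self):
        mask = rotated_rectangle_mask(0.0)
        with pytest.raises(ValueError, match="unknown descriptor method"):
            measure_descriptors(mask, method="caliper")


class TestCalibrateScale:
    def scene_with_marker(self, side_px=100):
        img = np.full((800, 800), 255, np.uint8)
        img[30:30 + side_px, 30:30 + side_px] = 0
        return img

    @pytest.mark.parametrize("declared_cm,expected", [(2.0, 50.0), (4.0, 25.0)])
    def test_known_square(self, declared_cm, expected):
        ppcm = calibrate_scale(self.scene_with_marker(), marker_cm=declared_cm)
        assert ppcm == pytest.approx(expected, rel=0.01)

    def test_marker_with_leaf_in_scene(self):
        truth = generate_leaf(SyntheticLeafSpec(seed=7))
        img = render_leaf(truth, ppcm=20, fiducial_cm=2.0)
        assert calibrate_scale(img, marker_cm=2.0) == pytest.approx(20.0, rel=0.02)

    def test_blank_scene_raises(self):
        with pytest.raises(MarkerNotFoundError, match="marker not detected"):
            calibrate_scale(np.full((400, 400), 255, np.uint8), marker_cm=2.0)

    def test_non_square_clutter_rejected(self):
        img = np.full((800, 800), 255, np.uint8)
        img[30:40, 30:300] = 0  # a ruler, 10×270 px
        with pytest.raises(MarkerNotFoundError):
            calibrate_scale(img, marker_cm=2.0)
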