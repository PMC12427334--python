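"""Feature extraction against closed-form oracles on analytic shapes."""

import math

import numpy as np
import pytest

from pigcycle.morphometrics import (
    BinaryMask,
    MaskError,
    contour_perimeter,
    ellipse_eccentricity,
    extract_features,
    min_rect_dims,
    preprocess,
    relative_area,
)
from pigcycle.synthetic import SilhouetteSpec, render_mask


def ramanujan_perimeter(a: float, b: float) -> float:
    h = (a - b) ** 2 / (a + b) ** 2
    return math.pi * (a + b) * (1 + 3 * h / (10 + math.sqrt(4 - 3 * h)))


class TestPreprocess:
    def test_interior_hole_is_filled(self):
        grid = np.zeros((40, 40), dtype=np.uint8)
        grid[5:35, 5:35] = 1
        grid[18:21, 18:21] = 0  # 3x3 interior hole
        before = grid.sum()
        out = preprocess(BinaryMask(grid=grid), closing_radius=0)
        assert out.foreground_count == before + 9

    def test_idempotent_on_solid_shape(self, ellipse_mask_200_100):
        mask, _ = ellipse_mask_200_100
        once = preprocess(mask)
        twice = preprocess(once)
        assert np.array_equal(once.grid, twice.grid)

    def test_keeps_only_largest_component(self):
        grid = np.zeros((60, 120), dtype=np.uint8)
        grid[10:35, 10:30] = 1  # 500 px blob
        grid[10:20, 80:85] = 1  # 50 px blob
        out = preprocess(BinaryMask(grid=grid), closing_radius=0)
        assert out.foreground_count == 500
        assert out.grid[:, 60:].sum() == 0

    def test_empty_mask_rejected(self):
        with pytest.raises(MaskError, match="empty"):
            preprocess(BinaryMask(grid=np.zeros((10, 10)), name="blank"))


class TestRelativeArea:
    def test_full_frame_is_one(self):
        assert relative_area(BinaryMask(grid=np.ones((32, 32)))) == 1.0

    def test_ellipse_matches_closed_form(self, ellipse_mask_200_100):
        mask, truth = ellipse_mask_200_100
        expected = truth["area"] / (640 * 640)
        assert relative_area(mask) == pytest.approx(expected, rel=0.01)


class TestContourPerimeter:
    def test_rectangle(self, rectangle_mask):
        assert contour_perimeter(rectangle_mask) == pytest.approx(2 * (99 + 49), rel=0.02)

    def test_circle(self):
        mask, _ = render_mask(SilhouetteSpec(semi_major_px=100, semi_minor_px=100))
        assert contour_perimeter(mask) == pytest.approx(2 * math.pi * 100, rel=0.03)

    def test_scale_linearity(self, rectangle_mask):
        base = contour_perimeter(rectangle_mask)
        halved = BinaryMask(grid=rectangle_mask.grid, scale=0.5)
        assert contour_perimeter(halved) == pytest.approx(base * 0.5, abs=1e-9)


class TestMinRect:
    def test_axis_aligned_rectangle(self):
        grid = np.zeros((100, 160), dtype=np.uint8)
        grid[20:80, 20:140] = 1  # 120 x 60
        bl, bw = min_rect_dims(BinaryMask(grid=grid))
        assert bl == pytest.approx(120, abs=1.0)
        assert bw == pytest.approx(60, abs=1.0)

    def test_rotation_invariance(self):
        # same 120x60 extent drawn rotated 30 degrees (superellipse, n large
        # approximates the rectangle)
        spec = SilhouetteSpec(
            semi_major_px=60, semi_minor_px=30, orientation_deg=30, shape_exponent=8,
            canvas_w=320, canvas_h=320,
        )
        mask, _ = render_mask(spec)
        bl, bw = min_rect_dims(mask)
        spec0 = SilhouetteSpec(
            semi_major_px=60, semi_minor_px=30, shape_exponent=8, canvas_w=320, canvas_h=320
        )
        mask0, _ = render_mask(spec0)
        bl0, bw0 = min_rect_dims(mask0)
        assert bl == pytest.approx(bl0, rel=0.02)
        assert bw == pytest.approx(bw0, rel=0.02)

    def test_square_gives_equal_sides(self):
        grid = np.zeros((80, 80), dtype=np.uint8)
        grid[20:60, 20:60] = 1
        bl, bw = min_rect_dims(BinaryMask(grid=grid))
        assert bl == pytest.approx(bw, rel=0.01)

    def test_degenerate_line_rejected(self):
        grid = np.zeros((40, 40), dtype=np.uint8)
        grid[20, 5:35] = 1
        with pytest.raises(MaskError):
            min_rect_dims(BinaryMask(grid=grid))


class TestEccentricity:
    def test_circle_is_zero(self):
        mask, _ = render_mask(SilhouetteSpec(semi_major_px=100, semi_minor_px=100))
        assert ellipse_eccentricity(mask) == pytest.approx(0.0, abs=0.02)

    @pytest.mark.parametrize(
        "a,b", [(200, 100), (200, 180)], ids=["e=0.866", "e=0.436"]
    )
    def test_matches_generating_axes(self, a, b):
        mask, _ = render_mask(SilhouetteSpec(semi_major_px=a, semi_minor_px=b))
        expected = math.sqrt(1 - (b / a) ** 2)
        assert ellipse_eccentricity(mask) == pytest.approx(expected, abs=0.02)

    def test_squared_variant(self):
        mask, _ = render_mask(SilhouetteSpec(semi_major_px=200, semi_minor_px=100))
        e = ellipse_eccentricity(mask)
        e2 = ellipse_eccentricity(mask, squared_variant=True)
        assert e2 == pytest.approx(e**2, abs=0.02)


class TestExtractFeatures:
    def test_composes_per_feature_oracles(self):
        a, b = 180, 90
        mask, truth = render_mask(SilhouetteSpec(semi_major_px=a, semi_minor_px=b,
                                                 orientation_deg=40))
        fv = extract_features(mask)
        assert fv.RA == pytest.approx(truth["area"] / 640**2, rel=0.01)
        assert fv.CP == pytest.approx(ramanujan_perimeter(a, b), rel=0.03)
        assert fv.BL == pytest.approx(2 * a, rel=0.02)
        assert fv.BW == pytest.approx(2 * b, rel=0.02)
        assert fv.E == pytest.approx(truth["eccentricity"], abs=0.02)

    def test_order_and_determinism(self, ellipse_mask_200_100):
        mask, _ = ellipse_mask_200_100
        fv1 = extract_features(mask)
        fv2 = extract_features(mask)
        assert np.array_equal(fv1.as_array(), fv2.as_array())
        arr = fv1.as_array()
        assert arr[0] == fv1.RA and arr[1] == fv1.CP and arr[4] == fv1.E

    def test_scale_equivariance(self, ellipse_mask_200_100):
        mask, _ = ellipse_mask_200_100
        fv1 = extract_features(mask)
        fv3 = extract_features(BinaryMask(grid=mask.grid, scale=3.0))
        assert fv3.RA == pytest.approx(fv1.RA)
        assert fv3.E == pytest.approx(fv1.E)
        for name in ("CP", "BL", "BW"):
            assert getattr(fv3, name) == pytest.approx(3 * getattr(fv1, name), rel=1e-9)

    def test_rotation_robustness(self):
        base = None
        for angle in (0, 25, 60, 110, 155):
            mask, _ = render_mask(
                SilhouetteSpec(semi_major_px=150, semi_minor_px=75,
                               orientation_deg=angle, shape_exponent=2.5)
            )
            fv = extract_features(mask)
            vec = np.array([fv.CP, fv.BL, fv.BW, fv.E])
            if base is None:
                base = vec
            else:
                assert np.all(np.abs(vec / base - 1) < 0.02), f"angle {angle}: {vec} vs {base}"

    def test_ra_monotone_in_shape_area(self):
        ras = [
            extract_features(render_mask(SilhouetteSpec(semi_major_px=a, semi_minor_px=a / 2))[0]).RA
            for a in (80, 140, 200, 260)
        ]
        assert all(x < y for x, y in zip(ras, ras[1:]))
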