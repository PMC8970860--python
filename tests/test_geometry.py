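import math

import numpy as np
import pytest

from helpers_oracles import brute_force_enclosing_circle, rasterize_ellipse
from strabmetric import (Circle, EllipseFit, detect_corneal_reflex,
                         enclosing_circle_of_points, fit_ellipse,
                         min_enclosing_circle, model_sclera,
                         recover_limbus_center)
from strabmetric.errors import (DegenerateMaskError,
                                GeometryInconsistencyError,
                                InvalidGeometryError, NoReflexError)
from strabmetric.synthetic import _disk_mask


def _points_mask(points, shape=(64, 64)):
    mask = np.zeros(shape, dtype=bool)
    for x, y in points:
        mask[y, x] = True
    return mask


class TestMinEnclosingCircle:
    def test_filled_disk(self):
        c = min_enclosing_circle(_disk_mask((200, 200), (100, 80), 20))
        assert c.center == pytest.approx((100.0, 80.0), abs=1e-9)
        assert 19.5 <= c.radius <= 20.5

    def test_two_point_diameter(self):
        c = min_enclosing_circle(_points_mask([(0, 0), (10, 0)]))
        assert c.center == pytest.approx((5.0, 0.0))
        assert c.radius == pytest.approx(5.0)

    def test_three_point_circumcircle_vs_oracle(self):
        pts = [(0, 0), (10, 0), (5, 8)]
        c = min_enclosing_circle(_points_mask(pts))
        (ox, oy), orad = brute_force_enclosing_circle(np.array(pts, float))
        assert c.center == pytest.approx((ox, oy), abs=1e-6)
        assert c.radius == pytest.approx(orad, abs=1e-6)

    def test_empty_mask_rejected(self):
        with pytest.raises(DegenerateMaskError):
            min_enclosing_circle(np.zeros((10, 10), dtype=bool))

    def test_collinear_points(self):
        c = min_enclosing_circle(_points_mask([(2, 5), (10, 5), (20, 5)]))
        assert c.center == pytest.approx((11.0, 5.0))
        assert c.radius == pytest.approx(9.0)

    def test_agrees_with_brute_force_on_random_sets(self, rng):
        for _ in range(40):
            n = rng.integers(2, 31)
            pts = rng.integers(0, 60, size=(n, 2)).astype(float)
            if len(np.unique(pts, axis=0)) < 2:
                continue
            mine = enclosing_circle_of_points(pts)
            (ox, oy), orad = brute_force_enclosing_circle(pts)
            assert abs(mine.radius - orad) <= 1e-6
            assert math.hypot(mine.center[0] - ox, mine.center[1] - oy) <= 1e-6

    def test_radius_monotone_under_point_removal(self, rng):
        pts = rng.integers(0, 50, size=(25, 2)).astype(float)
        pts = np.unique(pts, axis=0)
        full = enclosing_circle_of_points(pts).radius
        for _ in range(5):
            keep = rng.choice(len(pts), size=len(pts) - 5, replace=False)
            if len(np.unique(pts[keep], axis=0)) < 2:
                continue
            assert enclosing_circle_of_points(pts[keep]).radius <= full + 1e-9


class TestDetectCornealReflex:
    def test_single_saturated_pixel(self):
        img = np.full((100, 100), 0.3)
        img[42, 57] = 1.0
        mask = _disk_mask((100, 100), (57, 42), 15)
        assert detect_corneal_reflex(img, mask) == pytest.approx((57.0, 42.0))

    def test_uniform_bright_square_centroid(self):
        img = np.full((100, 100), 0.3)
        img[39:42, 59:62] = 1.0  # 3x3 centered at (60, 40)
        mask = _disk_mask((100, 100), (60, 40), 15)
        assert detect_corneal_reflex(img, mask) == pytest.approx((60.0, 40.0))

    def test_synthetic_scene_reflex_recovery(self, primary_scene):
        for eye, cx in (("left", 100.0), ("right", 260.0)):
            half = primary_scene.limbus_mask.copy()
            if eye == "left":
                half[:, 180:] = False
            else:
                half[:, :180] = False
            px, py = detect_corneal_reflex(primary_scene.image, half)
            truth = primary_scene.truth[eye].reflex_point
            assert math.hypot(px - truth[0], py - truth[1]) <= 0.75

    def test_bright_pixels_outside_mask_ignored(self):
        img = np.full((100, 100), 0.3)
        img[42, 57] = 1.0
        img[5, 5] = 1.0  # brighter spot far outside the limbus
        mask = _disk_mask((100, 100), (57, 42), 15)
        assert detect_corneal_reflex(img, mask) == pytest.approx((57.0, 42.0))

    def test_no_reflex_below_floor(self):
        img = np.full((100, 100), 0.35)
        mask = _disk_mask((100, 100), (50, 50), 15)
        with pytest.raises(NoReflexError):
            detect_corneal_reflex(img, mask)

    def test_empty_mask_rejected(self):
        with pytest.raises(DegenerateMaskError):
            detect_corneal_reflex(np.ones((10, 10)), np.zeros((10, 10), bool))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(InvalidGeometryError):
            detect_corneal_reflex(np.ones((10, 10)),
                                  np.ones((12, 10), dtype=bool))


class TestModelSclera:
    def test_radius_is_exactly_2_5x(self):
        comp = _disk_mask((200, 200), (100, 100), 50)
        circle = model_sclera(comp, limbus_radius=20.0)
        assert circle.radius == 50.0

    def test_center_matches_truth_on_synthetic_scene(self, primary_scene):
        half = primary_scene.sclera_mask.copy()
        half[:, 180:] = False
        circle = model_sclera(half, limbus_radius=20.0)
        truth = primary_scene.truth["left"].sclera_center
        assert math.hypot(circle.center[0] - truth[0],
                          circle.center[1] - truth[1]) <= 1.5

    def test_zero_limbus_radius_rejected(self):
        with pytest.raises(InvalidGeometryError):
            model_sclera(_disk_mask((50, 50), (25, 25), 10), 0.0)

    def test_empty_component_rejected(self):
        with pytest.raises(DegenerateMaskError):
            model_sclera(np.zeros((20, 20), dtype=bool), 10.0)


class TestFitEllipse:
    def test_axis_aligned_ellipse_recovery(self):
        mask = rasterize_ellipse((220, 220), (100, 100), 30, 20)
        fit = fit_ellipse(mask)
        assert fit.center == pytest.approx((100.0, 100.0), abs=0.5)
        assert fit.semi_major == pytest.approx(30.0, rel=0.02)
        assert fit.semi_minor == pytest.approx(20.0, rel=0.02)
        assert abs(fit.orientation_deg) <= 2.0

    def test_rotated_ellipse_recovery(self):
        mask = rasterize_ellipse((220, 220), (110, 95), 35, 18, 30.0)
        fit = fit_ellipse(mask)
        assert fit.center == pytest.approx((110.0, 95.0), abs=0.5)
        assert fit.semi_major == pytest.approx(35.0, rel=0.02)
        assert fit.semi_minor == pytest.approx(18.0, rel=0.02)
        assert fit.orientation_deg == pytest.approx(30.0, abs=2.0)

    def test_circle_has_near_unit_axis_ratio(self):
        fit = fit_ellipse(_disk_mask((120, 120), (60, 60), 25))
        assert 0.98 <= fit.axis_ratio <= 1.02

    def test_tiny_mask_rejected(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[5, 5:8] = True  # 3 pixels
        with pytest.raises(DegenerateMaskError):
            fit_ellipse(mask)

    def test_collinear_boundary_rejected(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[5, 2:18] = True
        with pytest.raises(DegenerateMaskError):
            fit_ellipse(mask)


class TestRecoverLimbusCenter:
    def test_near_circular_fallback_keeps_fit_center(self):
        fit = EllipseFit((120.0, 100.0), 24.0, 23.8, 0.0)  # ratio 0.99
        sclera = Circle((100.0, 100.0), 60.0)
        out = recover_limbus_center(fit, 24.0, sclera)
        assert out.center == fit.center
        assert out.radius == 24.0

    def test_foreshortened_limbus_hand_constructed(self):
        # eyeball at S=(100,100), R=60, limbus r=24 rotated 30 deg toward +x:
        # projected ellipse center E = S + sqrt(R^2-r^2)*sin(30), semi-minor
        # b = r*cos(30) along x, semi-major r along y.
        S = (100.0, 100.0)
        r, R, th = 24.0, 60.0, math.radians(30.0)
        d = math.sqrt(R * R - r * r)
        E = (S[0] + d * math.sin(th), S[1])
        b = r * math.cos(th)
        mask = rasterize_ellipse((240, 240), E, r, b, 90.0)
        fit = fit_ellipse(mask)
        assert fit.axis_ratio < 0.95
        out = recover_limbus_center(fit, r, Circle(S, R))
        # construction: one limbus radius back from the outer short-axis point
        expected = (E[0] + b - r, E[1])
        assert out.center == pytest.approx(expected, abs=0.75)
        assert out.radius == r

    def test_candidate_closer_to_sclera_center_wins(self):
        fit = EllipseFit((130.0, 100.0), 24.0, 18.0, 90.0)  # minor axis +-x
        sclera = Circle((100.0, 100.0), 60.0)
        out = recover_limbus_center(fit, 24.0, sclera)
        assert out.center == pytest.approx((130.0 + 18.0 - 24.0, 100.0))

    def test_symmetric_tie_resolves_along_minor_axis(self):
        # fit center exactly on the sclera center: documented deterministic
        # tie-break along the +minor-axis direction
        fit = EllipseFit((100.0, 100.0), 24.0, 18.0, 90.0)
        sclera = Circle((100.0, 100.0), 60.0)
        out = recover_limbus_center(fit, 24.0, sclera)
        # minor-axis direction for a 90-deg major axis is (-1, 0); the outer
        # contour point is (82, 100) and stepping back r=24 gives (106, 100)
        assert out.center == pytest.approx((106.0, 100.0))

    def test_candidates_outside_sclera_rejected(self):
        fit = EllipseFit((300.0, 100.0), 24.0, 18.0, 90.0)
        sclera = Circle((100.0, 100.0), 30.0)
        with pytest.raises(GeometryInconsistencyError):
            recover_limbus_center(fit, 24.0, sclera)

    def test_continuity_toward_circular_limit(self):
        # sweep the foreshortening angle to 0: recovered center approaches
        # the enclosing-circle center of the (circular) limbus mask
        S = (100.0, 100.0)
        r, R = 24.0, 60.0
        d = math.sqrt(R * R - r * r)
        prev_gap = None
        for deg in (25.0, 15.0, 8.0, 0.0):
            th = math.radians(deg)
            E = (S[0] + d * math.sin(th), S[1])
            mask = rasterize_ellipse((240, 240), E, r, r * math.cos(th), 90.0)
            fit = fit_ellipse(mask)
            out = recover_limbus_center(fit, r, Circle(S, R))
            mec = min_enclosing_circle(mask)
            gap = math.hypot(out.center[0] - mec.center[0],
                             out.center[1] - mec.center[1])
            if deg == 0.0:
                assert gap <= 0.5  # circular limit: centers coincide
            if prev_gap is not None:
                assert gap <= prev_gap + 0.5
            prev_gap = gap

    def test_zero_limbus_radius_rejected(self):
        fit = EllipseFit((0.0, 0.0), 2.0, 1.0, 0.0)
        with pytest.raises(InvalidGeometryError):
            recover_limbus_center(fit, 0.0, Circle((0.0, 0.0), 5.0))
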