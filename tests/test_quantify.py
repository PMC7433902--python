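"""Contour quantification: raster semantics, backgrounds, line profiles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from shapely.geometry import Point, Polygon

from centroasym import (
    ImageStack,
    PairGroundTruth,
    PolygonROI,
    estimate_background,
    line_profile_ratio,
    measure_total,
    points_in_polygon,
    render_pair,
    roi_for_focus,
)
from centroasym.quantify import detection_floor, rasterize


def star_polygon(rng, n_vertices=8, radius=10.0, center=(15.0, 15.0)):
    """Random star-shaped (hence simple) polygon."""
    ang = np.sort(rng.uniform(0, 2 * math.pi, n_vertices))
    r = rng.uniform(0.3 * radius, radius, n_vertices)
    cx, cy = center
    return np.column_stack([cx + r * np.cos(ang), cy + r * np.sin(ang)])


class TestPointInPolygon:
    def test_centers_on_boundary_count_inside(self, uniform_stack, square_roi):
        m = measure_total(uniform_stack, square_roi, "Asl", background=2.0)
        assert m.pixel_count == 25
        assert m.total("Asl") == pytest.approx(25 * 8.0)

    def test_agrees_with_shapely_oracle(self):
        """1,000 random star polygons x points vs shapely covers()."""
        rng = np.random.default_rng(11)
        checked = 0
        while checked < 1000:
            verts = star_polygon(rng)
            poly = Polygon(verts)
            pts = rng.uniform(0, 30, size=(20, 2))
            # skip points numerically on the boundary, where the tie rule
            # (ours: inside) and float noise make the oracle comparison moot
            clear = np.array([poly.exterior.distance(Point(p)) > 1e-6 for p in pts])
            got = points_in_polygon(pts[clear], verts)
            want = np.array([poly.covers(Point(p)) for p in pts[clear]])
            np.testing.assert_array_equal(got, want)
            checked += clear.sum()

    def test_even_odd_rule_on_bowtie(self):
        # self-intersecting bowtie: central crossing region has winding 0
        verts = np.array([(0, 0), (4, 4), (4, 0), (0, 4)], float)
        assert points_in_polygon(np.array([[1.0, 2.0]]), verts)[0]  # left lobe
        assert not points_in_polygon(np.array([[2.0, 1.0]]), verts)[0]


class TestMeasureTotal:
    def test_background_equal_to_signal_gives_zero(self, uniform_stack, square_roi):
        m = measure_total(uniform_stack, square_roi, "Asl", background=10.0)
        assert m.total("Asl") == 0.0

    def test_rendered_focus_total_matches_integration_oracle(self, noiseless_pair):
        """Total within 1% of truth x (Gaussian mass inside the contour).

        Oracle: numerical integration of the continuous Gaussian over the
        polygon via dense sub-pixel sampling, independent of the raster path.
        """
        truth, stack = noiseless_pair
        roi = roi_for_focus(truth.positions[0], truth.psf_sigma, centriole_id="c0")
        m = measure_total(stack, roi, "Asl", background=truth.background)

        x0, y0 = truth.positions[0]
        s = truth.psf_sigma
        poly = Polygon(roi.vertices)
        xmin, ymin, xmax, ymax = poly.bounds
        xs = np.arange(xmin, xmax, 0.05)
        ys = np.arange(ymin, ymax, 0.05)
        gx, gy = np.meshgrid(xs, ys)
        pts = np.column_stack([gx.ravel(), gy.ravel()])
        inside = np.array([poly.covers(Point(p)) for p in pts])
        dens = np.exp(-((pts[:, 0] - x0) ** 2 + (pts[:, 1] - y0) ** 2) / (2 * s * s))
        mass = dens[inside].sum() * 0.05 * 0.05 / (2 * math.pi * s * s)
        expected = truth.true_totals["Asl"][0] * mass
        assert m.total("Asl") == pytest.approx(expected, rel=0.01)

    def test_out_of_bounds_roi_flagged_and_clipped(self, uniform_stack):
        roi = PolygonROI("c", "edge", vertices=[(-3, -3), (4, -3), (4, 4), (-3, 4)])
        m = measure_total(uniform_stack, roi, "Asl", background=0.0)
        assert "out_of_bounds" in m.flags
        assert m.pixel_count == 25  # clipped to the 0..4 x 0..4 centers

    def test_empty_interior_raises(self, uniform_stack):
        roi = PolygonROI("c", "tiny", vertices=[(0.1, 0.1), (0.2, 0.1), (0.2, 0.2)])
        with pytest.raises(ValueError, match="no pixel centers"):
            measure_total(uniform_stack, roi, "Asl", background=0.0)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(gain=st.floats(min_value=0.01, max_value=100.0))
    def test_gain_invariance(self, gain):
        """Scaling pixels and background by g scales the total by g."""
        rng = np.random.default_rng(3)
        img = rng.uniform(5, 50, size=(1, 1, 16, 16))
        roi = PolygonROI("c", "r", vertices=[(3, 3), (12, 3), (12, 12), (3, 12)])
        base = measure_total(ImageStack(img, ["m"]), roi, "m", background=4.0)
        scaled = measure_total(ImageStack(img * gain, ["m"]), roi, "m", background=4.0 * gain)
        assert scaled.total("m") == pytest.approx(gain * base.total("m"), rel=1e-9)

    def test_monotone_in_roi_size_on_noiseless_render(self, noiseless_pair):
        truth, stack = noiseless_pair
        totals = []
        for k in (1.5, 2.0, 3.0, 4.0, 5.0):
            roi = roi_for_focus(truth.positions[0], truth.psf_sigma,
                                radius_sigmas=k, centriole_id="c")
            totals.append(measure_total(stack, roi, "Asl", truth.background).total("Asl"))
        assert all(b >= a - 1e-9 for a, b in zip(totals, totals[1:]))

    def test_total_clamp_mode(self, uniform_stack, square_roi):
        # per-pixel vs summed clamp differ when background exceeds the signal
        per_pixel = measure_total(uniform_stack, square_roi, "Asl", 12.0, clamp="pixel")
        summed = measure_total(uniform_stack, square_roi, "Asl", 12.0, clamp="total")
        assert per_pixel.total("Asl") == 0.0 and summed.total("Asl") == 0.0
        per_pixel = measure_total(uniform_stack, square_roi, "Asl", 8.0, clamp="pixel")
        summed = measure_total(uniform_stack, square_roi, "Asl", 8.0, clamp="total")
        assert per_pixel.total("Asl") == summed.total("Asl") == pytest.approx(50.0)


class TestBackground:
    def test_annulus_on_uniform_image_returns_value(self):
        stack = ImageStack(np.full((1, 1, 40, 40), 7.0), ["m"])
        roi = PolygonROI("c", "r", z_ref=0, vertices=[(16, 16), (24, 16), (24, 24), (16, 24)])
        assert estimate_background(stack, roi, channel="m") == 7.0

    def test_fixed_returns_config_value(self, uniform_stack, square_roi):
        assert estimate_background(uniform_stack, square_roi, method="fixed",
                                   fixed_value=100.0) == 100.0

    def test_annulus_recovers_true_background_on_render(self, noiseless_pair):
        truth, stack = noiseless_pair
        roi = roi_for_focus(truth.positions[1], truth.psf_sigma, centriole_id="c1")
        bg = estimate_background(stack, roi, channel="Asl")
        assert bg == pytest.approx(truth.background, rel=0.05)

    def test_annulus_outside_image_raises(self):
        stack = ImageStack(np.full((1, 1, 12, 12), 7.0), ["m"])
        roi = PolygonROI("c", "r", z_ref=0, vertices=[(1, 1), (6, 1), (6, 6), (1, 6)])
        with pytest.raises(ValueError, match="annulus"):
            estimate_background(stack, roi, channel="m")

    def test_detection_floor_positive_on_noisy_render(self):
        truth = PairGroundTruth(positions=np.array([[22.0, 32.0], [42.0, 32.0]]),
                                true_totals={"Cnb": (0.0, 900.0)}, seed=5)
        stack = render_pair(truth)
        roi = roi_for_focus(truth.positions[0], truth.psf_sigma, centriole_id="c0")
        floor = detection_floor(stack, roi, "Cnb")
        assert floor > 0
        # floor should not swallow a clearly detectable total
        assert floor < 900.0


class TestLineProfile:
    def test_uniform_image_ratio_one(self):
        stack = ImageStack(np.full((1, 1, 40, 40), 120.0), ["m"])
        cyto = PolygonROI("c", "cyto", z_ref=0, vertices=[(2, 2), (10, 2), (10, 10), (2, 10)])
        ratio, profile = line_profile_ratio(stack, ((15, 20), (30, 20)), cyto, "m")
        assert ratio == pytest.approx(1.0)
        assert np.allclose(profile, 120.0)

    def test_band_over_cytoplasm_ratio(self):
        img = np.full((1, 1, 40, 40), 500.0)
        img[0, 0, 2:11, 2:11] = 100.0  # cytoplasm patch
        stack = ImageStack(img, ["m"])
        cyto = PolygonROI("c", "cyto", z_ref=0, vertices=[(3, 3), (9, 3), (9, 9), (3, 9)])
        ratio, _ = line_profile_ratio(stack, ((20, 25), (34, 25)), cyto, "m")
        assert ratio == pytest.approx(5.0)

    def test_rendered_focus_ratio_matches_analytic(self):
        """Band mean = cyto + total x band-mass / band-area, within 5%."""
        total, sigma, bg = 8000.0, 1.5, 50.0
        truth = PairGroundTruth(positions=np.array([[32.0, 32.0], [5.0, 5.0]]),
                                true_totals={"m": (total, 0.0)}, psf_sigma=sigma,
                                background=bg, noise_model="none")
        stack = render_pair(truth)
        cyto = PolygonROI("c", "cyto", z_ref=0, vertices=[(45, 45), (60, 45), (60, 60), (45, 60)])
        width = 12
        line = ((24.0, 32.0), (40.0, 32.0))
        ratio, _ = line_profile_ratio(stack, line, cyto, "m", width=width)
        # nearly all Gaussian mass lies inside the 16x12 band around the focus
        band_area = 17 * width  # profile_line samples 17 positions x 12 width
        expected = (bg + total / band_area) / bg
        assert ratio == pytest.approx(expected, rel=0.05)

    def test_degenerate_normalization_raises(self):
        img = np.full((1, 1, 20, 20), 9.0)
        img[0, 0, 1:7, 1:7] = 0.0
        stack = ImageStack(img, ["m"])
        cyto = PolygonROI("c", "cyto", z_ref=0, vertices=[(2, 2), (5, 2), (5, 5), (2, 5)])
        with pytest.raises(ValueError, match="degenerate"):
            line_profile_ratio(stack, ((10, 10), (15, 15)), cyto, "m")

    def test_gain_invariance(self):
        rng = np.random.default_rng(9)
        img = rng.uniform(10, 90, size=(1, 1, 30, 30))
        cyto = PolygonROI("c", "cyto", z_ref=0, vertices=[(2, 2), (9, 2), (9, 9), (2, 9)])
        r1, _ = line_profile_ratio(ImageStack(img, ["m"]), ((12, 15), (25, 15)), cyto, "m")
        r2, _ = line_profile_ratio(ImageStack(img * 7.5, ["m"]), ((12, 15), (25, 15)), cyto, "m")
        assert r2 == pytest.approx(r1, rel=1e-12)
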