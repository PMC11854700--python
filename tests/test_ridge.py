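import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hipsono.errors import InsufficientRidgeSupport
from hipsono.ridge import (
    LocalMaximaSet,
    ROISpec,
    assess_quality,
    build_roi,
    detect_local_maxima,
    export_intensity_surface,
    fit_line,
    refine_points_subpixel,
    select_ilium_points,
)


def brute_force_local_maxima(image, roi, neighborhood_px):
    """Independent oracle: scan every ROI pixel's full neighborhood."""
    img = np.asarray(image, dtype=float)
    h, w = img.shape
    r = neighborhood_px // 2
    out = set()
    for y in range(max(roi.y_min, 0), min(roi.y_max, h)):
        for x in range(max(roi.x_min, 0), min(roi.x_max, w)):
            v = img[y, x]
            if v <= 0:
                continue
            neighborhood = img[
                max(y - r, 0) : min(y + r + 1, h), max(x - r, 0) : min(x + r + 1, w)
            ]
            if v >= neighborhood.max():
                out.add((x, y))
    return out


def brute_force_tls_angle(points, coarse=2001, refine_iters=60):
    """Independent oracle: minimize summed squared perpendicular distances
    over the line angle by dense grid search plus golden-section refinement.
    """
    pts = np.asarray(points, dtype=float)
    centered = pts - pts.mean(axis=0)

    def residual(theta_deg):
        t = math.radians(theta_deg)
        normal = np.array([-math.sin(t), math.cos(t)])
        return float(np.sum((centered @ normal) ** 2))

    grid = np.linspace(0.0, 180.0, coarse, endpoint=False)
    best = grid[int(np.argmin([residual(g) for g in grid]))]
    lo, hi = best - 180.0 / coarse, best + 180.0 / coarse
    phi = (math.sqrt(5) - 1) / 2
    a, b = lo, hi
    c, d = b - phi * (b - a), a + phi * (b - a)
    for _ in range(refine_iters):
        if residual(c) < residual(d):
            b, d = d, c
            c = b - phi * (b - a)
        else:
            a, c = c, d
            d = a + phi * (b - a)
    return ((a + b) / 2.0) % 180.0


class TestBuildRoi:
    def test_center_case(self):
        roi = build_roi((128.0, 140.0), (256, 256))
        assert (roi.x_min, roi.x_max) == (123, 133)
        assert (roi.y_min, roi.y_max) == (0, 145)
        assert roi.width == 10

    def test_left_border_clip(self):
        roi = build_roi((2.0, 140.0), (256, 256))
        assert (roi.x_min, roi.x_max) == (0, 7)

    def test_bottom_border_clip(self):
        roi = build_roi((128.0, 254.0), (256, 256))
        assert roi.y_max == 256

    def test_eap_outside_rejected(self):
        with pytest.raises(ValueError):
            build_roi((300.0, 10.0), (256, 256))


class TestDetectLocalMaxima:
    def test_single_bright_pixel(self):
        img = np.zeros((5, 5))
        img[2, 2] = 10.0
        got = detect_local_maxima(img, ROISpec(0, 5, 0, 5), 3)
        assert [(x, y) for x, y, _ in got.points] == [(2, 2)]

    def test_constant_plateau_all_returned(self):
        img = np.full((6, 6), 7.0)
        got = detect_local_maxima(img, ROISpec(1, 4, 1, 4), 3)
        assert len(got.points) == 9

    def test_zero_pixels_excluded(self):
        img = np.zeros((5, 5))
        got = detect_local_maxima(img, ROISpec(0, 5, 0, 5), 3)
        assert got.points == ()

    def test_even_neighborhood_rejected(self):
        with pytest.raises(ValueError):
            detect_local_maxima(np.ones((5, 5)), ROISpec(0, 5, 0, 5), 4)

    def test_empty_roi_after_clip(self):
        with pytest.raises(ValueError):
            detect_local_maxima(np.ones((5, 5)), ROISpec(10, 20, 0, 5), 3)

    @pytest.mark.parametrize("neighborhood", [3, 5, 7])
    def test_matches_brute_force_on_random_images(self, neighborhood, rng):
        for _ in range(20):
            img = np.round(rng.uniform(0, 255, (32, 32)) * rng.choice([0.0, 1.0], (32, 32), p=[0.1, 0.9]))
            x0, y0 = rng.integers(0, 20, 2)
            roi = ROISpec(int(x0), int(x0) + 10, int(y0), int(y0) + 10)
            got = {(x, y) for x, y, _ in detect_local_maxima(img, roi, neighborhood).points}
            assert got == brute_force_local_maxima(img, roi, neighborhood)

    def test_intensity_equals_image_value(self, rng):
        img = np.round(rng.uniform(0, 255, (32, 32)))
        got = detect_local_maxima(img, ROISpec(0, 32, 0, 32), 5)
        for x, y, v in got.points:
            assert v == img[y, x]


class TestSelectIliumPoints:
    def _maxima(self, pts):
        return LocalMaximaSet(points=tuple(pts), neighborhood_px=5)

    def test_one_per_row_identity(self):
        pts = [(5, y, 200.0) for y in range(12)]
        got = select_ilium_points(self._maxima(pts), k_min=10)
        assert got == [(5, y) for y in range(12)]

    def test_row_tie_keeps_brightest(self):
        pts = [(4, 0, 200.0), (7, 0, 180.0)] + [(5, y, 200.0) for y in range(1, 12)]
        got = select_ilium_points(self._maxima(pts), k_min=10)
        assert got[0] == (4, 0)

    def test_equal_intensity_tie_prefers_smaller_x(self):
        pts = [(6, 0, 200.0), (3, 0, 200.0)] + [(5, y, 200.0) for y in range(1, 12)]
        got = select_ilium_points(self._maxima(pts), k_min=10)
        assert got[0] == (3, 0)

    def test_insufficient_support(self):
        pts = [(5, y, 200.0) for y in range(5)]
        with pytest.raises(InsufficientRidgeSupport):
            select_ilium_points(self._maxima(pts), k_min=10)

    def test_dim_maxima_filtered_before_rows(self):
        pts = [(1, 0, 10.0)] + [(5, y, 200.0) for y in range(1, 12)]
        got = select_ilium_points(self._maxima(pts), k_min=10, min_rel_intensity=0.5)
        assert (1, 0) not in got

    def test_empty_maxima(self):
        with pytest.raises(InsufficientRidgeSupport):
            select_ilium_points(self._maxima([]))


class TestFitLine:
    def test_exact_vertical(self):
        line = fit_line([(50.0, float(y)) for y in range(20)])
        assert line.angle_deg == pytest.approx(90.0)
        assert line.anchor == (50.0, 9.5)

    def test_exact_diagonal(self):
        line = fit_line([(float(t), float(t)) for t in range(20)])
        assert line.angle_deg == pytest.approx(45.0)

    def test_horizontal(self):
        line = fit_line([(float(t), 3.0) for t in range(10)])
        assert line.angle_deg == pytest.approx(0.0)

    def test_direction_is_unit(self):
        line = fit_line([(0.0, 0.0), (3.0, 1.0), (6.0, 2.5)])
        assert math.hypot(*line.direction) == pytest.approx(1.0)

    def test_coincident_points_rejected(self):
        with pytest.raises(ValueError):
            fit_line([(1.0, 1.0), (1.0, 1.0), (1.0, 1.0)])

    def test_fewer_than_two_rejected(self):
        with pytest.raises(ValueError):
            fit_line([(1.0, 2.0)])

    def test_matches_brute_force_oracle_noisy_88deg(self, rng):
        t = math.radians(88.0)
        base = np.array([50.0, 10.0])
        d = np.array([math.cos(t), math.sin(t)])
        pts = [
            base + s * d + rng.normal(0, 0.3, 2) for s in np.linspace(0, 60, 30)
        ]
        line = fit_line(pts)
        oracle = brute_force_tls_angle(pts)
        assert line.angle_deg == pytest.approx(oracle, abs=1e-6)

    @settings(max_examples=25, deadline=None)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_matches_brute_force_oracle_random(self, seed):
        # elongated noisy clouds: isotropic clouds have a flat residual
        # landscape where no search-based oracle can resolve the angle
        r = np.random.default_rng(seed)
        t = r.uniform(0, np.pi)
        d = np.array([np.cos(t), np.sin(t)])
        s = np.linspace(0, 40, 12)
        pts = r.uniform(10, 90, 2) + np.outer(s, d) + r.normal(0, 0.5, (12, 2))
        line = fit_line(pts)
        oracle = brute_force_tls_angle(pts)
        delta = abs(line.angle_deg - oracle) % 180.0
        assert min(delta, 180.0 - delta) < 1e-6


class TestRefineSubpixel:
    def test_symmetric_profile_unmoved(self):
        img = np.zeros((5, 5))
        img[2, 1:4] = [50.0, 100.0, 50.0]
        assert refine_points_subpixel(img, [(2, 2)]) == [(2.0, 2.0)]

    def test_asymmetric_profile_shifts_toward_heavier_side(self):
        img = np.zeros((5, 5))
        img[2, 1:4] = [40.0, 100.0, 80.0]
        (x, y), = refine_points_subpixel(img, [(2, 2)])
        assert 2.0 < x <= 2.5
        assert y == 2.0

    def test_border_points_untouched(self):
        img = np.ones((5, 5))
        assert refine_points_subpixel(img, [(0, 2), (4, 2)]) == [(0.0, 2.0), (4.0, 2.0)]


class TestAssessQuality:
    @pytest.mark.parametrize(
        "angle,expected",
        [(86.99, False), (87.0, True), (90.0, True), (93.0, True), (93.01, False)],
    )
    def test_gate_inclusive_bounds(self, angle, expected):
        from hipsono.ridge import RidgeLine

        line = RidgeLine(anchor=(0, 0), direction=(0, 1), angle_deg=angle, n_points=10)
        result = assess_quality(line)
        assert result.qualified is expected
        assert result.iliac_angle_deg == angle

    def test_custom_gate(self):
        from hipsono.ridge import RidgeLine

        line = RidgeLine(anchor=(0, 0), direction=(0, 1), angle_deg=89.5, n_points=5)
        assert assess_quality(line, gate=(89.0, 91.0)).qualified
        assert not assess_quality(line, gate=(90.0, 91.0)).qualified

    def test_invalid_gate(self):
        from hipsono.ridge import RidgeLine

        line = RidgeLine(anchor=(0, 0), direction=(0, 1), angle_deg=90.0)
        with pytest.raises(ValueError):
            assess_quality(line, gate=(93.0, 87.0))


class TestExportSurface:
    def test_cardinality(self):
        img = np.arange(16, dtype=float).reshape(4, 4)
        triples = export_intensity_surface(img, ROISpec(1, 3, 1, 3))
        assert len(triples) == 4

    def test_lossless_roundtrip(self, rng):
        img = np.round(rng.uniform(0, 255, (16, 16)))
        roi = ROISpec(3, 9, 2, 12)
        triples = export_intensity_surface(img, roi)
        rebuilt = np.zeros((roi.height, roi.width))
        for x, y, z in triples:
            rebuilt[y - roi.y_min, x - roi.x_min] = z
        np.testing.assert_array_equal(rebuilt, img[roi.y_min : roi.y_max, roi.x_min : roi.x_max])

    def test_sorted_by_y_then_x(self, rng):
        img = rng.uniform(0, 255, (8, 8))
        triples = export_intensity_surface(img, ROISpec(0, 8, 0, 8))
        keys = [(y, x) for x, y, _ in triples]
        assert keys == sorted(keys)

    def test_roi_out_of_bounds_rejected(self):
        with pytest.raises(ValueError):
            export_intensity_surface(np.zeros((4, 4)), ROISpec(0, 8, 0, 4))
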