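"""Compact representation: resampling, section frames, averaging, rasters."""

import numpy as np
import pytest

from hemoline.centerline import (
    build_profile,
    rasterize_section,
    resample_centerline,
    section_planes,
)
from hemoline.exceptions import GeometryError, InputError, MissingDataError
from hemoline.oracle import FieldSamples, sample_fields


def _line(length, n=500):
    z = np.linspace(0.0, length, n)
    return np.column_stack([np.zeros(n), np.zeros(n), z])


class TestResample:
    def test_240mm_curve_gives_121_points(self):
        cl = resample_centerline(_line(240.0), spacing=2.0)
        assert cl.n_points == 121

    def test_short_segment_three_collinear_points(self):
        cl = resample_centerline(_line(4.0, n=50), spacing=2.0)
        assert cl.n_points == 3
        d = np.diff(cl.points, axis=0)
        assert np.allclose(np.cross(d[0], d[1]), 0.0)

    def test_consecutive_distances_on_synthetic_aorta(self, default_case):
        d = np.linalg.norm(np.diff(default_case.centerline.points, axis=0), axis=1)
        assert np.max(np.abs(d - 2.0)) < 1e-6

    def test_arc_length_strictly_increasing_from_zero(self, default_case):
        s = default_case.centerline.arc_length
        assert s[0] == 0.0
        assert np.all(np.diff(s) > 0)

    def test_total_stepped_length_close_to_curve_length(self):
        theta = np.linspace(0, np.pi, 2000)
        curve = np.column_stack([50 * np.cos(theta), 50 * np.sin(theta), np.zeros_like(theta)])
        cl = resample_centerline(curve, spacing=2.0)
        assert abs(cl.arc_length[-1] - 50 * np.pi) <= 2.0

    def test_too_short_curve_rejected(self):
        with pytest.raises(InputError):
            resample_centerline(_line(3.0, n=10), spacing=2.0)


class TestSectionPlanes:
    def test_straight_tube_normals_along_axis(self):
        cl = resample_centerline(_line(60.0), spacing=2.0)
        frames = section_planes(cl)
        for fr in frames:
            assert np.allclose(fr.normal, [0, 0, 1], atol=1e-9)

    def test_plane_count_equals_point_count(self, default_case):
        assert len(section_planes(default_case.centerline)) == default_case.centerline.n_points

    def test_planar_arc_frames_rotate_continuously(self):
        theta = np.linspace(0, np.pi, 3000)
        curve = np.column_stack([40 * np.cos(theta), np.zeros_like(theta), 40 * np.sin(theta)])
        cl = resample_centerline(curve, spacing=2.0)
        frames = section_planes(cl)
        for i, fr in enumerate(frames):
            # tangent of a circle is orthogonal to the radius vector
            radial = fr.origin / np.linalg.norm(fr.origin)
            assert abs(fr.normal @ radial) < 0.05
            if i:
                assert frames[i - 1].u @ fr.u > 0.99
                assert frames[i - 1].v @ fr.v > 0.99

    def test_duplicate_points_rejected(self):
        pts = np.zeros((4, 3))
        pts[:, 2] = [0.0, 2.0, 2.0, 4.0]
        from hemoline.centerline import Centerline

        cl = Centerline(points=pts, arc_length=np.array([0.0, 2.0, 2.0, 4.0]))
        with pytest.raises(GeometryError):
            section_planes(cl)


class TestAveraging:
    def test_mean_of_plane_samples(self):
        fs = FieldSamples(
            pressure=[(np.zeros((3, 3)), np.array([100.0, 110.0, 120.0]))],
            wss=[(np.zeros((3, 3)), np.array([12.0, 12.0, 12.0]))],
        )
        from hemoline.centerline import average_pressure, average_wss

        assert average_pressure(fs, 0) == pytest.approx(110.0)
        assert average_wss(fs, 0) == pytest.approx(12.0)

    def test_zero_noise_samples_reproduce_profile(self, default_case, default_profile):
        from hemoline.centerline import average_pressure
        from hemoline.oracle import OracleParams

        fs = sample_fields(
            default_case, default_profile,
            OracleParams(sample_noise_frac=0.0), seed=1, n_samples=16,
        )
        for i in (0, 30, 60):
            assert average_pressure(fs, i) == pytest.approx(default_profile.pressure[i])

    def test_noisy_means_within_three_standard_errors(self, default_case, default_profile, default_samples):
        from hemoline.centerline import average_pressure
        from hemoline.oracle import MMHG_PER_PA

        q = default_profile.flow_rate * 1e-6
        for i in (5, 40, 90):
            v = q / (default_case.sections[i].area * 1e-6)
            sigma = 0.05 * 0.5 * 1050.0 * v**2 * MMHG_PER_PA
            se = sigma / np.sqrt(64)
            assert abs(average_pressure(default_samples, i) - default_profile.pressure[i]) <= 3 * se + 1e-12

    def test_wss_mean_over_given_subset_only(self):
        # a segment whose sample list holds leaflet values only: the mean is
        # the hand mean of exactly that subset
        from hemoline.centerline import average_wss

        leaflet = np.array([22.0, 26.0, 30.0])
        fs = FieldSamples(pressure=[], wss=[(np.zeros((3, 3)), leaflet)])
        assert average_wss(fs, 0) == pytest.approx(leaflet.mean())

    def test_wss_average_nonnegative_for_any_samples(self):
        from hemoline.centerline import average_wss

        rng = np.random.default_rng(0)
        vals = rng.normal(0, 5, 32)
        fs = FieldSamples(pressure=[], wss=[(np.zeros((32, 3)), vals)])
        assert average_wss(fs, 0) >= 0.0

    def test_averaging_permutation_invariant_and_linear(self):
        from hemoline.centerline import average_pressure

        rng = np.random.default_rng(3)
        vals = rng.normal(100, 5, 40)
        perm = rng.permutation(40)
        fs1 = FieldSamples(pressure=[(np.zeros((40, 3)), vals)], wss=[])
        fs2 = FieldSamples(pressure=[(np.zeros((40, 3)), vals[perm])], wss=[])
        fs3 = FieldSamples(pressure=[(np.zeros((40, 3)), 2.0 * vals + 1.0)], wss=[])
        assert average_pressure(fs1, 0) == pytest.approx(average_pressure(fs2, 0))
        assert average_pressure(fs3, 0) == pytest.approx(2.0 * average_pressure(fs1, 0) + 1.0)

    def test_empty_samples_raise(self):
        from hemoline.centerline import average_pressure

        fs = FieldSamples(pressure=[], wss=[])
        with pytest.raises(MissingDataError):
            average_pressure(fs, 0)


class _FakeSection:
    def __init__(self, xy, index=0):
        self.boundary_local = xy
        self.index = index


class TestRasterize:
    def test_circle_occupied_fraction_matches_area_ratio(self):
        theta = np.linspace(0, 2 * np.pi, 256, endpoint=False)
        xy = np.column_stack([10 * np.cos(theta), 10 * np.sin(theta)])
        img = rasterize_section(_FakeSection(xy), grid_size=68, window_mm=50.0)
        assert img.occupied_fraction == pytest.approx(np.pi * 100 / 2500, abs=0.01)

    def test_default_grid_size(self, default_case):
        img = rasterize_section(default_case.sections[40])
        assert img.grid.shape == (68, 68)

    def test_pixel_area_estimate_within_three_percent(self):
        theta = np.linspace(0, 2 * np.pi, 256, endpoint=False)
        for r in (5.0, 8.0, 12.0):
            xy = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
            img = rasterize_section(_FakeSection(xy))
            assert abs(img.area_mm2() - np.pi * r**2) / (np.pi * r**2) < 0.03

    def test_empty_polygon_rejected(self):
        with pytest.raises(InputError):
            rasterize_section(_FakeSection(np.zeros((0, 2))))

    def test_boundary_exceeding_window_reported(self):
        theta = np.linspace(0, 2 * np.pi, 64, endpoint=False)
        xy = np.column_stack([40 * np.cos(theta), 40 * np.sin(theta)])
        with pytest.raises(GeometryError):
            rasterize_section(_FakeSection(xy), window_mm=50.0)

    def test_translation_invariance_wrt_origin(self, default_case):
        # the raster is defined in local in-plane coordinates: two sections
        # with the same local polygon give the same image regardless of origin
        sec_a = default_case.sections[80]
        moved = _FakeSection(sec_a.boundary_local.copy(), index=81)
        img_a = rasterize_section(sec_a)
        img_b = rasterize_section(moved)
        np.testing.assert_array_equal(img_a.grid, img_b.grid)


class TestBuildProfile:
    def test_zero_noise_round_trip_exact(self, default_case, default_profile):
        from hemoline.oracle import OracleParams

        fs = sample_fields(default_case, default_profile,
                           OracleParams(sample_noise_frac=0.0), seed=2, n_samples=8)
        prof = build_profile(default_case, fs)
        np.testing.assert_allclose(prof.pressure, default_profile.pressure, atol=1e-9)
        np.testing.assert_allclose(prof.wss[:-1], default_profile.wss[:-1], atol=1e-9)

    def test_profile_length_equals_point_count(self, default_case, default_samples):
        prof = build_profile(default_case, default_samples)
        assert prof.n_points == default_case.centerline.n_points

    def test_default_noise_round_trip_within_one_mmhg(self, default_case, default_profile, default_samples):
        prof = build_profile(default_case, default_samples)
        assert np.max(np.abs(prof.pressure - default_profile.pressure)) < 1.0

    def test_missing_sections_listed(self, default_case, default_samples):
        crippled = FieldSamples(
            pressure=default_samples.pressure[:-5],
            wss=default_samples.wss,
            flow_rate=default_samples.flow_rate,
        )
        with pytest.raises(MissingDataError):
            build_profile(default_case, crippled)
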