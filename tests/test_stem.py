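"""Cross-section chain: slice, circle fit, unwrap, Fourier, band, perimeter."""

import numpy as np
import pytest

import stemscan as ss
from stemscan import stem as st
from helpers import circle_points, grid_search_circle


class TestSlice:
    def test_band_keeps_expected_fraction_of_uniform_cylinder(self, rng):
        # oracle: direct height filter on the same sample
        n = 200_000
        th = rng.uniform(0, 2 * np.pi, n)
        z = rng.uniform(0, 2.0, n)
        pts = np.column_stack((0.15 * np.cos(th), 0.15 * np.sin(th), z))
        cloud = ss.PointCloud(pts)
        secs = st.extract_dbh_slice(cloud, ground=0.0)
        kept = sum(len(s.points) for s in secs)
        assert kept == int(((z >= 1.30) & (z < 1.35)).sum())
        assert kept / n == pytest.approx(0.025, abs=0.002)

    def test_default_band_is_five_centimetres_at_breast_height(self):
        assert st.DEFAULT_CENTER_HEIGHT - st.DEFAULT_THICKNESS / 2 == pytest.approx(1.30)
        assert st.DEFAULT_CENTER_HEIGHT + st.DEFAULT_THICKNESS / 2 == pytest.approx(1.35)

    def test_band_above_object_returns_empty(self):
        pts = np.column_stack((np.zeros(100), np.zeros(100), np.linspace(0, 1, 100)))
        assert st.extract_dbh_slice(ss.PointCloud(pts), ground=0.0) == []

    def test_two_stems_are_separated(self, rng):
        a = circle_points(200, r=0.1, cx=0.0)
        b = circle_points(200, r=0.1, cx=4.0)
        z = np.full(400, 1.32)
        cloud = ss.PointCloud(np.column_stack((np.vstack([a, b]), z)))
        secs = st.extract_dbh_slice(cloud, ground=0.0)
        assert len(secs) == 2
        assert all(len(s.points) == 200 for s in secs)

    def test_missing_ground_is_an_error(self):
        cloud = ss.PointCloud(np.zeros((5, 3)))
        with pytest.raises(ValueError, match="ground"):
            st.extract_dbh_slice(cloud, ground=None)


class TestCircleFit:
    def test_exact_circle_recovered_to_machine_precision(self):
        pts = circle_points(100, r=0.25, cx=1.0, cy=2.0)
        c = st.fit_circle(pts)
        assert c.center[0] == pytest.approx(1.0, abs=1e-9)
        assert c.center[1] == pytest.approx(2.0, abs=1e-9)
        assert c.radius == pytest.approx(0.25, abs=1e-9)

    def test_three_points_give_circumcircle(self):
        # circumcircle of (0,0), (2,0), (0,2) is centre (1,1), radius sqrt2
        pts = np.array([[0.0, 0.0], [2.0, 0.0], [0.0, 2.0]])
        c = st.fit_circle(pts)
        assert c.center == pytest.approx((1.0, 1.0), abs=1e-9)
        assert c.radius == pytest.approx(np.sqrt(2), abs=1e-9)

    def test_agrees_with_grid_search_oracle_on_noisy_circle(self, rng):
        sigma, n = 0.002, 2000
        pts = circle_points(n, r=0.25)
        pts += rng.normal(0, sigma, pts.shape)
        c = st.fit_circle(pts)
        (ox, oy), orad = grid_search_circle(pts, (0.0, 0.0))
        tol = 3 * sigma / np.sqrt(n)
        assert abs(c.radius - orad) < tol
        assert abs(c.radius - 0.25) < 3 * tol

    def test_collinear_points_rejected(self):
        pts = np.column_stack((np.linspace(0, 1, 50), np.linspace(0, 2, 50)))
        with pytest.raises(ValueError, match="collinear"):
            st.fit_circle(pts)


class TestUnwrap:
    def test_exact_circle_has_zero_deviation(self):
        pts = circle_points(500, r=0.2, cx=3.0, cy=-1.0)
        c = st.FittedCircle((3.0, -1.0), 0.2)
        prof = st.unwrap_to_polar(pts, c)
        assert np.abs(prof.deviation).max() < 1e-9
        assert np.all(np.diff(prof.theta) >= 0)

    def test_point_due_east_has_defined_angle_and_millimetre_deviation(self):
        c = st.FittedCircle((0.0, 0.0), 0.2)
        prof = st.unwrap_to_polar(np.array([[0.201, 0.0]]), c)
        assert prof.theta[0] == pytest.approx(0.0)
        assert prof.deviation[0] == pytest.approx(1.0)

    def test_ellipse_deviation_is_second_harmonic(self):
        # oracle: discrete Fourier decomposition of the deviation signal
        e = 0.05
        th = np.radians(np.arange(0, 360, 0.5))
        r = 0.25 * (1 + e * np.cos(2 * th))
        pts = np.column_stack((r * np.cos(th), r * np.sin(th)))
        c = st.fit_circle(pts)
        prof = st.unwrap_to_polar(pts, c)
        spec = np.abs(np.fft.rfft(prof.deviation))
        assert spec[2] > 5 * max(spec[1], spec[3], spec[4])

    def test_point_at_centre_rejected(self):
        c = st.FittedCircle((0.0, 0.0), 0.2)
        with pytest.raises(ValueError, match="centre"):
            st.unwrap_to_polar(np.array([[0.0, 0.0], [0.2, 0.0]]), c)


class TestFourier:
    def test_constant_deviation_is_pure_dc(self):
        prof = st.UnwrappedProfile(np.linspace(0, 359, 100), np.full(100, 4.2))
        m = st.fit_fourier(prof, K=5)
        assert m.a0 == pytest.approx(4.2, abs=1e-9)
        assert np.abs(np.array(m.harmonics)).max() < 1e-9

    def test_pure_second_harmonic_recovered(self):
        th = np.linspace(0, 360, 400, endpoint=False)
        prof = st.UnwrappedProfile(th, 3.0 * np.cos(np.radians(2 * th)))
        m = st.fit_fourier(prof, K=4)
        assert m.harmonics[1][0] == pytest.approx(3.0, abs=1e-9)
        res = prof.deviation - m(prof.theta)
        assert np.abs(res).max() < 1e-9

    def test_white_noise_absorbed_variance_matches_projection(self, rng):
        # oracle: LSQ projection absorbs ~(2K+1)/n of the noise variance
        n, K, sigma = 5000, 8, 1.0
        th = rng.uniform(0, 360, n)
        dev = rng.normal(0, sigma, n)
        m = st.fit_fourier(st.UnwrappedProfile(th, dev), K=K)
        fitted = m(th)
        assert fitted.var() <= (2 * K + 1) / n * sigma**2 * 1.5

    def test_too_few_points_rejected(self):
        prof = st.UnwrappedProfile(np.arange(10.0), np.arange(10.0))
        with pytest.raises(ValueError, match="at least"):
            st.fit_fourier(prof, K=5)


class TestResidualBand:
    def test_zero_residuals_give_zero_width(self):
        th = np.linspace(0, 359, 100)
        prof = st.UnwrappedProfile(th, np.zeros(100))
        band = st.residual_band95(prof, st.fit_fourier(prof, K=2))
        assert band.width95 == pytest.approx(0.0, abs=1e-12)

    def test_gaussian_residuals_match_normal_central_interval(self, rng):
        # oracle: central 95% interval of N(0, 1) is 2 * 1.96 = 3.92 mm
        n = 100_000
        prof = st.UnwrappedProfile(rng.uniform(0, 360, n), rng.normal(0, 1.0, n))
        band = st.residual_band95(prof, st.fit_fourier(prof, K=0))
        assert band.width95 == pytest.approx(3.92, abs=0.05)
        assert band.n_points == n

    def test_uniform_residuals_match_analytic_interval(self, rng):
        # central 95% of U(-1, 1) spans 0.95 * 2 = 1.90 mm
        n = 100_000
        prof = st.UnwrappedProfile(rng.uniform(0, 360, n), rng.uniform(-1, 1, n))
        band = st.residual_band95(prof, st.fit_fourier(prof, K=0))
        assert band.width95 == pytest.approx(1.90, abs=0.02)

    def test_few_residuals_warn_but_compute(self):
        th = np.linspace(0, 359, 20)
        prof = st.UnwrappedProfile(th, np.sin(np.radians(th)))
        model = st.fit_fourier(prof, K=1)
        with pytest.warns(UserWarning, match="unstable"):
            band = st.residual_band95(prof, model)
        assert band.width95 >= 0

    def test_shortest_interval_never_wider_than_central(self, rng):
        n = 20_000
        prof = st.UnwrappedProfile(
            rng.uniform(0, 360, n), rng.exponential(1.0, n)
        )
        m = st.fit_fourier(prof, K=0)
        assert (
            st.residual_band95(prof, m, shortest=True).width95
            <= st.residual_band95(prof, m).width95 + 1e-12
        )


class TestPerimeter:
    def test_dense_circle_matches_regular_polygon_closed_form(self):
        # inscribed 72-gon perimeter is 2 n R sin(pi/n)
        R, nbins = 0.25, 72
        pts = circle_points(20_000, r=R)
        c = st.fit_circle(pts)
        poly = st.perimeter_polygon(pts, c, n_bins=nbins)
        expected = 2 * nbins * R * np.sin(np.pi / nbins)
        assert poly.perimeter == pytest.approx(expected, rel=1e-3)
        assert abs(poly.perimeter - 2 * np.pi * R) / (2 * np.pi * R) < 0.005

    def test_square_section_perimeter(self):
        s = 0.4
        edge = np.linspace(-s / 2, s / 2, 4000)
        sides = [
            np.column_stack((edge, np.full_like(edge, -s / 2))),
            np.column_stack((edge, np.full_like(edge, s / 2))),
            np.column_stack((np.full_like(edge, -s / 2), edge)),
            np.column_stack((np.full_like(edge, s / 2), edge)),
        ]
        pts = np.vstack(sides)
        c = st.fit_circle(pts)
        poly = st.perimeter_polygon(pts, c, n_bins=72, quantile=1.0)
        assert poly.perimeter == pytest.approx(4 * s, rel=0.02)

    def test_sparse_bins_without_interpolation_rejected(self):
        pts = circle_points(30, r=0.2, arc=15.0)  # 3 occupied bins of 72
        c = st.FittedCircle((0.0, 0.0), 0.2)
        with pytest.raises(ValueError, match="empty angular bins"):
            st.perimeter_polygon(pts, c, n_bins=72, interpolate=False)

    def test_single_occupied_bin_rejected(self):
        pts = np.tile([[0.2, 0.0]], (10, 1))
        c = st.FittedCircle((0.0, 0.0), 0.2)
        with pytest.raises(ValueError, match="single"):
            st.perimeter_polygon(pts, c, n_bins=72)


class TestDbhFromPerimeter:
    def test_inverts_circumference(self):
        poly = st.PerimeterPolygon(circle_points(5000, r=0.505 / 2))
        assert st.dbh_from_perimeter(poly) == pytest.approx(50.5, abs=0.01)

    def test_unit_perimeter(self):
        # vertices chosen so the closed polygon length is exactly 1 m
        quarter = 0.25
        verts = np.array([[0, 0], [quarter, 0], [quarter, quarter], [0, quarter]])
        poly = st.PerimeterPolygon(verts)
        assert poly.perimeter == pytest.approx(1.0)
        assert st.dbh_from_perimeter(poly) == pytest.approx(31.83, abs=0.01)

    def test_hexagon_documents_polygon_coarseness_bias(self):
        # regular hexagon of circumradius R: perimeter 6R, diameter 6R/pi,
        # a 4.5% underestimate of 2R
        R = 0.3
        th = np.radians(np.arange(0, 360, 60))
        verts = np.column_stack((R * np.cos(th), R * np.sin(th)))
        d = st.dbh_from_perimeter(st.PerimeterPolygon(verts))
        assert d == pytest.approx(6 * R / np.pi * 100, abs=1e-9)
        assert d / (2 * R * 100) == pytest.approx(3 / np.pi, abs=1e-9)


class TestChainInvariants:
    @pytest.mark.parametrize("K", [4, 8, 12])
    def test_noise_band_recovers_radial_sigma(self, K):
        sigma = 0.005
        pts = ss.synthetic_section_points(0.25, 4000, sigma, seed=31)
        sec = st.CrossSection(pts, band=(1.30, 1.35))
        band = st.section_noise_band(sec, K=K)
        assert band.width95 == pytest.approx(3.92 * sigma * 1000, rel=0.10)

    def test_band_width_monotone_in_noise(self):
        widths = []
        for sigma_mm in (1, 5, 10, 20):
            pts = ss.synthetic_section_points(0.25, 4000, sigma_mm / 1000, seed=7)
            sec = st.CrossSection(pts, band=(1.30, 1.35))
            widths.append(st.section_noise_band(sec, K=8).width95)
        assert widths == sorted(widths)

    def test_rigid_motion_leaves_statistics_unchanged(self, rng):
        pts = ss.synthetic_section_points(0.25, 2000, 0.003, seed=3)
        sec = st.CrossSection(pts, band=(1.30, 1.35))
        ang = np.radians(37.0)
        rot = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
        moved = st.CrossSection(pts @ rot.T + [12.0, -7.0], band=(1.30, 1.35))
        a, b = st.fit_circle(sec), st.fit_circle(moved)
        assert abs(a.radius - b.radius) < 1e-9
        assert abs(
            st.section_noise_band(sec, K=8).width95
            - st.section_noise_band(moved, K=8).width95
        ) < 1e-9
        assert abs(st.estimate_dbh(sec) - st.estimate_dbh(moved)) < 1e-9
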