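import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import pvsflow as pf
from pvsflow.geometry import InvalidGeometryError

from conftest import ellipse_section


def mc_polar_moment(vertices, n_samples=2_000_000, seed=0):
    """Monte-Carlo oracle for area and polar moment of a polygon."""
    import shapely

    from shapely.geometry import Polygon

    poly = Polygon(vertices)
    minx, miny, maxx, maxy = poly.bounds
    rng = np.random.default_rng(seed)
    x = rng.uniform(minx, maxx, n_samples)
    y = rng.uniform(miny, maxy, n_samples)
    inside = shapely.contains_xy(poly, x, y)
    box = (maxx - minx) * (maxy - miny)
    A = box * inside.mean()
    cx, cy = x[inside].mean(), y[inside].mean()
    Ip = box * inside.mean() * np.mean(
        (x[inside] - cx) ** 2 + (y[inside] - cy) ** 2
    )
    return A, Ip


class TestPolygonMetrics:
    def test_circle_limits(self):
        sec = pf.CrossSection(z=0.0, vertices=pf.circle_polygon(1.0, 1000))
        m = pf.polygon_metrics(sec)
        assert m.A == pytest.approx(np.pi, rel=1e-4)
        assert m.beta == pytest.approx(1.0, abs=1e-6)
        assert m.I_p == pytest.approx(np.pi / 2.0, rel=1e-4)
        assert m.D_h <= 2.0 * m.r_eq

    def test_matched_ellipse_recovers_axis_ratio(self):
        m = pf.polygon_metrics(ellipse_section(2.0, 1.0, n=1000))
        assert m.beta == pytest.approx(2.0, rel=1e-5)
        assert m.A == pytest.approx(2.0 * np.pi, rel=1e-4)

    def test_square_moments_against_monte_carlo(self):
        v = np.array([[-1.0, -1.0], [1.0, -1.0], [1.0, 1.0], [-1.0, 1.0]])
        m = pf.polygon_metrics(pf.CrossSection(z=0.0, vertices=v))
        assert m.A == pytest.approx(4.0)
        assert m.I_p == pytest.approx(8.0 / 3.0)  # 2 * a^4/12 with a = 2
        A_mc, Ip_mc = mc_polar_moment(v)
        assert m.A == pytest.approx(A_mc, rel=5e-3)
        assert m.I_p == pytest.approx(Ip_mc, rel=5e-3)

    @pytest.mark.parametrize("seed", range(5))
    def test_random_star_polygon_moments_against_monte_carlo(self, seed):
        rng = np.random.default_rng(seed)
        th = np.linspace(0, 2 * np.pi, 64, endpoint=False)
        rho = 1.0 + 0.35 * rng.random(64)
        v = np.column_stack([rho * np.cos(th), rho * np.sin(th)])
        m = pf.polygon_metrics(pf.CrossSection(z=0.0, vertices=v))
        A_mc, Ip_mc = mc_polar_moment(v, seed=seed)
        assert m.A == pytest.approx(A_mc, rel=5e-3)
        assert m.I_p == pytest.approx(Ip_mc, rel=5e-3)
        assert m.D_h <= 2.0 * m.r_eq

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        angle=st.floats(0.0, 2 * np.pi),
        dx=st.floats(-50.0, 50.0),
        dy=st.floats(-50.0, 50.0),
    )
    def test_beta_rigid_motion_invariant(self, angle, dx, dy):
        base = ellipse_section(3.0, 1.7, n=128)
        R = np.array(
            [[np.cos(angle), -np.sin(angle)], [np.sin(angle), np.cos(angle)]]
        )
        moved = pf.CrossSection(z=0.0, vertices=base.vertices @ R.T + [dx, dy])
        b0 = pf.polygon_metrics(base).beta
        b1 = pf.polygon_metrics(moved).beta
        assert b1 == pytest.approx(b0, rel=1e-9)

    def test_degenerate_polygons_rejected(self):
        with pytest.raises(InvalidGeometryError):
            pf.CrossSection(z=0.0, vertices=[[0, 0], [1, 0]])
        with pytest.raises(InvalidGeometryError):
            pf.CrossSection(z=0.0, vertices=[[0, 0], [1, 0], [2, 0]])
        with pytest.raises(InvalidGeometryError):  # bow-tie
            pf.CrossSection(z=0.0, vertices=[[0, 0], [1, 1], [1, 0], [0, 1]])


class TestBuildDuct:
    @staticmethod
    def _circle_stack(radii, dz=0.7):
        return [
            pf.CrossSection(z=i * dz, vertices=pf.circle_polygon(r))
            for i, r in enumerate(radii)
        ]

    def test_constant_area_has_zero_derivatives(self):
        duct = pf.build_duct(self._circle_stack([5.0] * 30))
        assert np.allclose(duct.dA_dz, 0.0, atol=1e-9)
        assert np.allclose(duct.d2A_dz2, 0.0, atol=1e-9)

    def test_quadratic_area_second_derivative_exact(self):
        # A(z) = z^2 realized via r = sqrt(z^2/pi); central differences on a
        # uniform grid are exact for quadratics
        z = np.arange(5.0, 105.0, 0.7)
        secs = [
            pf.CrossSection(z=zi, vertices=pf.circle_polygon(np.sqrt(zi**2 / np.pi)))
            for zi in z
        ]
        duct = pf.build_duct(secs, resample_dz=0.7)
        interior = slice(2, -2)
        assert np.allclose(duct.d2A_dz2[interior], 2.0, rtol=2e-3)

    def test_sinusoid_area_curvature_matches_analytic(self, sinusoid_duct):
        # A = pi r^2 -> A'' = 2 pi (r r'' + r'^2); at the first bulge r'=0
        i = np.argmin(np.abs(sinusoid_duct.z - 12.5))
        r, k = 51.5, 2 * np.pi / 50.0
        expected = 2 * np.pi * (r * (-1.5 * k**2))
        assert sinusoid_duct.d2A_dz2[i] == pytest.approx(expected, rel=1e-2)

    def test_nonmonotone_z_rejected(self):
        secs = self._circle_stack([5.0] * 6)
        secs[3] = pf.CrossSection(z=0.1, vertices=pf.circle_polygon(5.0))
        with pytest.raises(InvalidGeometryError, match="strictly increas"):
            pf.build_duct(secs)


class TestCircularize:
    def test_preserves_area_profile(self, bilobe_duct):
        circ = pf.circularize(bilobe_duct)
        assert circ.circular
        assert np.allclose(circ.area_profile, bilobe_duct.area_profile, rtol=1e-3)

    def test_constant_elliptical_duct_becomes_circle(self):
        duct = pf.make_elliptical_duct(2.0, 1.0, length=10.0, dz=0.7)
        circ = pf.circularize(duct)
        m = pf.polygon_metrics(circ.sections[0])
        assert m.beta == pytest.approx(1.0, abs=1e-6)
        assert m.r_eq == pytest.approx(np.sqrt(2.0), rel=1e-3)

    def test_circle_minimizes_resistance_at_fixed_area(self, bilobe_duct):
        # per-station SUN of the circularized duct never exceeds the original
        for i in range(0, len(bilobe_duct), 25):
            R_orig = pf.sun_resistance(bilobe_duct.sections[i], mu=1.0)
            circ = pf.circularize(bilobe_duct)
            R_circ = pf.sun_resistance(circ.sections[i], mu=1.0)
            assert R_circ <= R_orig


class TestDeanNumber:
    def test_pial_pvs_magnitude(self):
        # Re ~ 1e-3, r_e ~ 6 um, r_c ~ 100 um -> De ~ 2.5e-4
        de = pf.dean_number(1e-3, 6.0, 100.0)
        assert de == pytest.approx(2.449e-4, rel=1e-3)
        assert de == pytest.approx(2.5e-4, abs=6e-6)  # printed to 2 figures

    def test_limits(self):
        assert pf.dean_number(0.0, 6.0, 100.0) == 0.0
        assert pf.dean_number(1e-3, 6.0, np.inf) == 0.0
        with pytest.raises(ValueError):
            pf.dean_number(1e-3, 6.0, 0.0)

    def test_curvature_radius_of_circular_arc(self):
        th = np.linspace(0, np.pi / 4, 20)
        pts = np.column_stack([100 * np.cos(th), 100 * np.sin(th), np.zeros_like(th)])
        r_c = pf.centerline_curvature_radius(pts)
        assert np.allclose(r_c[1:-1], 100.0, rtol=1e-6)

    def test_straight_centerline_gives_infinite_radius(self):
        pts = np.column_stack([np.zeros(10), np.zeros(10), np.arange(10.0)])
        r_c = pf.centerline_curvature_radius(pts)
        assert np.all(np.isinf(r_c))
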