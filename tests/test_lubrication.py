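import numpy as np
import pytest

import pvsflow as pf
from pvsflow.lubrication import ANALYTIC_SLOPE
from pvsflow.sun import ResistanceProfile

from conftest import ellipse_R_exact


class TestZerothOrder:
    def test_circle_is_hagen_poiseuille(self):
        p = pf.EllipseProfile(b=1.0, c=1.0)
        assert pf.ellipse_R0(p, mu=1.0) == pytest.approx(8.0 / np.pi)

    def test_two_to_one_ellipse(self):
        p = pf.EllipseProfile(b=2.0, c=1.0)
        assert pf.ellipse_R0(p, mu=1.0) == pytest.approx(20.0 / (8.0 * np.pi))

    def test_axis_and_area_forms_agree(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            b = 1.0 + 4.0 * rng.random()
            c = b / (1.0 + 3.0 * rng.random())
            R1 = pf.ellipse_R0(pf.EllipseProfile(b=b, c=c), mu=1.0)
            R2 = pf.ellipse_R0_area_form(np.pi * b * c, b / c, mu=1.0)
            assert R1 == pytest.approx(R2, rel=1e-12)


class TestSecondOrder:
    def test_uniform_duct_has_zero_correction(self):
        assert pf.ellipse_R2(pf.EllipseProfile(b=2.0, c=1.0), 1.0) == 0.0
        assert pf.fixed_beta_R2(10.0, 0.0, 0.0, 2.0, 1.0) == 0.0

    def test_linear_taper_hand_value(self):
        # b = c = 1, b' = c' = 0.1: R2 = -16 mu s^2 / (3 pi r^4)
        p = pf.EllipseProfile(b=1.0, c=1.0, db_dz=0.1, dc_dz=0.1)
        assert pf.ellipse_R2(p, mu=1.0) == pytest.approx(
            -16.0 * 0.01 / (3.0 * np.pi), rel=1e-12
        )

    def test_linear_taper_consistent_with_area_form(self):
        r, s = 1.0, 0.1
        p = pf.EllipseProfile(b=r, c=r, db_dz=s, dc_dz=s)
        A, dA, d2A = np.pi * r**2, 2 * np.pi * r * s, 2 * np.pi * s**2
        assert pf.ellipse_R2(p, 1.0) == pytest.approx(
            pf.fixed_beta_R2(A, dA, d2A, 1.0, 1.0), rel=1e-12
        )

    def test_symmetric_under_axis_swap(self):
        p1 = pf.EllipseProfile(2.0, 1.3, 0.05, -0.02, 0.01, 0.003)
        p2 = pf.EllipseProfile(1.3, 2.0, -0.02, 0.05, 0.003, 0.01)
        assert pf.ellipse_R2(p1, 1.0) == pytest.approx(pf.ellipse_R2(p2, 1.0), rel=1e-12)

    @pytest.mark.parametrize("beta", [1.0, 2.0, 3.5])
    def test_general_form_reduces_to_fixed_beta_on_self_similar_profiles(self, beta):
        rng = np.random.default_rng(int(beta * 10))
        for _ in range(20):
            c = 0.5 + 2.0 * rng.random()
            dc = 0.2 * rng.standard_normal()
            d2c = 0.05 * rng.standard_normal()
            p = pf.EllipseProfile(beta * c, c, beta * dc, dc, beta * d2c, d2c)
            A = np.pi * beta * c**2
            dA = 2 * np.pi * beta * c * dc
            d2A = 2 * np.pi * beta * (c * d2c + dc**2)
            R2a = pf.ellipse_R2(p, mu=1.0)
            R2b = pf.fixed_beta_R2(A, dA, d2A, beta, mu=1.0)
            assert R2a == pytest.approx(R2b, rel=1e-10)

    def test_fixed_beta_matches_circular_sinusoid_stations(self, sinusoid_duct):
        spec = pf.SinusoidSpec()
        k = 2 * np.pi / spec.wavelength
        for z in [5.0, 12.5, 20.0, 37.5]:
            r = spec.radius(z)
            dr = spec.amp * k * np.cos(k * z)
            d2r = -spec.amp * k**2 * np.sin(k * z)
            p = pf.EllipseProfile(r, r, dr, dr, d2r, d2r)
            A, dA = np.pi * r**2, 2 * np.pi * r * dr
            d2A = 2 * np.pi * (r * d2r + dr**2)
            assert pf.ellipse_R2(p, 1.0) == pytest.approx(
                pf.fixed_beta_R2(A, dA, d2A, 1.0, 1.0), rel=1e-10
            )

    def test_symbolic_rederivation_of_averaged_pressure_gradient(self):
        """The cross-section average of the pointwise 2nd-order pressure
        gradient equals -Q * R2 (one-time algebraic verification kept as a
        regression guard)."""
        import sympy as sp

        b, c, db, dc, d2b, d2c, mu, Q = sp.symbols(
            "b c db dc d2b d2c mu Q", positive=True
        )
        x2, y2 = b**2 / 4, c**2 / 4  # ellipse averages of x^2 and y^2
        avg = (
            mu * Q / (3 * sp.pi * b**5 * c**5)
            * (
                b**2 * c**2 * (2 * db**2 * (6 * x2 - 7 * c**2)
                               + (6 * y2 - c**2) * (2 * dc**2 - c * d2c))
                + b**4 * (-2 * c**2 * (db**2 + 7 * dc**2)
                          + c * (c**2 - 18 * y2) * d2c + 72 * y2 * dc**2)
                + 72 * x2 * c**4 * db**2
                + b**3 * c * (c * d2b * (c**2 - 6 * x2)
                              + 6 * db * dc * (3 * (x2 + y2) - c**2))
                + 3 * b * c**3 * (db * dc * (6 * (x2 + y2) - c**2)
                                  - 6 * x2 * c * d2b)
                + b**5 * c * (c * d2b - 3 * db * dc)
            )
        )
        R2 = -(mu / (6 * sp.pi * b**4 * c**4)) * (
            3 * c**4 * db * dc
            + b**3 * c * (2 * db**2 - 7 * c * d2c + 8 * dc**2)
            + b * c**3 * (8 * db**2 - c * d2c + 2 * dc**2)
            + b**4 * (3 * db * dc - c * d2b)
            + b**2 * c**2 * (6 * db * dc - 7 * c * d2b)
        )
        assert sp.simplify(avg + Q * R2) == 0


class TestErrorModel:
    def test_circle_prefactor_is_one_over_six_pi(self):
        assert pf.beta_prefactor(1.0) == pytest.approx(1.0 / (6.0 * np.pi), rel=1e-12)

    @pytest.mark.parametrize("beta", [2.0, 3.0, 5.0])
    def test_prefactor_symmetric_in_inverse_beta(self, beta):
        assert pf.beta_prefactor(beta) == pytest.approx(
            pf.beta_prefactor(1.0 / beta), rel=1e-12
        )

    def test_prefactor_deviation_bound(self):
        assert pf.beta_prefactor_max_deviation(step=0.5) == pytest.approx(
            13.33, abs=0.01
        )
        assert 13.3 <= pf.beta_prefactor_max_deviation() <= 13.5

    def test_uniform_duct_has_zero_error(self):
        full, lead = pf.elt_error(10.0, 0.0, 0.0, beta=1.5)
        assert full == 0.0 and lead == 0.0

    def test_error_positive_at_constrictions_negative_at_bulges(self, sinusoid_duct):
        # constriction: area minimum, A'' > 0 -> uniform-duct model under-
        # estimates (E > 0); bulge: A'' < 0 -> overestimates (E < 0)
        i_con = np.argmin(sinusoid_duct.area_profile)
        i_bul = np.argmax(sinusoid_duct.area_profile)
        for i, sign in [(i_con, 1.0), (i_bul, -1.0)]:
            full, lead = pf.elt_error(
                sinusoid_duct.area_profile[i],
                sinusoid_duct.dA_dz[i],
                sinusoid_duct.d2A_dz2[i],
            )
            assert np.sign(full) == sign and np.sign(lead) == sign

    def test_analytic_slope_value(self):
        assert ANALYTIC_SLOPE == pytest.approx(-5.305, abs=5e-3)


class TestLambdaCorrection:
    def test_fitted_circular_model_at_flat_station(self):
        lam = pf.CorrectionModel.circular().lambda_factor(0.0)
        assert lam == pytest.approx(100.0 / 100.22, rel=1e-12)

    def test_analytic_model_is_identity_at_flat_station(self):
        assert pf.CorrectionModel.analytic().lambda_factor(0.0) == 1.0

    def test_out_of_range_curvature_raises(self):
        with pytest.raises(ValueError, match="validity"):
            pf.CorrectionModel.analytic().lambda_factor(np.array([20.0]))

    def test_correction_rescales_profile_and_tags_method(self):
        prof = ResistanceProfile(
            z=np.array([0.0, 1.0, 2.0]),
            R_local=np.array([1.0, 2.0, 1.0]),
            method="SUA",
            d2A_dz2=np.array([0.5, 0.0, -0.5]),
        )
        corr = pf.lambda_correct(prof, model="circular")
        assert corr.method == "SUA·λ"
        lam = pf.CorrectionModel.circular().lambda_factor(prof.d2A_dz2)
        assert np.allclose(corr.R_local, prof.R_local * lam)

    def test_unknown_model_rejected(self):
        with pytest.raises(ValueError):
            pf.CorrectionModel.from_kind("quadratic")
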