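"""Guinier, Kratky, PDDF and sphere-relation analysis."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from micellkit import sas
from micellkit.synth import SasGeneratorSpec, gen_scattering_curve


def exact_guinier_curve(rg=1.7, qmax=3.0):
    q = np.geomspace(0.05, qmax, 120)
    return sas.ScatteringCurve(q, np.exp(-q**2 * rg**2 / 3.0))


class TestGuinier:
    def test_exact_curve_recovery(self):
        fit = sas.guinier_fit(exact_guinier_curve(1.7))
        assert fit.rg == pytest.approx(1.7, rel=1e-6)
        assert fit.i0 == pytest.approx(1.0, rel=1e-6)
        assert fit.qrg_max <= 1.3

    def test_sphere_form_factor_rg(self):
        """Recovered R_g obeys the sphere relation R_g = √(3/5)·R within 2%."""
        curve, truth = gen_scattering_curve(SasGeneratorSpec(radius=2.2))
        fit = sas.guinier_fit(curve)
        assert fit.rg == pytest.approx(np.sqrt(3 / 5) * 2.2, rel=0.02)

    def test_flat_curve_gives_zero_rg(self):
        q = np.geomspace(0.05, 3, 60)
        fit = sas.guinier_fit(sas.ScatteringCurve(q, np.ones_like(q)))
        assert fit.rg == 0.0

    def test_nonpositive_intensity_rejected(self):
        q = np.geomspace(0.05, 3, 60)
        y = np.exp(-q**2)
        y[5] = -1.0
        with pytest.raises(ValueError, match="non-positive"):
            sas.guinier_fit(sas.ScatteringCurve(q, y))

    def test_unit_safety_nm_vs_angstrom(self):
        """The same physical curve in Å⁻¹ and nm⁻¹ yields identical R_g (nm)."""
        curve_nm = exact_guinier_curve(1.7)
        curve_a = sas.ScatteringCurve(curve_nm.q / 10.0, curve_nm.intensity, units="A^-1")
        assert sas.guinier_fit(curve_a).rg == pytest.approx(sas.guinier_fit(curve_nm).rg, rel=1e-12)


class TestShapeIndicator:
    @pytest.mark.parametrize("x,expect", [
        (1.25, "globular"), (0.7, "elongated"), (0.85, "indeterminate"),
        (1.3, "indeterminate"), (2.0, "indeterminate"),
    ])
    def test_classification(self, x, expect):
        assert sas.shape_indicator(x) == expect

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            sas.shape_indicator(0.0)


class TestKratky:
    def test_inverse_square_becomes_constant(self):
        q = np.geomspace(0.1, 2, 50)
        kr = sas.kratky_transform(sas.ScatteringCurve(q, 1.0 / q**2))
        assert np.allclose(kr.intensity, 1.0)

    def test_uncertainty_propagation_exact(self):
        q = np.geomspace(0.1, 2, 50)
        sig = np.linspace(0.1, 0.5, 50)
        kr = sas.kratky_transform(sas.ScatteringCurve(q, np.ones_like(q), sig))
        assert np.allclose(kr.sigma, q**2 * sig)

    def test_sphere_is_bell_chain_is_not(self):
        sphere, _ = gen_scattering_curve(SasGeneratorSpec(radius=2.2))
        assert sas.kratky_is_bell(sphere)
        q = np.geomspace(0.05, 5, 120)
        chain = sas.ScatteringCurve(q, sas.debye_intensity(q, 1.7))
        assert not sas.kratky_is_bell(chain)


class TestPDDF:
    def test_sphere_recovery(self):
        """p(r) of a noise-free sphere matches the analytic shape on the grid."""
        curve, _ = gen_scattering_curve(SasGeneratorSpec(radius=2.2))
        pddf = sas.pddf_ift(curve, d_max=4.4)
        analytic = sas.sphere_pddf(pddf.r, 2.2)
        step = pddf.r[1] - pddf.r[0]
        assert abs(pddf.peak_r - pddf.r[np.argmax(analytic)]) <= step + 1e-12
        assert np.all(pddf.p >= -1e-12)
        assert pddf.p[0] == 0.0 and pddf.p[-1] == 0.0

    def test_forward_round_trip(self):
        curve, _ = gen_scattering_curve(SasGeneratorSpec(radius=2.2))
        pddf = sas.pddf_ift(curve, d_max=4.4)
        back = sas.pddf_forward(pddf, curve.q)
        rel = np.linalg.norm(back - curve.intensity) / np.linalg.norm(curve.intensity)
        assert rel < 0.01

    def test_rg_consistent_with_guinier(self):
        curve, _ = gen_scattering_curve(SasGeneratorSpec(radius=2.2))
        pddf = sas.pddf_ift(curve, d_max=4.4)
        guinier = sas.guinier_fit(curve)
        assert pddf.rg == pytest.approx(guinier.rg, rel=0.05)

    def test_support_matches_analytic_oracle(self):
        """Recovered support end agrees with the analytic-sphere support
        (same threshold estimator, same grid) within one grid step."""
        curve, _ = gen_scattering_curve(SasGeneratorSpec(radius=2.2, noise_rel=0.01, seed=3))
        pddf = sas.pddf_ift(curve, d_max=6.0)
        r = pddf.r
        oracle = sas.PDDF(r=r, p=sas.sphere_pddf(r, 2.2), d_max=6.0, alpha=0.0)
        step = r[1] - r[0]
        assert abs(sas.pddf_support(pddf) - sas.pddf_support(oracle)) <= step + 1e-12

    def test_invalid_dmax(self):
        curve, _ = gen_scattering_curve(SasGeneratorSpec(radius=2.2))
        with pytest.raises(ValueError):
            sas.pddf_ift(curve, d_max=-1.0)


class TestSphereRelations:
    def test_unit_radius(self):
        assert sas.rg_from_radius(1.0) == pytest.approx(0.7746, abs=1e-4)

    def test_inverse_reference_value(self):
        assert sas.radius_from_rg(1.9) == pytest.approx(2.453, abs=1e-3)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(r=st.floats(1e-3, 1e3))
    def test_round_trip_identity(self, r):
        assert sas.radius_from_rg(sas.rg_from_radius(r)) == pytest.approx(r, rel=1e-12)
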