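"""Sigmoid enthalpogram model, inflection location and fitting."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from micellkit import itc
from micellkit.synth import ItcGeneratorSpec, gen_itc_curve


def make_model(**kw):
    base = dict(h_ia=5.0, h_ib=0.0, h_fa=1.0, h_fb=0.0, cmc=0.07, width=0.005, n=1.0)
    base.update(kw)
    return itc.SigmoidModel(**base)


class TestEvalSigmoid:
    def test_low_concentration_limit_is_initial_baseline(self):
        m = make_model()
        assert itc.eval_sigmoid(m, m.cmc - 50 * m.width) == pytest.approx(5.0)

    def test_high_concentration_limit_is_final_baseline(self):
        m = make_model()
        assert itc.eval_sigmoid(m, m.cmc + 50 * m.width) == pytest.approx(1.0)

    def test_symmetric_logistic_midpoint(self):
        # for n = 1 the curve passes through the baseline midpoint at the centre
        assert itc.eval_sigmoid(make_model(), 0.07) == pytest.approx(3.0)

    @pytest.mark.parametrize("bad", [dict(width=-1e-3), dict(width=0.0), dict(n=0.0), dict(n=-2.0)])
    def test_invalid_model_rejected(self, bad):
        with pytest.raises(itc.InvalidModelError):
            itc.eval_sigmoid(make_model(**bad), 0.07)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        h_ia=st.floats(-10, 10), h_ib=st.floats(-20, 20),
        h_fa=st.floats(-10, 10), h_fb=st.floats(-20, 20),
        cmc=st.floats(0.01, 0.2), width=st.floats(1e-4, 0.02),
        n=st.floats(0.5, 5.0),
    )
    def test_limit_equivalence_property(self, h_ia, h_ib, h_fa, h_fb, cmc, width, n):
        """Far from the step the model equals its linear baselines.

        The step decays like exp(−n·u), so the 50-width offset is stretched
        for exponents below one.
        """
        m = itc.SigmoidModel(h_ia, h_ib, h_fa, h_fb, cmc, width, n)
        d = 50 * width * max(1.0, 1.0 / n)
        lo, hi = cmc - d, cmc + d
        assert itc.eval_sigmoid(m, lo) == pytest.approx(m.initial_baseline(lo), rel=1e-9, abs=1e-9)
        assert itc.eval_sigmoid(m, hi) == pytest.approx(m.final_baseline(hi), rel=1e-9, abs=1e-9)


def grid_inflection(model, half_window=None, n_grid=100_001):
    """Independent dense finite-difference scan for the second-derivative zero."""
    hw = half_window or 8 * model.width
    grid = np.linspace(model.cmc - hw, model.cmc + hw, n_grid)
    vals = itc.eval_sigmoid(model, grid)
    d2 = np.gradient(np.gradient(vals, grid), grid)
    idx = np.nonzero(np.diff(np.sign(d2)) != 0)[0]
    # refine each sign change by linear interpolation across the cell
    roots = grid[idx] - d2[idx] * (grid[idx + 1] - grid[idx]) / (d2[idx + 1] - d2[idx])
    return roots[np.argmin(np.abs(roots - model.cmc))]


class TestInflection:
    def test_symmetric_model_inflects_at_centre(self):
        assert itc.cmc_from_second_derivative(make_model()) == pytest.approx(0.07, abs=1e-12)

    def test_asymmetric_exponent_shifts_root(self):
        m = make_model(n=2.0)
        root = itc.cmc_from_second_derivative(m)
        assert root != pytest.approx(0.07, abs=1e-6)
        assert root == pytest.approx(grid_inflection(m), abs=1e-6)

    def test_sloped_baselines_match_grid_oracle(self):
        m = make_model(h_ib=2.0, h_fb=-1.0, n=1.5)
        assert itc.cmc_from_second_derivative(m) == pytest.approx(grid_inflection(m), abs=1e-6)

    def test_grid_oracle_agreement_random_models(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            m = itc.SigmoidModel(
                h_ia=rng.uniform(-8, 8), h_ib=rng.uniform(-15, 15),
                h_fa=rng.uniform(-8, 8), h_fb=rng.uniform(-15, 15),
                cmc=rng.uniform(0.03, 0.15), width=rng.uniform(1e-3, 1e-2),
                n=rng.uniform(0.3, 4.0),
            )
            try:
                root = itc.cmc_from_second_derivative(m)
            except itc.RootNotFoundError:
                continue
            assert root == pytest.approx(grid_inflection(m), abs=1e-6)

    def test_no_sign_change_raises(self):
        # a pure straight line has no inflection: force it by degenerate baselines
        m = make_model(h_ia=1.0, h_fa=1.0)
        with pytest.raises(itc.RootNotFoundError):
            itc.cmc_from_second_derivative(m)


class TestEnthalpyOfMicellisation:
    def test_flat_baseline_difference(self):
        assert itc.enthalpy_of_micellisation(make_model()) == pytest.approx(-4.0, abs=1e-9)

    def test_sloped_baselines_hand_value(self):
        # ΔH_d_f(0.1) − ΔH_d_i(0.1) = (0 − 0.5) − (2 + 1.0) = −3.5
        m = itc.SigmoidModel(2.0, 10.0, 0.0, -5.0, 0.1, 0.004, 1.0)
        assert itc.enthalpy_of_micellisation(m, at=0.1) == pytest.approx(-3.5)

    def test_double_step_heights_recovered(self):
        spec = ItcGeneratorSpec(
            centres=(0.05, 0.12), widths=(0.005, 0.008), exponents=(1.0, 1.0),
            baselines=((5.0, 0.0), (2.0, 0.0), (0.0, 0.0)),  # heights −3 and −2
            noise_sigma=0.0, n_points=140)
        curve, _ = gen_itc_curve(spec)
        fit = itc.fit_enthalpogram(curve, 2)
        dh1, dh2 = itc.enthalpy_of_micellisation(fit)
        assert dh1 == pytest.approx(-3.0, abs=0.05)
        assert dh2 == pytest.approx(-2.0, abs=0.05)


class TestFitEnthalpogram:
    def test_noise_free_exact_recovery(self):
        truth = dict(h_ia=4.0, h_ib=3.0, h_fa=0.5, h_fb=-2.0, cmc=0.08, width=0.006, n=1.4)
        spec = ItcGeneratorSpec(centres=(0.08,), widths=(0.006,), exponents=(1.4,),
                                baselines=((4.0, 3.0), (0.5, -2.0)), noise_sigma=0.0,
                                n_points=80)
        curve, _ = gen_itc_curve(spec)
        fit = itc.fit_enthalpogram(curve, 1)
        for name, val in truth.items():
            assert getattr(fit, name) == pytest.approx(val, rel=1e-6), name

    def test_noisy_centre_within_three_stderr(self):
        curve, _ = gen_itc_curve(ItcGeneratorSpec(noise_sigma=0.05, seed=42))
        fit = itc.fit_enthalpogram(curve, 1)
        assert abs(fit.cmc - 0.07) <= 3 * fit.stderr["cmc"]

    def test_double_sigmoid_centres_ordered_and_recovered(self):
        spec = ItcGeneratorSpec(
            centres=(0.05, 0.12), widths=(0.004, 0.008), exponents=(1.0, 1.0),
            baselines=((5.0, 0.0), (2.0, 0.0), (4.0, -5.0)),
            noise_sigma=0.05, n_points=140, seed=5)
        curve, _ = gen_itc_curve(spec)
        fit = itc.fit_enthalpogram(curve, 2)
        assert fit.cmc < fit.c_trans
        c1, c2 = itc.inflections_from_second_derivative(fit)
        assert abs(c1 - 0.05) <= 3 * itc.inflection_stderr(fit, 0)
        assert abs(c2 - 0.12) <= 3 * itc.inflection_stderr(fit, 1)

    def test_too_few_points_rejected(self):
        c = np.linspace(0.01, 0.1, 6)
        curve = itc.EnthalpogramCurve(298.15, c, np.ones_like(c))
        with pytest.raises(ValueError, match="at least"):
            itc.fit_enthalpogram(curve, 1)

    def test_curve_invariants(self):
        with pytest.raises(ValueError):
            itc.EnthalpogramCurve(298.15, [0.02, 0.01, 0.03], [1, 2, 3])
        with pytest.raises(ValueError):
            itc.EnthalpogramCurve(298.15, [-0.01, 0.01], [1, 2])
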