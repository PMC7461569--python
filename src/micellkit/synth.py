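"""Seeded generators of synthetic enthalpograms and scattering curves.

The generators emulate the statistical structure the analysis stages assume,
so the full pipeline runs and is tested without external data:

* ITC — single- or double-step generalized-logistic enthalpograms with
  linear baselines and additive homoscedastic Gaussian noise, on a
  concentration grid reaching ~5× the (last) step centre, mimicking a
  titration driven well past the c.m.c.
* SAS — polydisperse (lognormal) sphere form-factor curves with flat
  background, relative Gaussian noise and an optional low-Q power-law
  upturn mimicking micelle aggregation.

Every generator is deterministic for a fixed seed and returns the ground
truth next to the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .itc import DoubleSigmoidModel, EnthalpogramCurve, SigmoidModel, eval_double_sigmoid, eval_sigmoid
from .sas import ScatteringCurve, sphere_form_factor

__all__ = ["ItcGeneratorSpec", "SasGeneratorSpec", "gen_itc_curve", "gen_scattering_curve"]


@dataclass
class ItcGeneratorSpec:
    """Forward-model parameters for a synthetic enthalpogram.

    One centre in ``centres`` gives a sigmoidal curve, two give the
    bell-shaped two-step curve.  ``baselines`` holds the (intercept, slope)
    pairs of the successive linear regimes: two lines for one step, three
    for two steps.
    """

    centres: tuple[float, ...] = (0.07,)
    widths: tuple[float, ...] = (0.005,)
    exponents: tuple[float, ...] = (1.0,)
    baselines: tuple[tuple[float, float], ...] = ((5.0, 0.0), (1.0, 0.0))
    noise_sigma: float = 0.05        # kJ mol⁻¹, additive
    n_points: int = 60
    c_max_factor: float = 5.0        # grid reaches this multiple of the last centre
    c_min: float = 1e-3              # mol dm⁻³
    temperature: float = 298.15
    seed: int = 0

    def __post_init__(self):
        k = len(self.centres)
        if k not in (1, 2):
            raise ValueError("one or two step centres required")
        if len(self.widths) != k or len(self.exponents) != k:
            raise ValueError("widths/exponents must match the number of centres")
        if len(self.baselines) != k + 1:
            raise ValueError("need one more baseline than steps")
        if any(w <= 0 for w in self.widths):
            raise ValueError("widths must be positive")
        if k == 2 and not self.centres[0] < self.centres[1]:
            raise ValueError("step centres must be ordered")

    def model(self):
        """The noise-free forward model implied by this spec."""
        if len(self.centres) == 1:
            (ia, ib), (fa, fb) = self.baselines
            return SigmoidModel(ia, ib, fa, fb, self.centres[0],
                                self.widths[0], self.exponents[0])
        return DoubleSigmoidModel(lines=self.baselines,
                                  cmc=self.centres[0], c_trans=self.centres[1],
                                  width1=self.widths[0], width2=self.widths[1],
                                  n1=self.exponents[0], n2=self.exponents[1])


def gen_itc_curve(spec: ItcGeneratorSpec):
    """Synthetic enthalpogram + ground truth. Deterministic for fixed seed."""
    rng = np.random.default_rng(spec.seed)
    c = np.linspace(spec.c_min, spec.c_max_factor * spec.centres[-1], spec.n_points)
    model = spec.model()
    clean = (eval_sigmoid(model, c) if isinstance(model, SigmoidModel)
             else eval_double_sigmoid(model, c))
    noise = rng.normal(0.0, spec.noise_sigma, c.size) if spec.noise_sigma > 0 else 0.0
    sigma = np.full(c.size, spec.noise_sigma) if spec.noise_sigma > 0 else None
    curve = EnthalpogramCurve(spec.temperature, c, clean + noise, sigma)
    truth = {"model": model, "spec": spec, "clean": clean}
    return curve, truth


@dataclass
class SasGeneratorSpec:
    """Forward-model parameters for a synthetic sphere scattering curve."""

    radius: float = 2.2              # nm
    polydispersity: float = 0.0      # lognormal σ of the radius distribution
    background: float = 0.0          # flat, relative to I(0) = 1
    noise_rel: float = 0.0           # relative Gaussian noise level
    upturn_amplitude: float = 0.0    # low-Q power-law A·Q^(−p), same scale
    upturn_exponent: float = 2.5
    q_min: float = 0.063             # nm⁻¹ (instrument window 0.0063–0.58 Å⁻¹)
    q_max: float = 5.8
    n_points: int = 120
    seed: int = 0

    def __post_init__(self):
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if self.q_min <= 0 or self.q_max <= self.q_min:
            raise ValueError("Q grid must be positive increasing")


def _polydisperse_sphere(q, radius, pd_sigma, n_quad=41):
    """Number-averaged sphere intensity over a lognormal radius distribution.

    Gauss–Hermite quadrature in log-radius; particle intensity weighted by
    volume² (V ∝ R³ contrast weighting of dilute small-angle scattering).
    """
    if pd_sigma <= 0:
        return sphere_form_factor(q, radius)
    nodes, weights = np.polynomial.hermite_e.hermegauss(n_quad)
    i_sum = np.zeros_like(np.asarray(q, dtype=float))
    w_sum = 0.0
    mu = np.log(radius)
    for t, w in zip(nodes, weights):
        r = np.exp(mu + pd_sigma * t)
        v2 = r**6
        i_sum += w * v2 * sphere_form_factor(q, r)
        w_sum += w * v2
    return i_sum / w_sum


def gen_scattering_curve(spec: SasGeneratorSpec):
    """Synthetic sphere SAXS/SANS curve + ground truth, Q in nm⁻¹."""
    rng = np.random.default_rng(spec.seed)
    q = np.geomspace(spec.q_min, spec.q_max, spec.n_points)
    clean = _polydisperse_sphere(q, spec.radius, spec.polydispersity)
    clean = clean + spec.background
    if spec.upturn_amplitude > 0:
        clean = clean + spec.upturn_amplitude * q ** (-spec.upturn_exponent)
    if spec.noise_rel > 0:
        sigma = spec.noise_rel * np.abs(clean)
        data = clean + rng.normal(0.0, 1.0, q.size) * sigma
    else:
        # tiny floor keeps σ strictly positive for weighting
        sigma = np.full(q.size, 1e-12)
        data = clean.copy()
    curve = ScatteringCurve(q, data, sigma, "nm^-1",
                            {"synthetic": True, "radius_nm": spec.radius})
    truth = {"spec": spec, "clean": clean, "rg_nm": np.sqrt(3.0 / 5.0) * spec.radius,
             "d_max_nm": 2.0 * spec.radius}
    return curve, truth
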