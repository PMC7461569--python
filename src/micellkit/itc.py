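"""Enthalpogram analysis and micellisation thermodynamics.

An ITC dilution experiment on a micellar surfactant solution yields the
observed dilution enthalpy ΔH_d as a function of the cumulative surfactant
concentration C_s (the *enthalpogram*).  Away from any transition the curve
follows linear pre- and post-micellar baselines; the micellisation step
between them is described by a generalized-logistic ("modified Boltzmann")
sigmoid

    ΔH_d(C_s) = ΔH_d_f(C_s) + [ΔH_d_i(C_s) − ΔH_d_f(C_s)]
                · (1 + exp((C_s − C_cmc)/ΔC_s))^(−n)

with linear baselines ΔH_d_i = H_ia + H_ib·C_s and ΔH_d_f = H_fa + H_fb·C_s.
The critical micelle concentration is located as the zero of the second
derivative d²ΔH_d/dC_s² nearest the fitted centre, and the enthalpy of
micellisation as the baseline gap ΔH_mic = ΔH_d_f(c.m.c) − ΔH_d_i(c.m.c).

Bell-shaped enthalpograms, seen in the temperature window where micelles
reorganize, are modelled as two conjoined sigmoid steps over a shared
piecewise-linear baseline: the first inflection is the c.m.c, the second
(C_trans) marks the onset of the micelle shape transformation.

Micellisation free energy uses the charged-surfactant closed form
ΔG_mic = (0.5 + β)·R·T·ln X_cmc with counterion-binding degree β and
mole fraction X_cmc, and the entropy follows from the Gibbs–Helmholtz
identity TΔS = ΔH − ΔG.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from lmfit import Parameters, minimize
from scipy.optimize import brentq
from scipy.signal import savgol_filter

from .constants import GAS_CONSTANT, WATER_MOLARITY_298K

__all__ = [
    "EnthalpogramCurve",
    "SigmoidModel",
    "DoubleSigmoidModel",
    "ThermoResult",
    "InvalidModelError",
    "FitConvergenceError",
    "RootNotFoundError",
    "eval_sigmoid",
    "eval_double_sigmoid",
    "fit_enthalpogram",
    "cmc_from_second_derivative",
    "inflections_from_second_derivative",
    "enthalpy_of_micellisation",
    "inflection_stderr",
    "mole_fraction",
    "gibbs_of_micellisation",
    "entropy_from_gibbs_helmholtz",
    "beta_from_gibbs",
    "micellisation_thermodynamics",
]

MIN_POINTS_SINGLE = 8
MIN_POINTS_DOUBLE = 14


class InvalidModelError(ValueError):
    """Model parameters violate their invariants (ΔC_s ≤ 0, n ≤ 0, …)."""


class FitConvergenceError(RuntimeError):
    """Least-squares fit failed to converge to an admissible model."""

    def __init__(self, message: str, residual_norm: float | None = None):
        super().__init__(message)
        self.residual_norm = residual_norm


class RootNotFoundError(RuntimeError):
    """No sign change of the second derivative in the search window."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class EnthalpogramCurve:
    """One temperature's reduced titration data.

    Parameters
    ----------
    temperature : float
        Kelvin.
    concentration : array
        Surfactant concentration C_s, mol dm⁻³, strictly increasing, > 0.
    enthalpy : array
        Observed dilution enthalpy ΔH_d, kJ mol⁻¹.
    sigma : array, optional
        Per-point uncertainty of ΔH_d, kJ mol⁻¹.
    """

    temperature: float
    concentration: np.ndarray
    enthalpy: np.ndarray
    sigma: np.ndarray | None = None

    def __post_init__(self):
        self.concentration = np.asarray(self.concentration, dtype=float)
        self.enthalpy = np.asarray(self.enthalpy, dtype=float)
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
        if self.concentration.ndim != 1 or self.concentration.shape != self.enthalpy.shape:
            raise ValueError("concentration and enthalpy must be matching 1-D arrays")
        if np.any(self.concentration <= 0):
            raise ValueError("concentrations must be positive")
        if np.any(np.diff(self.concentration) <= 0):
            raise ValueError("concentrations must be strictly increasing")

    def __len__(self) -> int:
        return self.concentration.size


@dataclass
class SigmoidModel:
    """Generalized-logistic enthalpogram model with linear baselines.

    ``h_ia + h_ib·C`` is the initial (pre-micellar) baseline,
    ``h_fa + h_fb·C`` the final (post-micellar) one; ``cmc`` the step centre,
    ``width`` the concentration interval ΔC_s, ``n`` the asymmetry exponent.
    """

    h_ia: float
    h_ib: float
    h_fa: float
    h_fb: float
    cmc: float
    width: float
    n: float = 1.0
    stderr: dict[str, float | None] = field(default_factory=dict, repr=False)
    fit_report: dict = field(default_factory=dict, repr=False)

    def validate(self) -> None:
        if not (self.width > 0):
            raise InvalidModelError(f"transition width must be positive, got {self.width}")
        if not (self.n > 0):
            raise InvalidModelError(f"exponent n must be positive, got {self.n}")

    def initial_baseline(self, c):
        return self.h_ia + self.h_ib * np.asarray(c, dtype=float)

    def final_baseline(self, c):
        return self.h_fa + self.h_fb * np.asarray(c, dtype=float)

    def __call__(self, c):
        return eval_sigmoid(self, c)


@dataclass
class DoubleSigmoidModel:
    """Two conjoined sigmoid steps over a shared piecewise-linear baseline.

    Lines 1/2/3 are the pre-transition, inter-transition and post-transition
    baselines; the model interpolates 1→2 through the first step (centre
    ``cmc``) and 2→3 through the second (centre ``c_trans``).
    """

    lines: tuple[tuple[float, float], tuple[float, float], tuple[float, float]]
    cmc: float
    c_trans: float
    width1: float
    width2: float
    n1: float = 1.0
    n2: float = 1.0
    stderr: dict[str, float | None] = field(default_factory=dict, repr=False)
    fit_report: dict = field(default_factory=dict, repr=False)

    def validate(self) -> None:
        if not (self.width1 > 0 and self.width2 > 0):
            raise InvalidModelError("both widths must be positive")
        if not (self.n1 > 0 and self.n2 > 0):
            raise InvalidModelError("both exponents must be positive")
        if not self.cmc < self.c_trans:
            raise InvalidModelError("step centres must satisfy cmc < c_trans")

    def line(self, k, c):
        a, b = self.lines[k]
        return a + b * np.asarray(c, dtype=float)

    def __call__(self, c):
        return eval_double_sigmoid(self, c)


@dataclass
class ThermoResult:
    """Micellisation (or transformation) thermodynamics at one temperature."""

    T: float
    beta: float
    C: float
    X: float
    dG: float
    dH: float
    TdS: float
    dS: float


# ---------------------------------------------------------------------------
# sigmoid evaluation
# ---------------------------------------------------------------------------

def _softplus(u):
    """log(1 + exp(u)) without overflow."""
    u = np.asarray(u, dtype=float)
    return np.where(u > 0, u, 0.0) + np.log1p(np.exp(-np.abs(u)))


def _logistic_decay(u, n):
    """(1 + exp(u))^(−n), stable for large |u|; 1 at u→−∞, 0 at u→+∞."""
    return np.exp(-n * _softplus(u))


def eval_sigmoid(model: SigmoidModel, c):
    """Evaluate the single-step enthalpogram model at concentration(s) c."""
    model.validate()
    c = np.asarray(c, dtype=float)
    u = (c - model.cmc) / model.width
    g = _logistic_decay(u, model.n)
    out = model.final_baseline(c) + (model.initial_baseline(c) - model.final_baseline(c)) * g
    return out if out.ndim else float(out)


def eval_double_sigmoid(model: DoubleSigmoidModel, c):
    """Evaluate the two-step enthalpogram model at concentration(s) c."""
    model.validate()
    c = np.asarray(c, dtype=float)
    s1 = 1.0 - _logistic_decay((c - model.cmc) / model.width1, model.n1)
    s2 = 1.0 - _logistic_decay((c - model.c_trans) / model.width2, model.n2)
    out = (model.line(0, c)
           + (model.line(1, c) - model.line(0, c)) * s1
           + (model.line(2, c) - model.line(1, c)) * s2)
    return out if out.ndim else float(out)


def _sigmoid_second_derivative(model: SigmoidModel, c):
    """Analytic d²ΔH_d/dC_s² of the single-step model."""
    c = np.asarray(c, dtype=float)
    w, n = model.width, model.n
    u = (c - model.cmc) / w
    g = _logistic_decay(u, n)
    sig = 1.0 / (1.0 + np.exp(-u))          # logistic σ(u)
    gp = -n * sig * g / w                    # dg/dC
    gpp = (n * sig * g / w**2) * (n * sig - (1.0 - sig))
    d_slope = model.h_ib - model.h_fb
    d_val = model.initial_baseline(c) - model.final_baseline(c)
    return 2.0 * d_slope * gp + d_val * gpp


def _double_second_derivative(model: DoubleSigmoidModel, c, h=None):
    """Finite-difference second derivative of the two-step model."""
    c = np.asarray(c, dtype=float)
    if h is None:
        h = 1e-4 * min(model.width1, model.width2)
    f = lambda x: eval_double_sigmoid(model, x)
    return (f(c + h) - 2.0 * f(c) + f(c - h)) / h**2


# ---------------------------------------------------------------------------
# inflection location (c.m.c and C_trans)
# ---------------------------------------------------------------------------

def _root_nearest(fun, centre, half_window, n_scan=2001):
    grid = np.linspace(centre - half_window, centre + half_window, n_scan)
    vals = fun(grid)
    sign = np.sign(vals)
    idx = np.nonzero(np.diff(sign) != 0)[0]
    roots = []
    for i in idx:
        try:
            roots.append(brentq(lambda x: float(fun(x)), grid[i], grid[i + 1],
                                xtol=1e-14, rtol=8.9e-16))
        except ValueError:
            continue
    if not roots:
        raise RootNotFoundError(
            f"no sign change of the second derivative within ±{half_window:g} of {centre:g}")
    roots = np.asarray(roots)
    return float(roots[np.argmin(np.abs(roots - centre))])


def cmc_from_second_derivative(model: SigmoidModel, half_window: float | None = None):
    """Critical micelle concentration as the inflection of the fitted model.

    Returns the zero of d²ΔH_d/dC_s² nearest the fitted centre.  For the
    symmetric case (n = 1, flat baselines) this is exactly the fitted centre;
    asymmetric exponents and sloped baselines shift it.
    """
    model.validate()
    if half_window is None:
        half_window = 8.0 * model.width
    return _root_nearest(lambda c: _sigmoid_second_derivative(model, c),
                         model.cmc, half_window)


def inflections_from_second_derivative(model: DoubleSigmoidModel):
    """(c.m.c, C_trans): per-step inflection roots of the two-step model.

    Each root is searched in a bracket around its own step centre, capped at
    the midpoint between the two centres so the steps cannot swap.
    """
    model.validate()
    mid = 0.5 * (model.cmc + model.c_trans)
    f = lambda c: _double_second_derivative(model, c)
    w1 = min(8.0 * model.width1, mid - model.cmc)
    w2 = min(8.0 * model.width2, model.c_trans - mid)
    c1 = _root_nearest(f, model.cmc, w1)
    c2 = _root_nearest(f, model.c_trans, w2)
    return c1, c2


def enthalpy_of_micellisation(model, at=None):
    """Baseline-gap enthalpy at the inflection concentration(s).

    For a :class:`SigmoidModel` returns ΔH_mic = ΔH_d_f(c*) − ΔH_d_i(c*)
    with c* the second-derivative root (or the concentration(s) passed via
    ``at``).  For a :class:`DoubleSigmoidModel` returns the pair
    (ΔH_mic, ΔH_m.trans), each from the baseline pair adjacent to its own
    step; ``at`` is then a pair of concentrations.
    """
    if isinstance(model, DoubleSigmoidModel):
        c1, c2 = inflections_from_second_derivative(model) if at is None else at
        return (float(model.line(1, c1) - model.line(0, c1)),
                float(model.line(2, c2) - model.line(1, c2)))
    c = cmc_from_second_derivative(model) if at is None else at
    return float(model.final_baseline(c) - model.initial_baseline(c))


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _smoothed_derivative(c, h):
    """Savitzky–Golay smoothed dH/dC on the data grid."""
    win = min(len(h) if len(h) % 2 == 1 else len(h) - 1, 11)
    win = max(win, 5)
    smooth = savgol_filter(h, window_length=win, polyorder=2)
    return np.gradient(smooth, c)


def _step_guess(c, dh_dc, lo, hi):
    """Centre and width guess from the derivative-magnitude peak in [lo, hi)."""
    seg = slice(lo, hi)
    mag = np.abs(dh_dc[seg])
    k = int(np.argmax(mag)) + lo
    centre = c[k]
    # width from the half-maximum spread of the derivative peak
    half = mag.max() / 2.0
    above = np.nonzero(mag >= half)[0] + lo
    if above.size >= 2:
        width = max((c[above[-1]] - c[above[0]]) / 4.0, np.diff(c).min())
    else:
        width = (c[-1] - c[0]) / 20.0
    return centre, width


def _line_fit(c, h):
    if len(c) < 2:
        return float(np.mean(h)) if len(c) else 0.0, 0.0
    b, a = np.polyfit(c, h, 1)
    return float(a), float(b)


def fit_enthalpogram(curve: EnthalpogramCurve, n_steps: int = 1):
    """Least-squares fit of a single- or double-sigmoid enthalpogram model.

    Parameters
    ----------
    curve : EnthalpogramCurve
    n_steps : {1, 2}
        1 fits :class:`SigmoidModel`; 2 fits :class:`DoubleSigmoidModel`
        (for bell-shaped curves with two separable inflections).

    Returns the fitted model with per-parameter standard errors in
    ``model.stderr`` and residual diagnostics in ``model.fit_report``.
    Raises :class:`FitConvergenceError` if the optimiser fails or a fitted
    centre falls outside the data range.
    """
    if n_steps not in (1, 2):
        raise ValueError("n_steps must be 1 or 2")
    c, h = curve.concentration, curve.enthalpy
    need = MIN_POINTS_SINGLE if n_steps == 1 else MIN_POINTS_DOUBLE
    if len(curve) < need:
        raise ValueError(f"need at least {need} points for a {n_steps}-step fit, got {len(curve)}")
    weights = None if curve.sigma is None else 1.0 / curve.sigma
    dh_dc = _smoothed_derivative(c, h)
    span = c[-1] - c[0]
    wmin = np.diff(c).min() * 1e-3

    if n_steps == 1:
        centre, width = _step_guess(c, dh_dc, 0, len(c))
        nq = max(len(c) // 4, 2)
        ia, ib = _line_fit(c[:nq], h[:nq])
        fa, fb = _line_fit(c[-nq:], h[-nq:])
        params = Parameters()
        params.add("h_ia", value=ia)
        params.add("h_ib", value=ib)
        params.add("h_fa", value=fa)
        params.add("h_fb", value=fb)
        params.add("cmc", value=centre, min=c[0], max=c[-1])
        params.add("width", value=width, min=wmin, max=span)
        params.add("n", value=1.0, min=0.05, max=20.0)

        def resid(p):
            m = SigmoidModel(p["h_ia"].value, p["h_ib"].value, p["h_fa"].value,
                             p["h_fb"].value, p["cmc"].value, p["width"].value,
                             p["n"].value)
            r = eval_sigmoid(m, c) - h
            return r if weights is None else r * weights

        out = minimize(resid, params, method="leastsq")
        _check_fit(out, c)
        p = out.params
        model = SigmoidModel(*(p[k].value for k in
                               ("h_ia", "h_ib", "h_fa", "h_fb", "cmc", "width", "n")))
        model.stderr = {k: p[k].stderr for k in p}
        model.fit_report = _report(out)
        return model

    # two-step fit
    mid_guess = len(c) // 2
    c1, w1 = _step_guess(c, dh_dc, 0, mid_guess)
    c2, w2 = _step_guess(c, dh_dc, mid_guess, len(c))
    if c2 <= c1:  # fall back to an even split of the range
        c1, c2 = c[0] + 0.3 * span, c[0] + 0.7 * span
    n5 = max(len(c) // 5, 2)
    a1, b1 = _line_fit(c[:n5], h[:n5])
    a3, b3 = _line_fit(c[-n5:], h[-n5:])
    mid_mask = (c > c1 + 2 * w1) & (c < c2 - 2 * w2)
    if mid_mask.sum() >= 2:
        a2, b2 = _line_fit(c[mid_mask], h[mid_mask])
    else:
        a2, b2 = float(np.interp(0.5 * (c1 + c2), c, h)), 0.0

    params = Parameters()
    for name, val in (("a1", a1), ("b1", b1), ("a2", a2), ("b2", b2),
                      ("a3", a3), ("b3", b3)):
        params.add(name, value=val)
    params.add("cmc", value=c1, min=c[0], max=c[-1])
    params.add("dc", value=max(c2 - c1, 4 * wmin), min=2 * wmin, max=span)
    params.add("c_trans", expr="cmc + dc")
    params.add("width1", value=w1, min=wmin, max=span)
    params.add("width2", value=w2, min=wmin, max=span)
    params.add("n1", value=1.0, min=0.2, max=5.0)
    params.add("n2", value=1.0, min=0.2, max=5.0)

    def resid2(p):
        m = _double_from_params(p)
        r = eval_double_sigmoid(m, c) - h
        return r if weights is None else r * weights

    # two-stage fit: pin the exponents at the symmetric value first so the
    # centres/widths land well, then release everything
    params["n1"].vary = params["n2"].vary = False
    stage1 = minimize(resid2, params, method="leastsq")
    params = stage1.params
    params["n1"].vary = params["n2"].vary = True
    out = minimize(resid2, params, method="leastsq")
    _check_fit(out, c, two=True)
    model = _double_from_params(out.params)
    model.stderr = {k: out.params[k].stderr for k in out.params}
    model.fit_report = _report(out)
    return model


def _double_from_params(p):
    return DoubleSigmoidModel(
        lines=((p["a1"].value, p["b1"].value),
               (p["a2"].value, p["b2"].value),
               (p["a3"].value, p["b3"].value)),
        cmc=p["cmc"].value, c_trans=p["c_trans"].value,
        width1=p["width1"].value, width2=p["width2"].value,
        n1=p["n1"].value, n2=p["n2"].value)


def _check_fit(out, c, two=False):
    norm = float(np.sqrt(np.sum(np.asarray(out.residual) ** 2)))
    if not out.success:
        raise FitConvergenceError(f"fit did not converge: {out.message}", norm)
    centres = [out.params["cmc"].value]
    if two:
        centres.append(out.params["c_trans"].value)
    for x in centres:
        if not (c[0] <= x <= c[-1]):
            raise FitConvergenceError(
                f"fitted centre {x:g} outside data range [{c[0]:g}, {c[-1]:g}]", norm)


def _report(out):
    return {
        "nfev": out.nfev,
        "ndata": out.ndata,
        "chisqr": float(out.chisqr),
        "redchi": float(out.redchi),
        "residual_norm": float(np.sqrt(np.sum(np.asarray(out.residual) ** 2))),
        "success": bool(out.success),
        "var_names": list(out.var_names),
        "covar": None if out.covar is None else np.asarray(out.covar),
    }


def inflection_stderr(model, which: int = 0) -> float | None:
    """Delta-method standard error of a reported inflection concentration.

    Propagates the fit covariance through the second-derivative root: the
    root is re-located under small perturbations of each fitted parameter
    and the gradient is contracted with the covariance matrix.  ``which``
    selects the step (0 = c.m.c, 1 = C_trans) for two-step models.
    Returns None when no covariance is available.
    """
    covar = model.fit_report.get("covar")
    if covar is None:
        return None
    names = model.fit_report["var_names"]

    def root_of(m):
        if isinstance(m, DoubleSigmoidModel):
            return inflections_from_second_derivative(m)[which]
        return cmc_from_second_derivative(m)

    def with_param(name, value):
        m = _model_copy(model)
        _set_param(m, name, value)
        return m

    base = root_of(model)
    grad = np.zeros(len(names))
    for k, name in enumerate(names):
        sd = np.sqrt(max(covar[k, k], 0.0))
        if sd == 0:
            continue
        h = 0.1 * sd
        x0 = _get_param(model, name)
        try:
            grad[k] = (root_of(with_param(name, x0 + h)) - base) / h
        except (RootNotFoundError, InvalidModelError):
            grad[k] = 0.0
    var = float(grad @ covar @ grad)
    return float(np.sqrt(var)) if var > 0 else None


def _model_copy(model):
    import copy
    return copy.deepcopy(model)


_LINE_PARAMS = {"a1": (0, 0), "b1": (0, 1), "a2": (1, 0), "b2": (1, 1),
                "a3": (2, 0), "b3": (2, 1)}


def _set_param(model, name, value):
    if isinstance(model, DoubleSigmoidModel) and name in _LINE_PARAMS:
        i, j = _LINE_PARAMS[name]
        lines = [list(l) for l in model.lines]
        lines[i][j] = value
        model.lines = tuple(tuple(l) for l in lines)
    elif name == "dc":
        model.c_trans = model.cmc + value
    elif name == "cmc" and isinstance(model, DoubleSigmoidModel):
        dc = model.c_trans - model.cmc
        model.cmc = value
        model.c_trans = value + dc
    else:
        setattr(model, name, value)


def _get_param(model, name):
    if isinstance(model, DoubleSigmoidModel) and name in _LINE_PARAMS:
        i, j = _LINE_PARAMS[name]
        return model.lines[i][j]
    if name == "dc":
        return model.c_trans - model.cmc
    return getattr(model, name)


# ---------------------------------------------------------------------------
# thermodynamics
# ---------------------------------------------------------------------------

def mole_fraction(c, water_molarity: float = WATER_MOLARITY_298K):
    """Mole fraction of surfactant at molarity c in water."""
    c = np.asarray(c, dtype=float)
    x = c / (c + water_molarity)
    return x if x.ndim else float(x)


def gibbs_of_micellisation(c, beta, T, water_molarity: float = WATER_MOLARITY_298K,
                           mole_fraction_override=None):
    """ΔG_mic = (0.5 + β)·R·T·ln X, kJ mol⁻¹.

    ``c`` is the c.m.c (or C_trans for the transformation step) in mol dm⁻³;
    ``beta`` the counterion-binding degree in [0, 1].  The mole fraction uses
    the configurable water molarity (default: pure water at 298.15 K).
    """
    if not (0.0 <= beta <= 1.0):
        raise ValueError(f"beta must lie in [0, 1], got {beta}")
    if T <= 0:
        raise ValueError("temperature must be positive")
    if mole_fraction_override is not None:
        x = mole_fraction_override
    else:
        if np.any(np.asarray(c) <= 0):
            raise ValueError("concentration must be positive")
        x = mole_fraction(c, water_molarity)
    if np.any(np.asarray(x) > 1) or np.any(np.asarray(x) <= 0):
        raise ValueError("mole fraction must lie in (0, 1]")
    return (0.5 + beta) * GAS_CONSTANT * T * np.log(x) / 1000.0


def entropy_from_gibbs_helmholtz(dH, dG, T):
    """Gibbs–Helmholtz entropy: returns (TΔS in kJ mol⁻¹, ΔS in J mol⁻¹ K⁻¹)."""
    if T <= 0:
        raise ValueError("temperature must be positive")
    TdS = dH - dG
    return TdS, 1000.0 * TdS / T


def beta_from_gibbs(dG, c, T, water_molarity: float = WATER_MOLARITY_298K):
    """Invert the ΔG_mic expression for the counterion-binding degree β."""
    f = lambda b: gibbs_of_micellisation(c, b, T, water_molarity) - dG
    lo, hi = f(0.0), f(1.0)
    if lo * hi > 0:
        raise ValueError("no beta in [0, 1] reproduces this Gibbs energy")
    return brentq(f, 0.0, 1.0, xtol=1e-12)


def micellisation_thermodynamics(c, beta, T, dH,
                                 water_molarity: float = WATER_MOLARITY_298K) -> ThermoResult:
    """Assemble the full thermodynamic record for one step at one temperature."""
    dG = gibbs_of_micellisation(c, beta, T, water_molarity)
    TdS, dS = entropy_from_gibbs_helmholtz(dH, dG, T)
    return ThermoResult(T=T, beta=beta, C=c, X=mole_fraction(c, water_molarity),
                        dG=dG, dH=dH, TdS=TdS, dS=dS)
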