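"""Small-angle scattering shape analysis.

Implements the model-free toolbox used to size and classify micelles from
SAXS/SANS curves:

* Guinier analysis — weighted regression of ln I on Q² over a low-Q window
  iterated to self-consistency against a (Q·R_g)max cap, giving I(0), the
  radius of gyration R_g and the shape indicator (Q·R_g)max.
* Kratky transform — Q²I(Q) versus Q; a bell-shaped interior maximum flags a
  compact (globular) particle, a plateau or rise flags a flexible one.
* Pair distance distribution function — a GNOM-style regularized indirect
  Fourier transform of I(Q) to p(r) on [0, D_max] with p(0) = p(D_max) = 0,
  second-derivative smoothness weighted by α (L-curve chosen by default) and
  optional non-negativity.
* Sphere relations — R_g² = (3/5)R² and the analytic sphere form factor /
  PDDF used as oracles and by the synthetic generator.

Q is handled in nm⁻¹ internally; Å⁻¹ input is converted on declaration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import nnls

__all__ = [
    "ScatteringCurve",
    "GuinierFit",
    "PDDF",
    "sphere_form_factor",
    "sphere_pddf",
    "debye_intensity",
    "guinier_fit",
    "shape_indicator",
    "kratky_transform",
    "kratky_is_bell",
    "pddf_ift",
    "pddf_forward",
    "pddf_support",
    "rg_from_radius",
    "radius_from_rg",
    "estimate_dmax",
]


@dataclass
class ScatteringCurve:
    """One reduced small-angle scattering curve (Q, I, σ_I)."""

    q: np.ndarray
    intensity: np.ndarray
    sigma: np.ndarray | None = None
    units: str = "nm^-1"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.q = np.asarray(self.q, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
            if np.any(self.sigma <= 0):
                raise ValueError("sigma must be positive where given")
        if np.any(self.q <= 0) or np.any(np.diff(self.q) <= 0):
            raise ValueError("Q must be positive and strictly increasing")
        if self.units not in ("nm^-1", "A^-1"):
            raise ValueError(f"unknown Q unit {self.units!r}")

    def in_nm(self) -> "ScatteringCurve":
        """Return the curve with Q in nm⁻¹ (10 nm⁻¹ per Å⁻¹)."""
        if self.units == "nm^-1":
            return self
        return ScatteringCurve(self.q * 10.0, self.intensity, self.sigma,
                               "nm^-1", dict(self.metadata))


@dataclass
class GuinierFit:
    i0: float
    rg: float           # nm
    qrg_max: float
    window: tuple[int, int]      # [start, stop) indices into the curve
    n_points: int
    slope_stderr: float | None = None
    rg_stderr: float | None = None
    residual_norm: float = 0.0


@dataclass
class PDDF:
    r: np.ndarray        # nm
    p: np.ndarray
    d_max: float
    alpha: float
    residual_norm: float = 0.0
    warnings: list = field(default_factory=list)

    @property
    def rg(self) -> float:
        """R_g from the second moment of p(r): R_g² = ∫r²p dr / (2∫p dr)."""
        total = np.trapezoid(self.p, self.r)
        if total <= 0:
            return 0.0
        return float(np.sqrt(np.trapezoid(self.r**2 * self.p, self.r) / (2.0 * total)))

    @property
    def peak_r(self) -> float:
        return float(self.r[np.argmax(self.p)])


# ---------------------------------------------------------------------------
# analytic sphere / chain oracles
# ---------------------------------------------------------------------------

def sphere_form_factor(q, radius):
    """Normalized sphere form factor P(Q) = [3(sin x − x cos x)/x³]², x = QR."""
    x = np.asarray(q, dtype=float) * radius
    with np.errstate(invalid="ignore", divide="ignore"):
        amp = 3.0 * (np.sin(x) - x * np.cos(x)) / x**3
    return np.where(x < 1e-6, 1.0 - x**2 / 10.0, amp) ** 2


def sphere_pddf(r, radius):
    """Analytic p(r) of a homogeneous sphere, r ∈ [0, 2R] (arbitrary scale).

    p(r) ∝ r²·(1 − 3r/4R + r³/16R³), vanishing at r = 0 and r = 2R.
    """
    r = np.asarray(r, dtype=float)
    x = r / radius
    p = r**2 * (1.0 - 0.75 * x + x**3 / 16.0)
    return np.where((r >= 0) & (r <= 2.0 * radius), p, 0.0)


def debye_intensity(q, rg):
    """Debye function for a Gaussian chain: 2(e^{−x} − 1 + x)/x², x = (QR_g)²."""
    x = (np.asarray(q, dtype=float) * rg) ** 2
    with np.errstate(invalid="ignore", divide="ignore"):
        d = 2.0 * (np.expm1(-x) + x) / x**2
    return np.where(x < 1e-8, 1.0 - x / 3.0, d)


def rg_from_radius(radius):
    """Radius of gyration of a homogeneous sphere: R_g = √(3/5)·R."""
    if np.any(np.asarray(radius) <= 0):
        raise ValueError("radius must be positive")
    return np.sqrt(3.0 / 5.0) * radius


def radius_from_rg(rg):
    """Inverse sphere relation: R = √(5/3)·R_g."""
    if np.any(np.asarray(rg) <= 0):
        raise ValueError("radius of gyration must be positive")
    return np.sqrt(5.0 / 3.0) * rg


# ---------------------------------------------------------------------------
# Guinier analysis
# ---------------------------------------------------------------------------

def _weighted_linefit(x, y, w):
    """Weighted least squares y = a + b x; returns a, b, var(b)."""
    W = np.sum(w)
    xm = np.sum(w * x) / W
    ym = np.sum(w * y) / W
    sxx = np.sum(w * (x - xm) ** 2)
    b = np.sum(w * (x - xm) * (y - ym)) / sxx
    a = ym - b * xm
    resid = y - a - b * x
    n = len(x)
    var_b = (np.sum(w * resid**2) / max(n - 2, 1)) / sxx * n / W
    return a, b, var_b, float(np.sqrt(np.sum(resid**2)))


def guinier_fit(curve: ScatteringCurve, qrg_cap: float = 1.3,
                min_points: int = 5, skip_low_q: int = 0,
                max_iter: int = 50) -> GuinierFit:
    """Self-consistent Guinier fit on the largest admissible low-Q window.

    Regresses ln I on Q² (weighted by σ when available) starting from the
    full curve, then trims the window so that Q·R_g ≤ ``qrg_cap`` and
    re-fits until the window is stable.  ``skip_low_q`` drops the lowest-Q
    points (aggregation-upturn exclusion).
    """
    cv = curve.in_nm()
    q, I = cv.q[skip_low_q:], cv.intensity[skip_low_q:]
    sig = None if cv.sigma is None else cv.sigma[skip_low_q:]
    if np.any(I <= 0):
        raise ValueError("non-positive intensities in the Guinier window")
    if len(q) < min_points:
        raise ValueError(f"need at least {min_points} points")

    x, y = q**2, np.log(I)
    w = np.ones_like(x) if sig is None else (I / sig) ** 2
    hi = len(q)
    seen = set()
    for _ in range(max_iter):
        a, b, var_b, rnorm = _weighted_linefit(x[:hi], y[:hi], w[:hi])
        rg = float(np.sqrt(-3.0 * b)) if b < 0 else 0.0
        if rg == 0.0:
            hi_new = len(q)  # flat or rising curve: keep everything
        else:
            hi_new = int(np.searchsorted(q, qrg_cap / rg, side="right"))
            hi_new = max(hi_new, min_points)
        if hi_new == hi:
            break
        if hi_new in seen:  # limit cycle on noisy data: settle on the smaller window
            hi = min(hi, hi_new)
            a, b, var_b, rnorm = _weighted_linefit(x[:hi], y[:hi], w[:hi])
            rg = float(np.sqrt(-3.0 * b)) if b < 0 else 0.0
            break
        seen.add(hi)
        hi = hi_new
    else:
        raise RuntimeError("Guinier window iteration did not converge")
    rg_err = None
    if rg > 0 and var_b > 0:
        rg_err = float(1.5 * np.sqrt(var_b) / rg)
    return GuinierFit(i0=float(np.exp(a)), rg=rg, qrg_max=float(q[hi - 1] * rg),
                      window=(skip_low_q, skip_low_q + hi), n_points=hi,
                      slope_stderr=float(np.sqrt(var_b)), rg_stderr=rg_err,
                      residual_norm=rnorm)


def shape_indicator(qrg_max: float) -> str:
    """Classify particle shape from (Q·R_g)max.

    0.9 < x < 1.3 → 'globular'; x < 0.8 → 'elongated'; the published rule
    leaves [0.8, 0.9] and ≥ 1.3 unclassified → 'indeterminate'.
    """
    if qrg_max <= 0:
        raise ValueError("(QRg)max must be positive")
    if 0.9 < qrg_max < 1.3:
        return "globular"
    if qrg_max < 0.8:
        return "elongated"
    return "indeterminate"


# ---------------------------------------------------------------------------
# Kratky analysis
# ---------------------------------------------------------------------------

def kratky_transform(curve: ScatteringCurve) -> ScatteringCurve:
    """(Q, Q²·I(Q)) with exact first-order uncertainty σ_out = Q²·σ_I."""
    cv = curve.in_nm()
    sig = None if cv.sigma is None else cv.q**2 * cv.sigma
    return ScatteringCurve(cv.q, cv.q**2 * cv.intensity, sig, "nm^-1",
                           {**cv.metadata, "transform": "kratky"})


def kratky_is_bell(curve: ScatteringCurve, edge_frac: float = 0.05,
                   drop_frac: float = 0.7) -> bool:
    """Compactness flag: single interior maximum of Q²I(Q).

    True when the Kratky maximum sits strictly inside the Q range (not in
    the outer ``edge_frac`` tails) and the transform falls back below
    ``drop_frac`` of the peak at high Q — the bell shape of a compact
    particle.  A Gaussian-chain plateau (monotonic rise to a flat tail)
    fails both conditions.
    """
    kr = kratky_transform(curve)
    y = kr.intensity
    k = int(np.argmax(y))
    edge = max(int(edge_frac * len(y)), 1)
    interior = edge <= k < len(y) - edge
    return bool(interior and y[-1] < drop_frac * y[k])


# ---------------------------------------------------------------------------
# indirect Fourier transform to p(r)
# ---------------------------------------------------------------------------

def _ift_system(q, d_max, n_r):
    """Design matrix A with I(Q_i) = Σ_j A_ij p_j (trapezoid quadrature)."""
    r = np.linspace(0.0, d_max, n_r)
    dr = r[1] - r[0]
    qr = np.outer(q, r)
    with np.errstate(invalid="ignore", divide="ignore"):
        kern = np.sin(qr) / qr
    kern[:, 0] = 1.0
    wq = np.full(n_r, dr)
    wq[[0, -1]] = 0.5 * dr
    return r, 4.0 * np.pi * kern * wq


def _second_difference(n):
    """Second-difference operator including the pinned boundary nodes."""
    d = np.zeros((n - 2, n))
    for i in range(n - 2):
        d[i, i:i + 3] = (1.0, -2.0, 1.0)
    return d


def _solve_ift(Aw, yw, D, alpha, non_negative):
    top = np.vstack([Aw, np.sqrt(alpha) * D])
    rhs = np.concatenate([yw, np.zeros(D.shape[0])])
    if non_negative:
        p, _ = nnls(top, rhs)
    else:
        p = np.linalg.lstsq(top, rhs, rcond=None)[0]
    return p


def _lcurve_alpha(Aw, yw, D, alphas):
    """L-curve corner: maximum curvature of (log ρ(α), log η(α))."""
    rho, eta = [], []
    for a in alphas:
        p = _solve_ift(Aw, yw, D, a, non_negative=False)
        rho.append(np.log(np.linalg.norm(Aw @ p - yw) + 1e-300))
        eta.append(np.log(np.linalg.norm(D @ p) + 1e-300))
    rho, eta = np.asarray(rho), np.asarray(eta)
    # discrete curvature of the parametric curve
    dr, de = np.gradient(rho), np.gradient(eta)
    d2r, d2e = np.gradient(dr), np.gradient(de)
    denom = (dr**2 + de**2) ** 1.5 + 1e-300
    kappa = (dr * d2e - de * d2r) / denom
    return float(alphas[int(np.argmax(kappa))])


def pddf_ift(curve: ScatteringCurve, d_max: float, alpha: float | None = None,
             n_r: int = 101, non_negative: bool = True,
             skip_low_q: int = 0) -> PDDF:
    """Regularized indirect Fourier transform of I(Q) to p(r).

    Solves I(Q) = 4π ∫₀^{Dmax} p(r)·sin(Qr)/(Qr) dr on an ``n_r``-point grid
    with p(0) = p(D_max) = 0, smoothness penalty α·‖p″‖² (α from an L-curve
    scan when not given) and optional non-negativity.
    """
    if d_max <= 0:
        raise ValueError("D_max must be positive")
    cv = curve.in_nm()
    q = cv.q[skip_low_q:]
    y = cv.intensity[skip_low_q:]
    sig = None if cv.sigma is None else cv.sigma[skip_low_q:]
    warnings = []
    if np.pi / q[-1] > d_max / 4:
        warnings.append("data support is marginal for this D_max")

    r, A = _ift_system(q, d_max, n_r)
    # pin the boundary: solve only for interior nodes
    Ai = A[:, 1:-1]
    D = _second_difference(n_r)[:, 1:-1]
    wt = np.ones_like(y) if sig is None else 1.0 / sig
    scale = float(np.max(np.abs(y)))
    Aw = Ai * wt[:, None] / scale
    yw = y * wt / scale

    if alpha is None:
        alphas = np.logspace(-8, 4, 31) * np.linalg.norm(Aw) ** 2 / np.linalg.norm(D) ** 2
        alpha = _lcurve_alpha(Aw, yw, D, alphas)
    elif alpha == 0:
        warnings.append("alpha = 0: unregularized system may be ill-conditioned")

    p_int = _solve_ift(Aw, yw, D, alpha, non_negative)
    p = np.zeros(n_r)
    p[1:-1] = p_int * scale
    resid = float(np.linalg.norm(Ai @ (p[1:-1] / scale) - y / scale))
    return PDDF(r=r, p=p, d_max=float(d_max), alpha=float(alpha),
                residual_norm=resid, warnings=warnings)


def pddf_forward(pddf: PDDF, q) -> np.ndarray:
    """Scattered intensity implied by a p(r) (round-trip check)."""
    q = np.asarray(q, dtype=float)
    _, A = _ift_system(q, pddf.d_max, len(pddf.r))
    return A @ pddf.p


def pddf_support(pddf: PDDF, frac: float = 0.01) -> float:
    """Largest r where p(r) exceeds ``frac`` of its peak (support estimate)."""
    above = pddf.r[pddf.p > frac * pddf.p.max()]
    return float(above[-1]) if above.size else 0.0


def estimate_dmax(curve: ScatteringCurve, **guinier_kw) -> float:
    """Sphere-based D_max guess: 2·√(5/3)·R_g from a Guinier fit."""
    fit = guinier_fit(curve, **guinier_kw)
    if fit.rg <= 0:
        raise ValueError("cannot estimate D_max from a flat curve")
    return float(2.0 * radius_from_rg(fit.rg))
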