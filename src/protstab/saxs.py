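"""Small-angle X-ray scattering reduction and model scattering.

Implements the standard solution-scattering toolchain for a monodisperse
globular particle:

* **Guinier analysis** — ln I(q) vs q² on the low-angle window q·Rg ≤ 1.3
  gives the radius of gyration (slope = -Rg²/3) and the zero-angle intensity
  I(0) (intercept).
* **Kratky transform** — q²·I(q) vs q; a bell-then-decay ("hyperbolic")
  shape is the signature of a compact globular particle.
* **Indirect Fourier transform** — recovers the pair-distance distribution
  p(r) from I(q) = 4π ∫₀^Dmax p(r)·sin(qr)/(qr) dr by smoothness-regularized
  non-negative least squares with p(0) = p(Dmax) = 0; Dmax is located by a
  grid search over trial values.
* **I(0)/C molecular weight** — against reference standards measured at
  known concentration.
* **Debye model scattering** — I(q) = Σᵢⱼ wᵢwⱼ·sin(q·rᵢⱼ)/(q·rᵢⱼ) from point
  coordinates (in vacuo: no hydration shell, q-independent weights), with
  reduced-χ² comparison of a scalable model curve against data.

q follows the 4π·sin(θ)/λ convention throughout (Å⁻¹); the nominal
resolution of a measurement is 2π/q_max.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
from scipy import stats
from scipy.optimize import nnls
from scipy.spatial.distance import pdist
from sklearn.base import BaseEstimator

from .datatypes import (
    AtomicModel,
    Discrepancy,
    GuinierFit,
    PairDistribution,
    ScatteringCurve,
)
from .equilibrium import _xcol


def resolution(q_max: float) -> float:
    """Nominal real-space resolution 2π/q_max (Å)."""
    if q_max <= 0:
        raise ValueError("q_max must be positive")
    return 2.0 * np.pi / q_max


# ---------------------------------------------------------------------------
# Analytic form factors (used both as fixtures and as closed-form references)
# ---------------------------------------------------------------------------

def _sphere_amplitude(x: np.ndarray) -> np.ndarray:
    """Normalized sphere scattering amplitude 3(sin x - x cos x)/x³."""
    x = np.asarray(x, dtype=float)
    out = np.ones_like(x)
    nz = x != 0
    xs = x[nz]
    out[nz] = 3.0 * (np.sin(xs) - xs * np.cos(xs)) / xs**3
    return out


def sphere_intensity(q, radius: float, i0: float = 1.0) -> np.ndarray:
    """Exact scattering intensity of a homogeneous sphere of given radius (Å)."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    return i0 * _sphere_amplitude(np.asarray(q, dtype=float) * radius) ** 2


def ellipsoid_intensity(q, a: float, c: float, i0: float = 1.0,
                        quad_order: int = 64) -> np.ndarray:
    """Orientation-averaged intensity of an ellipsoid of revolution.

    Semi-axes (a, a, c); the average over orientations is done by fixed-order
    Gauss–Legendre quadrature in cos(angle) on [0, 1], which is deterministic
    and accurate for smooth form factors.
    """
    if a <= 0 or c <= 0:
        raise ValueError("semi-axes must be positive")
    q = np.asarray(q, dtype=float)
    x, w = np.polynomial.legendre.leggauss(quad_order)
    # map nodes from [-1, 1] to [0, 1]
    u = 0.5 * (x + 1.0)
    w = 0.5 * w
    nu2 = (c / a) ** 2
    r_eff = a * np.sqrt(1.0 + u**2 * (nu2 - 1.0))  # (quad,)
    amp = _sphere_amplitude(np.outer(q, r_eff))  # (nq, quad)
    return i0 * (amp**2) @ w


def prolate_semi_axes(rg: float, dmax: float) -> tuple[float, float]:
    """Semi-axes (a, c) of a prolate ellipsoid with given Rg and Dmax.

    Uses Rg² = (2a² + c²)/5 and Dmax = 2c; raises if the pair is
    geometrically inconsistent (requires a ≤ c for a prolate body).
    """
    c = dmax / 2.0
    a2 = (5.0 * rg**2 - c**2) / 2.0
    if a2 <= 0:
        raise ValueError("Rg too small for the requested Dmax")
    a = float(np.sqrt(a2))
    if a > c:
        raise ValueError("Rg too large for a prolate body with this Dmax")
    return a, float(c)


# ---------------------------------------------------------------------------
# Guinier analysis
# ---------------------------------------------------------------------------

class GuinierAnalysis(BaseEstimator):
    """Automatic Guinier fit on the widest valid low-q window.

    Starting from the lowest-q points, the window is iterated: fit
    ln I = ln I0 - (Rg²/3)·q², update Rg, re-select q ≤ qrg_limit/Rg, until
    the window is stable. The window is then shrunk from the high-q end
    while the fit residuals show systematic structure (runs test at
    ``curvature_p``), which removes the form-factor curvature that leaks
    into the qRg ≤ 1.3 window when data are nearly noise-free. Raises if the
    final window has fewer than ``min_points`` points or the slope implies
    an imaginary Rg.
    """

    def __init__(self, qrg_limit: float = 1.3, qmin_cut: Optional[float] = None,
                 min_points: int = 8, curvature_p: float = 0.05):
        self.qrg_limit = qrg_limit
        self.qmin_cut = qmin_cut
        self.min_points = min_points
        self.curvature_p = curvature_p

    def fit(self, X, y):
        q = _xcol(X)
        intensity = np.asarray(y, dtype=float)
        if self.qmin_cut is not None:
            keep = q >= self.qmin_cut
            q, intensity = q[keep], intensity[keep]
        pos = intensity > 0
        q, intensity = q[pos], intensity[pos]
        if q.size < self.min_points:
            raise ValueError(f"fewer than {self.min_points} usable low-q points")
        q2 = q**2
        lni = np.log(intensity)

        n_win = max(self.min_points, q.size // 10)
        for _ in range(100):
            res = stats.linregress(q2[:n_win], lni[:n_win])
            if res.slope >= 0:
                raise ValueError("non-negative Guinier slope: Rg is imaginary")
            rg = float(np.sqrt(-3.0 * res.slope))
            n_new = int(np.searchsorted(q, self.qrg_limit / rg, side="right"))
            n_new = min(max(n_new, self.min_points), q.size)
            if n_new == n_win:
                break
            n_win = n_new
        # hard invariant: shrink until q_max·Rg ≤ limit (or the floor is hit)
        while n_win > self.min_points and q[n_win - 1] * rg > self.qrg_limit:
            n_win -= 1
            res = stats.linregress(q2[:n_win], lni[:n_win])
            if res.slope >= 0:
                raise ValueError("non-negative Guinier slope: Rg is imaginary")
            rg = float(np.sqrt(-3.0 * res.slope))
        # curvature screen: trim the high-q end while residuals are structured
        from ._fitting import runs_test_p

        while n_win > self.min_points:
            resid = lni[:n_win] - (res.intercept + res.slope * q2[:n_win])
            if runs_test_p(resid) > self.curvature_p:
                break
            n_win -= 1
            res = stats.linregress(q2[:n_win], lni[:n_win])
            if res.slope >= 0:
                raise ValueError("non-negative Guinier slope: Rg is imaginary")
            rg = float(np.sqrt(-3.0 * res.slope))
        if n_win < self.min_points:
            raise ValueError(f"Guinier window shrank below {self.min_points} points")

        self.Rg_ = rg
        self.I0_ = float(np.exp(res.intercept))
        self.Rg_err_ = float(3.0 * res.stderr / (2.0 * rg))
        self.I0_err_ = float(self.I0_ * res.intercept_stderr)
        self.q_range_used_ = (float(q[0]), float(q[n_win - 1]))
        self.qmax_rg_ = float(q[n_win - 1] * rg)
        self.r2_ = float(res.rvalue**2)
        self.n_points_ = int(n_win)
        return self

    def result(self) -> GuinierFit:
        return GuinierFit(
            Rg=self.Rg_, I0=self.I0_, Rg_err=self.Rg_err_, I0_err=self.I0_err_,
            q_range_used=self.q_range_used_, qmax_rg=self.qmax_rg_,
            r2=self.r2_, n_points=self.n_points_,
        )


def guinier_fit(curve: ScatteringCurve, qmin_cut: Optional[float] = None,
                qrg_limit: float = 1.3) -> GuinierFit:
    """Automatic Guinier analysis of a scattering curve."""
    est = GuinierAnalysis(qrg_limit=qrg_limit, qmin_cut=qmin_cut)
    est.fit(curve.q, curve.intensity)
    return est.result()


def kratky(curve: ScatteringCurve) -> tuple[np.ndarray, np.ndarray]:
    """Kratky transform (q, q²·I(q)); globular particles show a bell shape."""
    return curve.q.copy(), curve.q**2 * curve.intensity


# ---------------------------------------------------------------------------
# Indirect Fourier transform
# ---------------------------------------------------------------------------

def _design_matrix(q: np.ndarray, r: np.ndarray) -> np.ndarray:
    """Trapezoid-weighted kernel A with I(q) = A @ p for p sampled on r."""
    dr = r[1] - r[0]
    w = np.full(r.size, dr)
    w[0] = w[-1] = dr / 2.0
    qr = np.outer(q, r)
    kern = np.ones_like(qr)
    nz = qr != 0
    kern[nz] = np.sin(qr[nz]) / qr[nz]
    return 4.0 * np.pi * kern * w


def _second_difference(n_interior: int) -> np.ndarray:
    """Second-difference operator on interior points with zero endpoints."""
    d = np.zeros((n_interior, n_interior))
    for i in range(n_interior):
        d[i, i] = -2.0
        if i > 0:
            d[i, i - 1] = 1.0
        if i < n_interior - 1:
            d[i, i + 1] = 1.0
    return d


def _solve_pr(aw: np.ndarray, yw: np.ndarray, d2: np.ndarray, alpha: float):
    """NNLS solve of the stacked regularized system; returns interior p."""
    top = aw
    bot = alpha * d2
    stacked = np.vstack([top, bot])
    rhs = np.concatenate([yw, np.zeros(d2.shape[0])])
    p, _ = nnls(stacked, rhs)
    return p


def _decay_end(chi: np.ndarray, trials: np.ndarray,
               strong_ratio: float = 0.25, floor_guard: float = 1.0,
               extend_gain: float = 3.0, plateau_rtol: float = 0.05) -> int:
    """Index of the trial Dmax at which the probe χ²(Dmax) stops improving.

    Below the true maximum dimension the data cannot be represented and χ²
    falls steeply — typically by an order of magnitude per Å — so the last
    strong drop (factor < ``strong_ratio``, starting from well above the
    numerical floor) marks the end of the informative decay. When χ²
    continues to improve substantially past that point (near-noiseless data
    with a faint long-distance tail), the estimate is extended to the first
    trial within ``plateau_rtol`` of the remaining minimum. Without any
    strong drop (noise-dominated data) the first trial within
    ``plateau_rtol`` of the global minimum is used.
    """
    n = chi.size
    floor = float(np.median(chi[3 * n // 4:]))
    strong = (chi[1:] < strong_ratio * chi[:-1]) & (chi[:-1] > floor_guard * floor)
    if not np.any(strong):
        return int(np.argmax(chi <= (1.0 + plateau_rtol) * chi.min()))
    i_stop = int(np.nonzero(strong)[0][-1] + 1)
    tail = chi[i_stop:]
    if tail.min() < chi[i_stop] / extend_gain:
        rel = np.argmax(tail <= (1.0 + plateau_rtol) * tail.min())
        return i_stop + int(rel)
    return i_stop


class PairDistanceIFT(BaseEstimator):
    """Regularized indirect Fourier transform for p(r) and Dmax.

    Parameters
    ----------
    dmax : float, optional
        Maximum particle dimension (Å). When None, a 1 Å grid search over
        [2·Rg, 4·Rg] (Rg from an automatic Guinier fit) locates the trial at
        which the reciprocal-space fit quality of a lightly-regularized
        probe solve stops improving — below the true Dmax the data cannot
        be represented and χ² falls steeply with each 1 Å step.
    alpha : float, optional
        Smoothness weight on the second difference of p(r). When None it is
        chosen by an L-curve corner search.
    n_r : int
        Number of r-grid points between 0 and Dmax.

    Notes
    -----
    The inverse problem is solved by non-negative least squares on
    ``I(q) = 4π ∫ p(r)·sinc(qr) dr`` with hard constraints p(0) = p(Dmax) = 0
    and p ≥ 0, so the nonnegativity and endpoint conditions hold by
    construction on every output.
    """

    #: regularization reduction for the Dmax-search probe solves
    _SEARCH_ALPHA_FACTOR = 1e-2

    def __init__(self, dmax: Optional[float] = None, alpha: Optional[float] = None,
                 n_r: int = 81):
        self.dmax = dmax
        self.alpha = alpha
        self.n_r = n_r

    # -- internals ----------------------------------------------------------

    def _weighted_system(self, q, intensity, sigma, dmax):
        r = np.linspace(0.0, dmax, self.n_r)
        a_full = _design_matrix(q, r)
        a = a_full[:, 1:-1]  # endpoint columns are constrained to zero
        w = 1.0 / sigma
        return r, a * w[:, None], intensity * w, a

    def _lcurve_alpha(self, aw, yw, d2):
        """Corner of the residual-norm vs penalty-norm L-curve."""
        scale = np.linalg.norm(aw) / max(np.linalg.norm(d2), 1e-300)
        alphas = scale * np.logspace(-5, 2, 12)
        rho, eta = [], []
        for al in alphas:
            p = _solve_pr(aw, yw, d2, al)
            rho.append(np.log(np.linalg.norm(aw @ p - yw) + 1e-300))
            eta.append(np.log(np.linalg.norm(d2 @ p) + 1e-300))
        rho, eta = np.asarray(rho), np.asarray(eta)
        # discrete curvature of the parametric curve (rho, eta)
        k = np.zeros(len(alphas))
        for i in range(1, len(alphas) - 1):
            x1, x2, x3 = rho[i - 1], rho[i], rho[i + 1]
            y1, y2, y3 = eta[i - 1], eta[i], eta[i + 1]
            area = (x2 - x1) * (y3 - y1) - (x3 - x1) * (y2 - y1)
            d12 = np.hypot(x2 - x1, y2 - y1)
            d23 = np.hypot(x3 - x2, y3 - y2)
            d13 = np.hypot(x3 - x1, y3 - y1)
            denom = d12 * d23 * d13
            k[i] = 2.0 * area / denom if denom > 0 else 0.0
        return float(alphas[int(np.argmax(k))])

    def _probe_chi2(self, q, intensity, sigma, dmax, alpha, d2):
        """Fit quality of a lightly-regularized unconstrained solve.

        Used only by the Dmax search: while the trial Dmax is below the true
        maximum dimension the data cannot be fit and χ² falls steeply (orders
        of magnitude per Å) as the trial grows; at the true Dmax the decay
        terminates. Weak smoothing is essential here — the corner-of-L-curve
        alpha used for the final solve flattens the faint p(r) tail into the
        baseline and ends the decay a few Å early.
        """
        _, aw, yw, _ = self._weighted_system(q, intensity, sigma, dmax)
        stacked = np.vstack([aw, alpha * d2])
        rhs = np.concatenate([yw, np.zeros(d2.shape[0])])
        p, *_ = np.linalg.lstsq(stacked, rhs, rcond=None)
        return float(np.mean((aw @ p - yw) ** 2))

    # -- sklearn surface ----------------------------------------------------

    def fit(self, X, y, sigma: Optional[np.ndarray] = None):
        q = _xcol(X)
        intensity = np.asarray(y, dtype=float)
        if sigma is None:
            sigma = np.full_like(intensity, max(float(np.ptp(intensity)), 1.0) * 1e-2)
        else:
            sigma = np.asarray(sigma, dtype=float)

        if self.dmax is None:
            g = GuinierAnalysis().fit(q, intensity)
            rg = g.Rg_
            trials = np.arange(np.ceil(2.0 * rg), np.floor(4.0 * rg) + 1.0, 1.0)
            if q[0] * trials[0] >= np.pi:
                raise ValueError(
                    "q-range information-insufficient: qmin·Dmax ≥ π"
                )
            # one alpha, chosen mid-range, reused across the scan
            r0, aw0, yw0, _ = self._weighted_system(
                q, intensity, sigma, trials[trials.size // 2]
            )
            d2 = _second_difference(self.n_r - 2)
            alpha = self.alpha if self.alpha is not None else self._lcurve_alpha(
                aw0, yw0, d2
            )
            probe_alpha = alpha * self._SEARCH_ALPHA_FACTOR
            chi = np.array([
                self._probe_chi2(q, intensity, sigma, d, probe_alpha, d2)
                for d in trials
            ])
            dmax = float(trials[_decay_end(chi, trials)])
        else:
            dmax = float(self.dmax)
            if dmax <= 0:
                raise ValueError("dmax must be positive")
            if q[0] * dmax >= np.pi:
                raise ValueError("q-range information-insufficient: qmin·Dmax ≥ π")

        r, aw, yw, a_unw = self._weighted_system(q, intensity, sigma, dmax)
        d2 = _second_difference(self.n_r - 2)
        alpha = self.alpha if self.alpha is not None else self._lcurve_alpha(aw, yw, d2)
        p_int = _solve_pr(aw, yw, d2, alpha)
        p = np.concatenate([[0.0], p_int, [0.0]])
        negative = bool(np.any(p < 0))
        p = np.clip(p, 0.0, None)

        norm = np.trapezoid(p, r)
        if norm <= 0:
            raise ValueError("IFT produced an identically zero p(r); check alpha")
        rg2 = np.trapezoid(r**2 * p, r) / (2.0 * norm)
        self.r_ = r
        self.p_ = p
        self.Dmax_ = dmax
        self.Rg_real_ = float(np.sqrt(rg2))
        self.I0_ = float(4.0 * np.pi * norm)
        self.alpha_ = float(alpha)
        self.chi2_ = float(np.mean((aw @ p_int - yw) ** 2))
        self.negative_lobe_flag_ = negative
        return self

    def predict(self, X):
        """Reciprocal-space curve implied by the fitted p(r)."""
        q = _xcol(X)
        a = _design_matrix(q, self.r_)
        return a @ self.p_

    def result(self) -> PairDistribution:
        return PairDistribution(
            r=self.r_, p=self.p_, Dmax=self.Dmax_, Rg_real=self.Rg_real_,
            I0=self.I0_, alpha=self.alpha_, chi2=self.chi2_,
            negative_lobe_flag=self.negative_lobe_flag_,
        )


def ift_pr(curve: ScatteringCurve, dmax_trial: Optional[float] = None,
           alpha: Optional[float] = None, n_r: int = 81) -> PairDistribution:
    """Pair-distance distribution by regularized IFT (Dmax searched if None)."""
    est = PairDistanceIFT(dmax=dmax_trial, alpha=alpha, n_r=n_r)
    est.fit(curve.q, curve.intensity, sigma=curve.sigma)
    return est.result()


# ---------------------------------------------------------------------------
# Molecular weight from I(0)/C
# ---------------------------------------------------------------------------

def mw_from_i0(sample: ScatteringCurve,
               refs: Sequence[tuple[ScatteringCurve, float]]) -> float:
    """Molecular weight (kDa) from concentration-normalized zero-angle intensity.

    Each reference is a (curve, known MW in kDa) pair measured at known
    concentration; I(0) values come from the automatic Guinier fit. The
    sample MW is (I0/C)_sample divided by the mean specific signal
    (I0/C)/MW of the references.
    """
    if sample.concentration is None:
        raise ValueError("sample curve needs a concentration")
    if not refs:
        raise ValueError("at least one reference standard is required")
    i0_s = guinier_fit(sample).I0
    specific = []
    for curve, mw in refs:
        if curve.concentration is None:
            raise ValueError("reference curve needs a concentration")
        if mw <= 0:
            raise ValueError("reference MW must be positive")
        specific.append(guinier_fit(curve).I0 / curve.concentration / mw)
    return float(i0_s / sample.concentration / np.mean(specific))


# ---------------------------------------------------------------------------
# Debye model scattering and discrepancy
# ---------------------------------------------------------------------------

def debye_intensity(model: AtomicModel, q_grid,
                    hist_bin: Optional[float] = None) -> ScatteringCurve:
    """In-vacuo Debye-sum intensity of a point-scatterer model.

    I(q) = Σᵢ Σⱼ wᵢwⱼ·sinc(q·rᵢⱼ). With ``hist_bin`` set, pair distances are
    binned at that width (Å) and the sum runs over bin centers — an O(N²)
    histogram build then O(n_bins) per q point.
    """
    q = np.asarray(q_grid, dtype=float)
    w = model.weights
    self_term = float(np.sum(w**2))
    n = w.size
    if n == 1:
        return ScatteringCurve(q=q, intensity=np.full(q.size, self_term))
    d = pdist(model.coordinates)
    iu, ju = np.triu_indices(n, k=1)
    pw = w[iu] * w[ju]
    if hist_bin is not None:
        nbins = max(int(np.ceil(d.max() / hist_bin)), 1)
        hist, edges = np.histogram(d, bins=nbins, range=(0.0, nbins * hist_bin),
                                   weights=pw)
        centers = 0.5 * (edges[:-1] + edges[1:])
        keep = hist != 0
        d, pw = centers[keep], hist[keep]
    intensity = np.empty(q.size)
    for i, qi in enumerate(q):
        x = qi * d
        kern = np.ones_like(x)
        nz = x != 0
        kern[nz] = np.sin(x[nz]) / x[nz]
        intensity[i] = self_term + 2.0 * float(pw @ kern)
    return ScatteringCurve(q=q, intensity=intensity, label=model.label)


def chi2_discrepancy(data: ScatteringCurve, model: ScatteringCurve,
                     scale: Optional[float] = None) -> Discrepancy:
    """Reduced χ² between data and a model curve.

    χ² = (1/N)·Σ((I_data − s·I_model)/σ)², with s the analytic least-squares
    scale unless ``scale`` is given. The model is linearly interpolated onto
    the overlapping part of the data grid; per-point data errors are
    required (no silent unit weights).
    """
    if data.sigma is None:
        raise ValueError("data curve needs per-point errors for χ²")
    lo = max(data.q[0], model.q[0])
    hi = min(data.q[-1], model.q[-1])
    sel = (data.q >= lo) & (data.q <= hi)
    if sel.sum() < 2:
        raise ValueError("no common q support between data and model")
    qd = data.q[sel]
    yd = data.intensity[sel]
    sd = data.sigma[sel]
    ym = np.interp(qd, model.q, model.intensity)
    if scale is None:
        scale = float(np.sum(yd * ym / sd**2) / np.sum(ym**2 / sd**2))
    chi2 = float(np.mean(((yd - scale * ym) / sd) ** 2))
    return Discrepancy(chi2=chi2, scale=float(scale), n_points=int(sel.sum()))
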