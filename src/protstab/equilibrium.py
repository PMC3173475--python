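"""Two-state equilibrium unfolding by linear extrapolation, and thermal melts.

Model
-----
For a reversible two-state transition N ⇌ D with equilibrium constant
``k_den = [D]/[N]``, the unfolding free energy is

    ΔG = -R·T·ln(k_den),

and the linear extrapolation method (LEM) posits

    ΔG([den]) = ΔG° - m·[den],

with ΔG° the unfolding free energy in water and m proportional to the change
in solvent-accessible surface area on unfolding. The denatured fraction is

    f_D = 1 / (1 + exp((ΔG° - m·[den]) / (R·T))),

and the observed spectroscopic signal is the population-weighted average of
the native and denatured endpoint signals,

    S_obs = S_N·f_N + S_D·f_D.

``TwoStateUnfolding`` fits (ΔG°, m, S_N, S_D) to an isotherm; by default the
baselines are denaturant-independent constants, with an optional
Santoro–Bolen-style linear-baseline extension. The gas constant is fixed at
1.9872 cal·mol⁻¹·K⁻¹ (see :mod:`protstab.constants`).

Thermal melts are fit with a four-parameter sigmoid logistic in temperature;
only the apparent transition temperature Tm is thermodynamically meaningful
when melting is irreversible.
"""

from __future__ import annotations

import warnings
from typing import Optional

import numpy as np
from scipy.special import expit
from sklearn.base import BaseEstimator, RegressorMixin

from ._fitting import fit_least_squares, param_errors
from .constants import R_GAS_KCAL
from .datatypes import (
    AsaComparison,
    DenaturationIsotherm,
    ThermalCurve,
    ThermalFit,
    TwoStateFit,
)


# ---------------------------------------------------------------------------
# Closed-form pieces of the LEM model
# ---------------------------------------------------------------------------

def lem_free_energy(k_den: float, temperature: float) -> float:
    """Unfolding free energy ΔG = -R·T·ln(k_den), in kcal/mol.

    Parameters
    ----------
    k_den : float
        Equilibrium denaturation constant [D]/[N]; must be positive.
    temperature : float
        Absolute temperature in K; must be positive.
    """
    if k_den <= 0:
        raise ValueError("k_den must be positive")
    if temperature <= 0:
        raise ValueError("temperature must be positive (Kelvin)")
    return float(-R_GAS_KCAL * temperature * np.log(k_den))


def fraction_denatured(dG0, m, conc, temperature: float = 298.15):
    """Denatured fraction under the LEM model (array-safe in ``conc``).

    f_D = 1/(1 + exp((ΔG° − m·[den])/(R·T))); f_N = 1 − f_D.
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive (Kelvin)")
    rt = R_GAS_KCAL * temperature
    return expit((np.asarray(conc, dtype=float) * m - dG0) / rt)


def _two_state_signal(conc, dG0, m, s_n, s_d, rt):
    fd = expit((conc * m - dG0) / rt)
    return s_n * (1.0 - fd) + s_d * fd


def _two_state_signal_linbase(conc, dG0, m, s_n, s_d, a_n, a_d, rt):
    fd = expit((conc * m - dG0) / rt)
    return (s_n + a_n * conc) * (1.0 - fd) + (s_d + a_d * conc) * fd


def _xcol(X) -> np.ndarray:
    """Accept a 1-D vector or a single-column 2-D matrix."""
    arr = np.asarray(X, dtype=float)
    if arr.ndim == 2 and arr.shape[1] == 1:
        arr = arr[:, 0]
    if arr.ndim != 1:
        raise ValueError(f"expected a 1-D vector or (n, 1) matrix, got shape {arr.shape}")
    return arr


# ---------------------------------------------------------------------------
# Estimators
# ---------------------------------------------------------------------------

class TwoStateUnfolding(BaseEstimator, RegressorMixin):
    """Two-state LEM fit of an equilibrium denaturation isotherm.

    Parameters
    ----------
    temperature : float, default 298.15
        Absolute temperature (K) entering R·T.
    linear_baselines : bool, default False
        Float per-state linear baseline slopes (Santoro–Bolen style) in
        addition to the constant endpoint signals.
    init : dict, optional
        Optional start values; keys among {"dG0", "m", "signal_native",
        "signal_denatured"}. Missing keys fall back to data-driven starts.
    plateau_rtol : float, default 0.05
        Flatness tolerance for the pre/post-transition plateau check, as a
        fraction of the total signal range.

    Attributes
    ----------
    dG0_, m_ : float
        Unfolding free energy (kcal/mol) and m-value (kcal/(mol·M)).
    signal_native_, signal_denatured_ : float
        Endpoint signals (at 0 M denaturant when baselines are linear).
    midpoint_ : float
        Transition midpoint ΔG°/m (M).
    covariance_ : ndarray
        Parameter covariance, order (dG0, m, S_N, S_D[, a_N, a_D]).
    """

    def __init__(
        self,
        temperature: float = 298.15,
        linear_baselines: bool = False,
        init: Optional[dict] = None,
        plateau_rtol: float = 0.05,
    ):
        self.temperature = temperature
        self.linear_baselines = linear_baselines
        self.init = init
        self.plateau_rtol = plateau_rtol

    def _initial_guess(self, conc, y):
        n = conc.size
        edge = max(2, n // 10)
        s_n = float(np.mean(y[:edge]))
        s_d = float(np.mean(y[-edge:]))
        span = s_d - s_n
        if span == 0:
            span = 1.0
        # midpoint: first crossing of the half-signal level
        half = s_n + 0.5 * span
        crossing = np.nonzero(np.diff(np.sign(y - half)))[0]
        if crossing.size:
            i = crossing[0]
            f = (half - y[i]) / (y[i + 1] - y[i]) if y[i + 1] != y[i] else 0.5
            cm = float(conc[i] + f * (conc[i + 1] - conc[i]))
        else:
            cm = float(np.median(conc))
        if cm <= 0:
            cm = float(np.median(conc[conc > 0])) if np.any(conc > 0) else 1.0
        # m from the maximal signal slope: dS/dc at midpoint = span·m/(4RT)
        rt = R_GAS_KCAL * self.temperature
        dy = np.gradient(y, conc)
        max_slope = float(np.max(np.abs(dy)))
        m0 = 4.0 * rt * max_slope / abs(span)
        m0 = max(m0, 1e-3)
        init = dict(self.init or {})
        return (
            init.get("dG0", m0 * cm),
            init.get("m", m0),
            init.get("signal_native", s_n),
            init.get("signal_denatured", s_d),
        )

    def fit(self, X, y):
        conc = _xcol(X)
        y = np.asarray(y, dtype=float)
        if conc.size != y.size:
            raise ValueError("X and y must have equal length")
        n_par = 6 if self.linear_baselines else 4
        if conc.size < n_par:
            raise ValueError(f"need at least {n_par} points to fit {n_par} parameters")
        rt = R_GAS_KCAL * self.temperature

        # plateau screen: both ends should be flat relative to the full swing
        edge = max(2, conc.size // 10)
        span = abs(np.mean(y[-edge:]) - np.mean(y[:edge]))
        tol = self.plateau_rtol * max(span, np.ptp(y), 1e-12)
        self.plateau_warning_ = bool(
            np.ptp(y[:edge]) > tol or np.ptp(y[-edge:]) > tol
        )
        if self.plateau_warning_:
            warnings.warn(
                "isotherm end segments are not flat; baselines may be poorly "
                "determined",
                stacklevel=2,
            )

        dg0, m0, s_n0, s_d0 = self._initial_guess(conc, y)
        if self.linear_baselines:
            model = lambda c, dg, m, sn, sd, an, ad: _two_state_signal_linbase(
                c, dg, m, sn, sd, an, ad, rt
            )
            p0 = [dg0, m0, s_n0, s_d0, 0.0, 0.0]
        else:
            model = lambda c, dg, m, sn, sd: _two_state_signal(c, dg, m, sn, sd, rt)
            p0 = [dg0, m0, s_n0, s_d0]

        popt, pcov, resid = fit_least_squares(model, conc, y, p0)
        errs = param_errors(pcov)
        self.dG0_, self.m_ = float(popt[0]), float(popt[1])
        self.signal_native_, self.signal_denatured_ = float(popt[2]), float(popt[3])
        self.baseline_slopes_ = (
            (float(popt[4]), float(popt[5])) if self.linear_baselines else None
        )
        self.dG0_err_, self.m_err_ = float(errs[0]), float(errs[1])
        self.signal_native_err_ = float(errs[2])
        self.signal_denatured_err_ = float(errs[3])
        self.covariance_ = pcov
        self.midpoint_ = self.dG0_ / self.m_ if self.m_ != 0 else np.nan
        self.residuals_ = resid
        self.residual_rms_ = float(np.sqrt(np.mean(resid**2)))
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        conc = _xcol(X)
        rt = R_GAS_KCAL * self.temperature
        if self.baseline_slopes_ is not None:
            a_n, a_d = self.baseline_slopes_
            return _two_state_signal_linbase(
                conc, self.dG0_, self.m_, self.signal_native_,
                self.signal_denatured_, a_n, a_d, rt,
            )
        return _two_state_signal(
            conc, self.dG0_, self.m_, self.signal_native_, self.signal_denatured_, rt
        )

    def result(self) -> TwoStateFit:
        """Package the fitted attributes as a :class:`TwoStateFit` record."""
        return TwoStateFit(
            dG0=self.dG0_,
            m_value=self.m_,
            signal_native=self.signal_native_,
            signal_denatured=self.signal_denatured_,
            dG0_err=self.dG0_err_,
            m_err=self.m_err_,
            signal_native_err=self.signal_native_err_,
            signal_denatured_err=self.signal_denatured_err_,
            covariance=self.covariance_,
            midpoint=self.midpoint_,
            temperature=self.temperature,
            residual_rms=self.residual_rms_,
            n_points=self.residuals_.size,
            baseline_slopes=self.baseline_slopes_,
            plateau_warning=self.plateau_warning_,
        )


class ThermalMelt(BaseEstimator, RegressorMixin):
    """Four-parameter sigmoid logistic fit of a thermal melt.

    y(T) = baseline + amplitude / (1 + exp(-(T - Tm)/slope))

    The inflection temperature Tm is the apparent transition temperature;
    amplitude may take either sign (ellipticity typically becomes less
    negative on unfolding).
    """

    def __init__(self, init: Optional[dict] = None):
        self.init = init

    @staticmethod
    def _model(t, baseline, amplitude, tm, slope):
        return baseline + amplitude * expit((t - tm) / slope)

    def fit(self, X, y):
        t = _xcol(X)
        y = np.asarray(y, dtype=float)
        if t.size != y.size:
            raise ValueError("X and y must have equal length")
        if t.size < 8:
            raise ValueError("need at least 8 points spanning the transition")
        edge = max(2, t.size // 10)
        y0 = float(np.mean(y[:edge]))
        y1 = float(np.mean(y[-edge:]))
        half = 0.5 * (y0 + y1)
        crossing = np.nonzero(np.diff(np.sign(y - half)))[0]
        tm0 = float(t[crossing[0]]) if crossing.size else float(np.median(t))
        init = dict(self.init or {})
        p0 = [
            init.get("baseline", y0),
            init.get("amplitude", y1 - y0),
            init.get("tm", tm0),
            init.get("slope", max(np.ptp(t) / 20.0, 1e-3)),
        ]
        popt, pcov, resid = fit_least_squares(self._model, t, y, p0)
        errs = param_errors(pcov)
        self.baseline_, self.amplitude_ = float(popt[0]), float(popt[1])
        self.tm_, self.slope_ = float(popt[2]), float(popt[3])
        self.tm_err_ = float(errs[2])
        self.covariance_ = pcov
        self.residual_rms_ = float(np.sqrt(np.mean(resid**2)))
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        return self._model(_xcol(X), self.baseline_, self.amplitude_, self.tm_, self.slope_)

    def result(self) -> ThermalFit:
        return ThermalFit(
            tm=self.tm_,
            amplitude=self.amplitude_,
            slope=self.slope_,
            baseline=self.baseline_,
            tm_err=self.tm_err_,
            covariance=self.covariance_,
            residual_rms=self.residual_rms_,
        )


# ---------------------------------------------------------------------------
# Module-level wrappers and comparisons
# ---------------------------------------------------------------------------

def fit_two_state(
    iso: DenaturationIsotherm,
    init: Optional[dict] = None,
    linear_baselines: bool = False,
) -> TwoStateFit:
    """Fit a denaturation isotherm with the two-state LEM model."""
    est = TwoStateUnfolding(
        temperature=iso.temperature, linear_baselines=linear_baselines, init=init
    )
    est.fit(iso.denaturant, iso.signal)
    return est.result()


def fit_thermal(melt: ThermalCurve, init: Optional[dict] = None) -> ThermalFit:
    """Fit a thermal melt with the four-parameter logistic."""
    est = ThermalMelt(init=init)
    est.fit(melt.temperature_c, melt.ellipticity)
    return est.result()


def compare_asa(fit_apo: TwoStateFit, fit_holo: TwoStateFit) -> AsaComparison:
    """Compare m-values between free and ligand-bound fits.

    Δm = m_holo − m_apo tracks the binding-induced change in unfolding ΔASA
    under the assumption of a common unfolded state. The sign is called only
    when |Δm| exceeds the combined 1-sigma error of the two fits.
    """
    delta = fit_holo.m_value - fit_apo.m_value
    err = float(np.hypot(fit_apo.m_err, fit_holo.m_err))
    if np.isfinite(err) and abs(delta) > err:
        sign = "positive" if delta > 0 else "negative"
    else:
        sign = "indeterminate"
    return AsaComparison(
        m_apo=fit_apo.m_value,
        m_holo=fit_holo.m_value,
        delta_m=delta,
        delta_m_err=err,
        sign_ddASA=sign,
    )


def ddG(fit_apo: TwoStateFit, fit_holo: TwoStateFit) -> tuple[float, float]:
    """Stability gain ΔΔG = ΔG°_holo − ΔG°_apo with propagated 1-sigma error."""
    value = fit_holo.dG0 - fit_apo.dG0
    err = float(np.hypot(fit_apo.dG0_err, fit_holo.dG0_err))
    return value, err
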