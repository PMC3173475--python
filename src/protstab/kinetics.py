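"""Stopped-flow kinetics: exponential traces, lag phases, chevron plots and
activation thermodynamics.

Observed transitions are fit with the single-exponential convention

    F(t) = F0 + Amp·(exp(-k·t) - 1),

so a positive amplitude denotes a signal decay (unfolding quenches
tryptophan fluorescence) and a negative amplitude a rise.

Chevron analysis assembles ln k versus denaturant per direction, screens each
arm for linearity (iterative endpoint trimming until a runs test on the
residuals no longer rejects randomness), and extrapolates both arms to water:
k_NU(0) and k_UN(0). For a two-state system the kinetic and equilibrium
pictures must agree,

    k_eq = k_NU/k_UN,   ΔG° = -R·T·ln(k_NU(0)/k_UN(0)),

which is exposed as ``dG_kinetic``. Deviation of the unfolding arm from
linearity at high denaturant ("rollover") flags a populated intermediate.

Temperature series are analyzed two ways: the linear Arrhenius form
ln k = ln γ - ΔE‡/(R·T), and the transition-state form with a
temperature-dependent activation enthalpy,

    ln k = ln(k_B·T/h) + ΔS‡(T)/R - ΔH‡(T)/(R·T),
    ΔH‡(T) = ΔH‡ + ΔCp‡·(T - T0),   ΔS‡(T) = ΔS‡ + ΔCp‡·ln(T/T0),

whose curvature in 1/T measures the activation heat capacity ΔCp‡. The
prefactor is fixed at k_B/h: a free pre-exponential γ would be exactly
degenerate with ΔS‡, so the reported entropy absorbs that convention.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
from scipy import stats
from scipy.signal import savgol_filter
from sklearn.base import BaseEstimator, RegressorMixin

from ._fitting import fit_least_squares, param_errors, runs_test_p
from .constants import KB_OVER_H, R_GAS_KCAL
from .datatypes import (
    ChevronArm,
    ChevronFit,
    ExponentialFit,
    EyringFit,
    EyringSeries,
    KineticTrace,
    LagResult,
)
from .equilibrium import _xcol


# ---------------------------------------------------------------------------
# Model functions
# ---------------------------------------------------------------------------

def exponential_signal(t, offset, amplitude, rate):
    """Single-exponential trace F(t) = F0 + Amp·(exp(-k·t) - 1)."""
    return offset + amplitude * (np.exp(-rate * np.asarray(t, dtype=float)) - 1.0)


def eyring_ln_rate(temperature, dH, dS, dCp, T0: float = 298.0):
    """Transition-state ln k with activation heat capacity (kcal units).

    ΔH‡ and ΔS‡ are the activation enthalpy/entropy at the reference
    temperature T0; ΔCp‡ carries their temperature dependence.
    """
    t = np.asarray(temperature, dtype=float)
    dh_t = dH + dCp * (t - T0)
    ds_t = dS + dCp * np.log(t / T0)
    return np.log(KB_OVER_H * t) + ds_t / R_GAS_KCAL - dh_t / (R_GAS_KCAL * t)


# ---------------------------------------------------------------------------
# Single-exponential trace fitting
# ---------------------------------------------------------------------------

class SingleExponential(BaseEstimator, RegressorMixin):
    """Least-squares fit of a single-exponential stopped-flow trace.

    Attributes
    ----------
    rate_ : float
        Observed rate constant k (s^-1), constrained positive.
    amplitude_ : float
        Total signal change; positive for a decay under this convention.
    offset_ : float
        Initial signal F0.
    residuals_ : ndarray
        Fit residuals, exported for flatness inspection.
    rate_at_bound_ : bool
        True when k pinned near the positivity bound (degenerate trace).
    """

    #: lower bound keeping the rate positive during optimization
    _RATE_FLOOR = 1e-12

    def fit(self, X, y):
        t = _xcol(X)
        y = np.asarray(y, dtype=float)
        if t.size != y.size:
            raise ValueError("X and y must have equal length")
        if np.ptp(y) == 0:
            raise ValueError("signal does not vary; nothing to fit")
        f0 = float(np.mean(y[: max(2, t.size // 20)]))
        amp0 = f0 - float(np.mean(y[-max(2, t.size // 20):]))
        if amp0 == 0:
            amp0 = np.ptp(y) or 1.0
        # crude rate start: time to cover (1 - 1/e) of the swing
        target = f0 - amp0 * (1.0 - np.exp(-1.0))
        idx = np.argmin(np.abs(y - target))
        t_e = t[idx] if t[idx] > 0 else (t[-1] - t[0]) / 3.0
        k0 = 1.0 / max(t_e, 1e-9)
        popt, pcov, resid = fit_least_squares(
            exponential_signal,
            t,
            y,
            [f0, amp0, k0],
            bounds=([-np.inf, -np.inf, self._RATE_FLOOR], [np.inf, np.inf, np.inf]),
        )
        errs = param_errors(pcov)
        self.offset_, self.amplitude_, self.rate_ = map(float, popt)
        self.rate_err_ = float(errs[2])
        self.residuals_ = resid
        self.residual_rms_ = float(np.sqrt(np.mean(resid**2)))
        self.rate_at_bound_ = bool(self.rate_ < 10 * self._RATE_FLOOR)
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        return exponential_signal(_xcol(X), self.offset_, self.amplitude_, self.rate_)

    def result(self) -> ExponentialFit:
        return ExponentialFit(
            rate=self.rate_,
            amplitude=self.amplitude_,
            offset=self.offset_,
            rate_err=self.rate_err_,
            residual_rms=self.residual_rms_,
            residuals=self.residuals_,
            rate_at_bound=self.rate_at_bound_,
        )


def fit_exponential(trace: KineticTrace) -> ExponentialFit:
    """Fit a kinetic trace to the single-exponential model."""
    est = SingleExponential().fit(trace.time, trace.signal)
    return est.result()


# ---------------------------------------------------------------------------
# Lag-phase extraction
# ---------------------------------------------------------------------------

def detect_lag(trace: KineticTrace) -> LagResult:
    """Lag duration of a refolding trace by maximal-slope tangent extrapolation.

    The tangent is taken at the point of maximal (smoothed) slope of the
    rising signal; the lag is the time at which that tangent line crosses
    the initial signal level. A trace whose slope is already maximal at
    t = 0 (a pure exponential rise) has no lag and is flagged as such.
    """
    if trace.direction != "refolding":
        raise ValueError("lag detection applies to refolding traces")
    t, y = trace.time, trace.signal
    n = t.size
    # noise-adaptive smoothing: a narrow window preserves the tangent on
    # clean data; noisy data get ~10% of the trace so noise cannot relocate
    # the maximal-slope point
    w_small = min(11, (n - 1) | 1)
    probe = savgol_filter(y, w_small, 2) if w_small >= 5 else y
    noise_ratio = float(np.std(y - probe) / max(np.ptp(y), 1e-300))
    if noise_ratio < 1e-3:
        window = w_small
    else:
        window = min(51, max(5, (n // 10) | 1), (n - 1) | 1)
    smooth = savgol_filter(y, window, 2) if window >= 5 else y
    dy = np.gradient(smooth, t)
    imax = int(np.argmax(dy))
    dmax = dy[imax]
    if dmax <= 0:
        return LagResult(lag_duration=0.0, line_slope=0.0, line_intercept=float(y[0]),
                         no_lag_flag=True)
    baseline = float(smooth[0])  # denoised initial signal level
    # maximal slope within half a smoothing window of t0 is indistinguishable
    # from a monotone rise: no lag
    if imax <= window // 2:
        return LagResult(lag_duration=0.0, line_slope=float(dmax),
                         line_intercept=baseline, no_lag_flag=True)
    # tangent at the inflection point of the (smoothed) rise
    slope = float(dmax)
    intercept = float(smooth[imax] - slope * t[imax])
    lag = (baseline - intercept) / slope
    no_lag = lag <= 0
    return LagResult(
        lag_duration=float(max(lag, 0.0)),
        line_slope=float(slope),
        line_intercept=float(intercept),
        no_lag_flag=bool(no_lag),
    )


# ---------------------------------------------------------------------------
# Chevron analysis
# ---------------------------------------------------------------------------

def _fit_arm(conc, lnk, direction, temperature, p_threshold=0.05):
    """Linear arm fit with iterative endpoint trimming until residuals pass a
    runs test; returns the arm record and the excluded concentrations."""
    order = np.argsort(conc)
    conc, lnk = conc[order], lnk[order]
    mask = np.ones(conc.size, dtype=bool)
    while mask.sum() > 3:
        c, k = conc[mask], lnk[mask]
        slope, intercept = np.polyfit(c, k, 1)
        resid = k - (slope * c + intercept)
        if runs_test_p(resid) > p_threshold:
            break
        idx = np.nonzero(mask)[0]
        # trim the endpoint deviating more from the line
        drop = idx[0] if abs(resid[0]) > abs(resid[-1]) else idx[-1]
        mask[drop] = False
    c, k = conc[mask], lnk[mask]
    if c.size < 2:
        return None, conc[~mask], order
    if c.size > 2:
        coef, cov = np.polyfit(c, k, 1, cov=True)
    else:
        coef = np.polyfit(c, k, 1)
        cov = np.full((2, 2), np.nan)
    arm = ChevronArm(
        direction=direction,
        slope=float(coef[0]),
        intercept=float(coef[1]),
        slope_err=float(np.sqrt(cov[0, 0])) if np.all(np.isfinite(cov)) else np.nan,
        intercept_err=float(np.sqrt(cov[1, 1])) if np.all(np.isfinite(cov)) else np.nan,
        m_ddagger=float(abs(coef[0]) * R_GAS_KCAL * temperature),
        used_mask=mask,
    )
    return arm, conc[~mask], order


class ChevronAnalysis(BaseEstimator):
    """Chevron-plot assembly and linear-arm extrapolation to 0 M denaturant.

    ``fit(X, y)`` takes ``X`` with columns (denaturant_M, direction_code)
    where the code is 0 for unfolding and 1 for refolding, and ``y`` the
    natural log of the observed rate. Points failing the per-arm linearity
    screen (rollover) are excluded from the line and flagged.
    """

    DIRECTION_CODES = {"unfolding": 0, "refolding": 1}

    def __init__(self, temperature: float = 298.15, p_threshold: float = 0.05):
        self.temperature = temperature
        self.p_threshold = p_threshold

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        lnk = np.asarray(y, dtype=float)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError("X must have two columns: (denaturant, direction code)")
        conc, code = X[:, 0], X[:, 1].astype(int)

        self.arms_ = {}
        rollover = False
        onset = None
        for name, c in self.DIRECTION_CODES.items():
            sel = code == c
            if sel.sum() == 0:
                continue
            if sel.sum() < 3 and sel.sum() != 2:
                raise ValueError(f"{name} arm needs at least 3 points")
            if sel.sum() == 2:
                # two exact points define the line
                cc, kk = conc[sel], lnk[sel]
                slope = (kk[1] - kk[0]) / (cc[1] - cc[0])
                intercept = kk[0] - slope * cc[0]
                arm = ChevronArm(
                    direction=name, slope=float(slope), intercept=float(intercept),
                    slope_err=np.nan, intercept_err=np.nan,
                    m_ddagger=float(abs(slope) * R_GAS_KCAL * self.temperature),
                    used_mask=np.ones(2, dtype=bool),
                )
                excluded = np.array([])
            else:
                arm, excluded, _ = _fit_arm(
                    conc[sel], lnk[sel], name, self.temperature, self.p_threshold
                )
            if arm is None:
                self.arms_[name] = None
                continue
            self.arms_[name] = arm
            if name == "unfolding" and excluded.size:
                rollover = True
                onset = float(np.min(excluded))

        unf = self.arms_.get("unfolding")
        ref = self.arms_.get("refolding")
        self.kNU0_ = float(np.exp(unf.intercept)) if unf else None
        self.kUN0_ = float(np.exp(ref.intercept)) if ref else None
        if unf and ref:
            self.keq0_ = self.kNU0_ / self.kUN0_
            self.dG_kinetic_ = -R_GAS_KCAL * self.temperature * np.log(self.keq0_)
        else:
            self.keq0_ = None
            self.dG_kinetic_ = None
        self.rollover_flag_ = rollover
        self.rollover_onset_ = onset
        self._conc, self._lnk, self._code = conc, lnk, code
        return self

    def result(self) -> ChevronFit:
        names = {v: k for k, v in self.DIRECTION_CODES.items()}
        return ChevronFit(
            denaturant=self._conc,
            ln_rate=self._lnk,
            direction=[names[c] for c in self._code],
            unfolding_arm=self.arms_.get("unfolding"),
            refolding_arm=self.arms_.get("refolding"),
            kNU0=self.kNU0_,
            kUN0=self.kUN0_,
            keq0=self.keq0_,
            dG_kinetic=self.dG_kinetic_,
            temperature=self.temperature,
            rollover_flag=self.rollover_flag_,
            rollover_onset=self.rollover_onset_,
        )


def build_chevron(
    fits: Sequence[tuple], temperature: float = 298.15, p_threshold: float = 0.05
) -> ChevronFit:
    """Assemble a chevron from (rate-or-ExponentialFit, denaturant, direction)
    triples and fit both arms."""
    rows, lnk = [], []
    for fit, den, direction in fits:
        rate = fit.rate if hasattr(fit, "rate") else float(fit)
        if rate <= 0:
            raise ValueError("rates must be positive")
        rows.append([den, ChevronAnalysis.DIRECTION_CODES[direction]])
        lnk.append(np.log(rate))
    est = ChevronAnalysis(temperature=temperature, p_threshold=p_threshold)
    est.fit(np.asarray(rows, dtype=float), np.asarray(lnk, dtype=float))
    return est.result()


# ---------------------------------------------------------------------------
# Activation thermodynamics
# ---------------------------------------------------------------------------

class ArrheniusAnalysis(BaseEstimator, RegressorMixin):
    """Linear Arrhenius fit: ln k regressed on 1/(R·T); slope gives -ΔE‡.

    A quadratic term in 1/(R·T) is also fit to quantify residual curvature
    (its t-statistic and p-value), which is the diagnostic for a
    temperature-dependent activation enthalpy.
    """

    def fit(self, X, y):
        t = _xcol(X)
        lnk = np.asarray(y, dtype=float)
        if t.size < 4:
            raise ValueError("need at least 4 temperatures")
        x = 1.0 / (R_GAS_KCAL * t)
        res = stats.linregress(x, lnk)
        self.dE_ = float(-res.slope)
        self.dE_err_ = float(res.stderr)
        self.prefactor_ln_ = float(res.intercept)
        self.residuals_ = lnk - (res.slope * x + res.intercept)
        # curvature diagnostic from a quadratic expansion
        if t.size >= 5:
            coef, cov = np.polyfit(x - x.mean(), lnk, 2, cov=True)
            tstat = coef[0] / np.sqrt(cov[0, 0])
            self.curvature_stat_ = float(tstat)
            self.curvature_p_ = float(2 * stats.t.sf(abs(tstat), t.size - 3))
        else:
            self.curvature_stat_ = np.nan
            self.curvature_p_ = np.nan
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        x = 1.0 / (R_GAS_KCAL * _xcol(X))
        return -self.dE_ * x + self.prefactor_ln_

    def result(self) -> EyringFit:
        return EyringFit(
            dH=np.nan, dS=np.nan, dCp=0.0, T0=np.nan,
            dE_arrhenius=self.dE_,
            prefactor_ln=self.prefactor_ln_,
            curvature_stat=self.curvature_stat_,
            curvature_p=self.curvature_p_,
            residual_rms=float(np.sqrt(np.mean(self.residuals_**2))),
        )


class EyringCp(BaseEstimator, RegressorMixin):
    """Nonlinear Eyring fit with activation heat capacity.

    Fits (ΔH‡, ΔS‡, ΔCp‡) at reference temperature ``T0`` (default 298 K).
    Setting ``fix_dCp=0`` recovers the constant-enthalpy transition-state
    model, whose slope-derived enthalpy matches the Arrhenius ΔE‡ minus RT.
    """

    def __init__(self, T0: float = 298.0, fix_dCp: Optional[float] = None):
        self.T0 = T0
        self.fix_dCp = fix_dCp

    def fit(self, X, y):
        t = _xcol(X)
        lnk = np.asarray(y, dtype=float)
        if t.size < 6 and self.fix_dCp is None:
            raise ValueError("need at least 6 temperatures to fit ΔCp‡")
        span = np.ptp(t)
        # starts from the linear model
        x = 1.0 / (R_GAS_KCAL * t)
        lin = stats.linregress(x, lnk)
        dh0 = -lin.slope - R_GAS_KCAL * self.T0
        ds0 = R_GAS_KCAL * (lin.intercept - np.log(KB_OVER_H * self.T0))
        if self.fix_dCp is not None:
            model = lambda tt, dh, ds: eyring_ln_rate(tt, dh, ds, self.fix_dCp, self.T0)
            p0 = [dh0, ds0]
        else:
            model = lambda tt, dh, ds, dcp: eyring_ln_rate(tt, dh, ds, dcp, self.T0)
            p0 = [dh0, ds0, 0.0]
        popt, pcov, resid = fit_least_squares(model, t, lnk, p0)
        errs = param_errors(pcov)
        self.dH_, self.dS_ = float(popt[0]), float(popt[1])
        self.dH_err_, self.dS_err_ = float(errs[0]), float(errs[1])
        if self.fix_dCp is not None:
            self.dCp_, self.dCp_err_ = float(self.fix_dCp), 0.0
        else:
            self.dCp_, self.dCp_err_ = float(popt[2]), float(errs[2])
        self.covariance_ = pcov
        self.residuals_ = resid
        self.residual_rms_ = float(np.sqrt(np.mean(resid**2)))
        # ΔCp‡ rides on curvature: a narrow span or an error swamping the
        # estimate means the data cannot constrain it
        self.dCp_identifiable_ = bool(
            span >= 10.0 and np.isfinite(self.dCp_err_)
        )
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        return eyring_ln_rate(_xcol(X), self.dH_, self.dS_, self.dCp_, self.T0)

    def result(self) -> EyringFit:
        return EyringFit(
            dH=self.dH_, dS=self.dS_, dCp=self.dCp_, T0=self.T0,
            dH_err=self.dH_err_, dS_err=self.dS_err_, dCp_err=self.dCp_err_,
            dCp_identifiable=self.dCp_identifiable_,
            residual_rms=self.residual_rms_,
        )


def fit_arrhenius(series: EyringSeries) -> EyringFit:
    """Linear Arrhenius analysis of a temperature series."""
    est = ArrheniusAnalysis().fit(series.temperature, series.ln_rate)
    return est.result()


def fit_eyring_cp(series: EyringSeries, T0: float = 298.0,
                  fix_dCp: Optional[float] = None) -> EyringFit:
    """Eyring fit with activation heat capacity around reference T0."""
    est = EyringCp(T0=T0, fix_dCp=fix_dCp).fit(series.temperature, series.ln_rate)
    out = est.result()
    # carry the linear diagnostics alongside
    if series.temperature.size >= 4:
        lin = fit_arrhenius(series)
        out.dE_arrhenius = lin.dE_arrhenius
        out.prefactor_ln = lin.prefactor_ln
        out.curvature_stat = lin.curvature_stat
        out.curvature_p = lin.curvature_p
    return out
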