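"""Shared nonlinear least-squares machinery.

Thin wrapper around :func:`scipy.optimize.least_squares` that returns the
parameter covariance estimated from the Jacobian at the solution
(``cov = (JᵀJ)⁻¹ · SSR/(n−p)``) and converts optimizer failure into
:class:`~protstab.exceptions.FitConvergenceError` carrying the last iterate.
"""

from __future__ import annotations

from typing import Callable, Optional, Sequence

import numpy as np
from scipy.optimize import least_squares

from .exceptions import FitConvergenceError


def fit_least_squares(
    model: Callable[..., np.ndarray],
    x: np.ndarray,
    y: np.ndarray,
    p0: Sequence[float],
    bounds: Optional[tuple] = None,
    weights: Optional[np.ndarray] = None,
):
    """Fit ``y ≈ model(x, *params)`` by least squares.

    Returns
    -------
    popt : ndarray
        Parameter estimates.
    pcov : ndarray
        Covariance matrix (NaN-filled if the Jacobian is rank-deficient).
    residuals : ndarray
        ``y - model(x, *popt)`` (unweighted).
    """
    p0 = np.asarray(p0, dtype=float)

    def resid(p):
        r = y - model(x, *p)
        if weights is not None:
            r = r * weights
        return r

    kwargs = {}
    if bounds is not None:
        kwargs["bounds"] = bounds
    res = least_squares(resid, p0, **kwargs)
    if not res.success:
        raise FitConvergenceError(
            f"least-squares fit did not converge: {res.message}", last_iterate=res.x
        )
    n, p = res.fun.size, p0.size
    dof = max(n - p, 1)
    s2 = 2.0 * res.cost / dof
    jtj = res.jac.T @ res.jac
    try:
        pcov = np.linalg.inv(jtj) * s2
    except np.linalg.LinAlgError:
        pcov = np.full((p, p), np.nan)
    residuals = y - model(x, *res.x)
    return res.x, pcov, residuals


def runs_test_p(resid: np.ndarray) -> float:
    """Two-sided Wald–Wolfowitz runs-test p-value on residual signs.

    Used as a systematic-curvature screen: structured residuals produce few
    runs and a small p-value.
    """
    from scipy import stats

    resid = np.asarray(resid, dtype=float)
    s = np.sign(resid[resid != 0])
    n1 = int(np.sum(s > 0))
    n2 = int(np.sum(s < 0))
    if n1 == 0 or n2 == 0:
        return 1.0
    runs = 1 + int(np.sum(s[1:] != s[:-1]))
    n = n1 + n2
    mean = 2.0 * n1 * n2 / n + 1.0
    var = 2.0 * n1 * n2 * (2.0 * n1 * n2 - n) / (n**2 * (n - 1.0))
    if var <= 0:
        return 1.0
    z = (runs - mean) / np.sqrt(var)
    return float(2.0 * stats.norm.sf(abs(z)))


def param_errors(pcov: np.ndarray) -> np.ndarray:
    """1-sigma parameter uncertainties from a covariance matrix."""
    d = np.diag(pcov).copy()
    d[d < 0] = np.nan
    return np.sqrt(d)
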