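"""Synthetic datasets with known ground truth for every pipeline stage.

Each generator emulates one experimental design from the study conditions —
equilibrium denaturation isotherms, CD thermal melts, stopped-flow traces
(including the sequential U→I→N scheme that produces a refolding lag),
temperature series of rates with activation heat-capacity curvature, and
scattering curves of globular bodies — so every fitter in the package can be
validated by parameter recovery without any external data.

Noise is additive Gaussian on the observed channel (signal, ln k, or, for
scattering, relative to I(q) since intensities span decades). Identical seed
and parameters give bit-identical output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np

from .constants import KB_OVER_H  # noqa: F401  (re-exported convention)
from .datatypes import (
    AtomicModel,
    DenaturationIsotherm,
    EyringSeries,
    KineticTrace,
    ScatteringCurve,
    ThermalCurve,
)
from .equilibrium import fraction_denatured
from .kinetics import eyring_ln_rate, exponential_signal
from .saxs import debye_intensity, ellipsoid_intensity, prolate_semi_axes, sphere_intensity

_KINDS = ("isotherm", "melt", "trace", "eyring_series", "saxs_body")


@dataclass(frozen=True)
class GroundTruth:
    """Generator configuration: known parameters, noise level and seed.

    ``params`` must contain every parameter the corresponding fitter
    estimates, in the package's canonical units (kcal/mol, kcal/(mol·M),
    K or °C as labeled, s⁻¹, Å).
    """

    kind: str
    params: Mapping
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.kind not in _KINDS:
            raise ValueError(f"kind must be one of {_KINDS}, got {self.kind!r}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def _rng(truth: GroundTruth, seed: Optional[int]) -> np.random.Generator:
    return np.random.default_rng(truth.seed if seed is None else seed)


# ---------------------------------------------------------------------------
# Equilibrium isotherms
# ---------------------------------------------------------------------------

def gen_isotherm(truth: GroundTruth, seed: Optional[int] = None) -> DenaturationIsotherm:
    """Two-state LEM denaturation isotherm with Gaussian signal noise.

    Required params: dG0 (kcal/mol), m (kcal/(mol·M), > 0), signal_native,
    signal_denatured, denaturant_grid (M, non-negative increasing);
    optional temperature (K, default 298.15).
    """
    p = truth.params
    grid = np.asarray(p["denaturant_grid"], dtype=float)
    if np.any(np.diff(grid) <= 0):
        raise ValueError("denaturant grid must be strictly increasing")
    if np.any(grid < 0):
        raise ValueError("denaturant grid must be non-negative")
    if p["m"] <= 0:
        raise ValueError("m must be positive for a cooperative transition")
    temperature = p.get("temperature", 298.15)
    fd = fraction_denatured(p["dG0"], p["m"], grid, temperature)
    signal = p["signal_native"] * (1.0 - fd) + p["signal_denatured"] * fd
    if truth.noise_sd > 0:
        signal = signal + _rng(truth, seed).normal(0.0, truth.noise_sd, grid.size)
    return DenaturationIsotherm(
        denaturant=grid, signal=signal, temperature=temperature,
        label=p.get("label", "synthetic isotherm"),
    )


# ---------------------------------------------------------------------------
# Thermal melts
# ---------------------------------------------------------------------------

def gen_melt(truth: GroundTruth, seed: Optional[int] = None) -> ThermalCurve:
    """Four-parameter logistic thermal melt; inflection at Tm (°C).

    Required params: tm (°C), amplitude, slope (°C), baseline,
    temperature_grid (°C, increasing). A Tm outside the grid is allowed but
    warned about, since the fit will then extrapolate.
    """
    p = truth.params
    grid = np.asarray(p["temperature_grid"], dtype=float)
    tm = p["tm"]
    if not (grid[0] <= tm <= grid[-1]):
        warnings.warn("Tm lies outside the temperature grid", stacklevel=2)
    from scipy.special import expit

    y = p["baseline"] + p["amplitude"] * expit((grid - tm) / p["slope"])
    if truth.noise_sd > 0:
        y = y + _rng(truth, seed).normal(0.0, truth.noise_sd, grid.size)
    return ThermalCurve(temperature_c=grid, ellipticity=y,
                        label=p.get("label", "synthetic melt"))


# ---------------------------------------------------------------------------
# Kinetic traces
# ---------------------------------------------------------------------------

def sequential_uin_populations(t, k_ui: float, k_in: float):
    """Populations (U, I, N) of the irreversible scheme U→I→N.

    Closed-form solution of the linear ODE system with U(0)=1. The
    degenerate case k_UI = k_IN uses its analytic limit
    N(t) = 1 − (1 + k t)·e^(−k t).
    """
    if k_ui <= 0 or k_in <= 0:
        raise ValueError("rates must be positive")
    t = np.asarray(t, dtype=float)
    u = np.exp(-k_ui * t)
    if np.isclose(k_ui, k_in, rtol=1e-10):
        i = k_ui * t * np.exp(-k_ui * t)
    else:
        i = k_ui / (k_in - k_ui) * (np.exp(-k_ui * t) - np.exp(-k_in * t))
    n = 1.0 - u - i
    return u, i, n


def gen_trace(truth: GroundTruth, seed: Optional[int] = None) -> KineticTrace:
    """Stopped-flow trace, single-exponential or sequential U→I→N.

    ``scheme='single_exp'`` needs rate (s⁻¹), amplitude, offset and t_grid;
    the trace follows F(t) = F0 + Amp·(exp(−k t) − 1). ``scheme=
    'sequential_UIN'`` needs k_UI, k_IN and per-species fluorescence
    coefficients (signal_unfolded, signal_intermediate, signal_native); a
    lag appears when the second step carries the signal change.
    """
    p = truth.params
    scheme = p.get("scheme", "single_exp")
    t = np.asarray(p["t_grid"], dtype=float)
    if scheme == "single_exp":
        if p["rate"] <= 0:
            raise ValueError("rate must be positive")
        y = exponential_signal(t, p.get("offset", 1.0), p["amplitude"], p["rate"])
    elif scheme == "sequential_UIN":
        u, i, n = sequential_uin_populations(t, p["k_UI"], p["k_IN"])
        y = (
            p.get("offset", 0.0)
            + p.get("signal_unfolded", 0.0) * u
            + p.get("signal_intermediate", 0.0) * i
            + p.get("signal_native", 1.0) * n
        )
    else:
        raise ValueError(f"unknown kinetic scheme {scheme!r}")
    if truth.noise_sd > 0:
        y = y + _rng(truth, seed).normal(0.0, truth.noise_sd, t.size)
    return KineticTrace(
        time=t, signal=y,
        denaturant=p.get("denaturant", 0.0),
        temperature=p.get("temperature", 298.15),
        direction=p.get("direction", "unfolding"),
    )


# ---------------------------------------------------------------------------
# Temperature series
# ---------------------------------------------------------------------------

def gen_eyring_series(truth: GroundTruth, seed: Optional[int] = None) -> EyringSeries:
    """ln k vs T series from the transition-state model with ΔCp‡ curvature.

    Required params: dH (kcal/mol), dS (kcal/(mol·K)), dCp (kcal/(mol·K)),
    T0 (K) and temperature_grid (K, all positive). Gaussian noise of sd
    ``noise_sd`` is added to ln k.
    """
    p = truth.params
    t = np.asarray(p["temperature_grid"], dtype=float)
    if np.any(t <= 0):
        raise ValueError("temperatures must be positive (Kelvin)")
    lnk = eyring_ln_rate(t, p["dH"], p["dS"], p["dCp"], p.get("T0", 298.0))
    if truth.noise_sd > 0:
        lnk = lnk + _rng(truth, seed).normal(0.0, truth.noise_sd, t.size)
    return EyringSeries(temperature=t, ln_rate=lnk,
                        label=p.get("label", "synthetic rate series"))


# ---------------------------------------------------------------------------
# Scattering bodies
# ---------------------------------------------------------------------------

def ellipsoid_bead_model(a: float, c: float, spacing: float = 4.0,
                         label: str = "ellipsoid beads") -> AtomicModel:
    """Uniform bead fill of a prolate ellipsoid (semi-axes a, a, c).

    Beads sit on a cubic grid of the given spacing inside the body, with the
    two poles (0, 0, ±c) appended so the maximum inter-bead distance equals
    the geometric maximum dimension 2c exactly.
    """
    if a <= 0 or c <= 0:
        raise ValueError("semi-axes must be positive")
    ax = np.arange(-a, a + spacing / 2, spacing)
    az = np.arange(-c, c + spacing / 2, spacing)
    xx, yy, zz = np.meshgrid(ax, ax, az, indexing="ij")
    inside = (xx / a) ** 2 + (yy / a) ** 2 + (zz / c) ** 2 <= 1.0
    coords = np.column_stack([xx[inside], yy[inside], zz[inside]])
    poles = np.array([[0.0, 0.0, c], [0.0, 0.0, -c]])
    coords = np.vstack([coords, poles])
    return AtomicModel(coordinates=coords, weights=np.ones(len(coords)), label=label)


def gen_saxs_body(truth: GroundTruth, seed: Optional[int] = None) -> ScatteringCurve:
    """Scattering curve of a globular body with a per-point error column.

    ``body`` selects the model: ``sphere`` (exact form factor; params:
    radius), ``prolate_ellipsoid`` (orientation-averaged quadrature; params:
    a and c, or rg and dmax), or ``bead_model`` (Debye sum; params: model, an
    :class:`AtomicModel`, or a/c/spacing for an ellipsoid fill).

    The σ column is ``sigma_frac``·I(q) (default 2%) plus a small additive
    floor. ``noise_sd`` is interpreted as *relative* noise — Gaussian with
    sd = noise_sd·I(q) — because scattering intensities span decades.
    """
    p = truth.params
    body = p["body"]
    q = np.asarray(p["q_grid"], dtype=float)
    i0 = p.get("I0", 1.0)
    if body == "sphere":
        intensity = sphere_intensity(q, p["radius"], i0)
    elif body == "prolate_ellipsoid":
        if "a" in p and "c" in p:
            a, c = p["a"], p["c"]
        else:
            a, c = prolate_semi_axes(p["rg"], p["dmax"])
        intensity = ellipsoid_intensity(q, a, c, i0)
    elif body == "bead_model":
        model = p.get("model")
        if model is None:
            model = ellipsoid_bead_model(p["a"], p["c"], p.get("spacing", 4.0))
        curve = debye_intensity(model, q, hist_bin=p.get("hist_bin"))
        intensity = curve.intensity * (i0 / float(model.weights.sum() ** 2))
    else:
        raise ValueError(f"unknown body {body!r}")
    sigma_frac = p.get("sigma_frac", 0.02)
    sigma = sigma_frac * np.abs(intensity) + p.get("sigma_floor", 1e-6 * i0)
    if truth.noise_sd > 0:
        intensity = intensity + _rng(truth, seed).normal(
            0.0, truth.noise_sd * np.abs(intensity)
        )
    return ScatteringCurve(q=q, intensity=intensity, sigma=sigma,
                           concentration=p.get("concentration"),
                           label=p.get("label", f"synthetic {body}"))
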