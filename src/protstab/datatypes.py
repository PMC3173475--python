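"""Data containers and fit-result records.

Input containers are lightweight dataclasses around validated numpy arrays;
result records carry the fitted parameters, their 1-sigma uncertainties and
enough bookkeeping (covariance, residual norms, flags) to serialize a full
report. All temperatures are stored in Kelvin internally except where a type
is explicitly a Celsius-gridded thermal melt; energies are kcal/mol, m-values
kcal/(mol·M), rates s^-1, lengths Å.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np


def _as_float_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


def _require_increasing(arr: np.ndarray, name: str, strict: bool = True) -> None:
    d = np.diff(arr)
    if strict and np.any(d <= 0):
        raise ValueError(f"{name} must be strictly increasing")
    if not strict and np.any(d < 0):
        raise ValueError(f"{name} must be non-decreasing")


# ---------------------------------------------------------------------------
# Input containers
# ---------------------------------------------------------------------------

@dataclass
class Spectrum:
    """Fluorescence emission spectrum: intensity vs emission wavelength (nm)."""

    wavelength: np.ndarray
    intensity: np.ndarray
    excitation_nm: Optional[float] = None
    temperature: Optional[float] = None  # K
    label: str = ""

    def __post_init__(self):
        self.wavelength = _as_float_array(self.wavelength, "wavelength")
        self.intensity = _as_float_array(self.intensity, "intensity")
        if self.wavelength.size != self.intensity.size:
            raise ValueError("wavelength and intensity must have equal length")
        if self.wavelength.size < 2:
            raise ValueError("a spectrum needs at least two points")
        _require_increasing(self.wavelength, "wavelength")
        if np.any(self.intensity < 0):
            raise ValueError("negative intensities are not physical")


@dataclass
class DenaturationIsotherm:
    """Equilibrium signal vs denaturant concentration (M), at fixed T (K)."""

    denaturant: np.ndarray
    signal: np.ndarray
    temperature: float = 298.15
    label: str = ""

    def __post_init__(self):
        self.denaturant = _as_float_array(self.denaturant, "denaturant")
        self.signal = _as_float_array(self.signal, "signal")
        if self.denaturant.size != self.signal.size:
            raise ValueError("denaturant and signal must have equal length")
        if self.denaturant.size < 6:
            raise ValueError("an isotherm needs at least 6 points")
        if np.any(self.denaturant < 0):
            raise ValueError("denaturant concentrations must be non-negative")
        _require_increasing(self.denaturant, "denaturant")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive (Kelvin)")


@dataclass
class ThermalCurve:
    """CD thermal melt: ellipticity vs temperature (°C grid, as recorded)."""

    temperature_c: np.ndarray
    ellipticity: np.ndarray
    label: str = ""

    def __post_init__(self):
        self.temperature_c = _as_float_array(self.temperature_c, "temperature_c")
        self.ellipticity = _as_float_array(self.ellipticity, "ellipticity")
        if self.temperature_c.size != self.ellipticity.size:
            raise ValueError("temperature and ellipticity must have equal length")
        if self.temperature_c.size < 8:
            raise ValueError("a melt needs at least 8 points")
        _require_increasing(self.temperature_c, "temperature_c")


@dataclass
class KineticTrace:
    """Stopped-flow trace: fluorescence signal vs time (s)."""

    time: np.ndarray
    signal: np.ndarray
    denaturant: float = 0.0
    temperature: float = 298.15  # K
    direction: str = "unfolding"

    def __post_init__(self):
        self.time = _as_float_array(self.time, "time")
        self.signal = _as_float_array(self.signal, "signal")
        if self.time.size != self.signal.size:
            raise ValueError("time and signal must have equal length")
        if self.time.size < 20:
            raise ValueError("a kinetic trace needs at least 20 points")
        if self.time[0] < 0:
            raise ValueError("time must start at or after zero")
        _require_increasing(self.time, "time")
        if self.direction not in ("unfolding", "refolding"):
            raise ValueError("direction must be 'unfolding' or 'refolding'")


@dataclass
class EyringSeries:
    """ln(rate) vs absolute temperature, for activation analysis."""

    temperature: np.ndarray  # K
    ln_rate: np.ndarray
    label: str = ""

    def __post_init__(self):
        self.temperature = _as_float_array(self.temperature, "temperature")
        self.ln_rate = _as_float_array(self.ln_rate, "ln_rate")
        if self.temperature.size != self.ln_rate.size:
            raise ValueError("temperature and ln_rate must have equal length")
        if np.any(self.temperature <= 0):
            raise ValueError("temperatures must be positive (Kelvin)")
        _require_increasing(self.temperature, "temperature")


@dataclass
class ScatteringCurve:
    """SAXS curve: I(q) with optional per-point errors, q in Å^-1.

    q follows the 4π·sin(θ)/λ convention. ``concentration`` (mg/mL) is
    carried for I(0)/C molecular-weight estimation.
    """

    q: np.ndarray
    intensity: np.ndarray
    sigma: Optional[np.ndarray] = None
    concentration: Optional[float] = None
    label: str = ""

    def __post_init__(self):
        self.q = _as_float_array(self.q, "q")
        self.intensity = _as_float_array(self.intensity, "intensity")
        if self.q.size != self.intensity.size:
            raise ValueError("q and intensity must have equal length")
        if np.any(self.q <= 0):
            raise ValueError("q must be positive")
        _require_increasing(self.q, "q")
        if self.sigma is not None:
            self.sigma = _as_float_array(self.sigma, "sigma")
            if self.sigma.size != self.q.size:
                raise ValueError("sigma must match q in length")
            if np.any(self.sigma <= 0):
                raise ValueError("sigma must be positive where present")
        if self.concentration is not None and self.concentration <= 0:
            raise ValueError("concentration must be positive")


@dataclass
class AtomicModel:
    """Point-scatterer model: coordinates (Å) with per-site weights."""

    coordinates: np.ndarray  # (N, 3)
    weights: np.ndarray  # (N,)
    label: str = ""

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise ValueError("coordinates must have shape (N, 3)")
        if self.coordinates.shape[0] < 1:
            raise ValueError("at least one site is required")
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("coordinates must be finite")
        self.weights = _as_float_array(self.weights, "weights")
        if self.weights.size != self.coordinates.shape[0]:
            raise ValueError("weights must match coordinates in length")

    def radius_of_gyration(self) -> float:
        """Weight-weighted coordinate radius of gyration (Å)."""
        w = self.weights / self.weights.sum()
        center = w @ self.coordinates
        d2 = np.sum((self.coordinates - center) ** 2, axis=1)
        return float(np.sqrt(w @ d2))

    def max_distance(self) -> float:
        """Maximum inter-site distance (Å)."""
        from scipy.spatial.distance import pdist

        if self.coordinates.shape[0] == 1:
            return 0.0
        return float(pdist(self.coordinates).max())


# ---------------------------------------------------------------------------
# Result records
# ---------------------------------------------------------------------------

class _Record:
    """Mixin: JSON-friendly dict serialization for result dataclasses."""

    def to_dict(self) -> dict:
        def clean(v):
            if isinstance(v, np.ndarray):
                return v.tolist()
            if isinstance(v, (np.floating, np.integer)):
                return v.item()
            if isinstance(v, dict):
                return {k: clean(x) for k, x in v.items()}
            if isinstance(v, (list, tuple)):
                return [clean(x) for x in v]
            return v

        return {k: clean(v) for k, v in asdict(self).items()}


@dataclass
class TwoStateFit(_Record):
    """Two-state linear-extrapolation fit of a denaturation isotherm."""

    dG0: float  # kcal/mol
    m_value: float  # kcal/(mol·M)
    signal_native: float
    signal_denatured: float
    dG0_err: float
    m_err: float
    signal_native_err: float
    signal_denatured_err: float
    covariance: np.ndarray  # 4x4 (or 6x6 with linear baselines)
    midpoint: float  # M, = dG0/m
    temperature: float  # K
    residual_rms: float
    n_points: int
    baseline_slopes: Optional[tuple] = None  # (native, denatured) if floated
    plateau_warning: bool = False


@dataclass
class AsaComparison(_Record):
    """m-value comparison between apo and ligand-bound fits.

    The sign of the m-value change tracks the sign of the binding-induced
    change in unfolding ΔASA, under the assumption of a common unfolded state.
    """

    m_apo: float
    m_holo: float
    delta_m: float
    delta_m_err: float
    sign_ddASA: str  # positive | negative | indeterminate


@dataclass
class ThermalFit(_Record):
    """Four-parameter logistic fit of a thermal melt."""

    tm: float  # °C, inflection
    amplitude: float
    slope: float  # transition width parameter, °C
    baseline: float
    tm_err: float
    covariance: np.ndarray
    residual_rms: float


@dataclass
class ExponentialFit(_Record):
    """Single-exponential fit F(t) = F0 + Amp·(exp(-k t) - 1)."""

    rate: float  # s^-1
    amplitude: float
    offset: float
    rate_err: float
    residual_rms: float
    residuals: np.ndarray
    rate_at_bound: bool = False


@dataclass
class LagResult(_Record):
    """Lag phase of a refolding trace, by maximal-slope tangent extrapolation."""

    lag_duration: float  # s
    line_slope: float
    line_intercept: float
    no_lag_flag: bool = False


@dataclass
class ChevronArm(_Record):
    """One linear arm of a chevron plot (ln k vs [denaturant])."""

    direction: str
    slope: float  # d ln k / d[den], M^-1
    intercept: float  # ln k at 0 M
    slope_err: float
    intercept_err: float
    m_ddagger: float  # |slope|·R·T, kcal/(mol·M)
    used_mask: np.ndarray  # points surviving the linearity screen
    converged: bool = True


@dataclass
class ChevronFit(_Record):
    """Chevron analysis: both arms, 0 M extrapolations, equilibrium link."""

    denaturant: np.ndarray
    ln_rate: np.ndarray
    direction: list
    unfolding_arm: Optional[ChevronArm]
    refolding_arm: Optional[ChevronArm]
    kNU0: Optional[float]  # unfolding rate at 0 M, s^-1
    kUN0: Optional[float]  # refolding rate at 0 M, s^-1
    keq0: Optional[float]  # kNU0/kUN0
    dG_kinetic: Optional[float]  # -RT ln keq0, kcal/mol
    temperature: float
    rollover_flag: bool = False
    rollover_onset: Optional[float] = None


@dataclass
class EyringFit(_Record):
    """Activation parameters from temperature dependence of a rate."""

    dH: float  # kcal/mol at T0
    dS: float  # kcal/(mol·K) at T0
    dCp: float  # kcal/(mol·K)
    T0: float  # K
    dH_err: float = np.nan
    dS_err: float = np.nan
    dCp_err: float = np.nan
    dE_arrhenius: float = np.nan  # kcal/mol, linear model
    prefactor_ln: float = np.nan  # intercept of the linear model
    curvature_stat: float = np.nan  # t-statistic of quadratic term in 1/RT
    curvature_p: float = np.nan
    dCp_identifiable: bool = True
    residual_rms: float = np.nan


@dataclass
class GuinierFit(_Record):
    """Guinier analysis: ln I vs q² on the qRg ≤ 1.3 window."""

    Rg: float  # Å
    I0: float
    Rg_err: float
    I0_err: float
    q_range_used: tuple
    qmax_rg: float
    r2: float
    n_points: int


@dataclass
class PairDistribution(_Record):
    """Real-space pair-distance distribution p(r) from regularized IFT."""

    r: np.ndarray  # Å
    p: np.ndarray
    Dmax: float  # Å
    Rg_real: float  # Å, from p(r) moments
    I0: float  # 4π ∫ p dr
    alpha: float  # smoothness weight used
    chi2: float  # reduced χ² of the reciprocal-space fit
    negative_lobe_flag: bool = False


@dataclass
class Discrepancy(_Record):
    """Error-weighted reduced χ² between data and a scalable model curve."""

    chi2: float
    scale: float
    n_points: int
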