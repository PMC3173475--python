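"""File readers and writers.

Formats are the plain-text dialects common to spectroscopy and scattering
benches: two-column CSV for spectra, isotherms, melts and traces (header
optional, header names matched case- and whitespace-insensitively);
whitespace-separated ``q I [σ]`` .dat files with ``#`` comments for SAXS;
PDB for coordinates. Writers emit exactly the dialects the readers consume,
so generated fixtures exercise the full round trip. Malformed lines are
reported with their line numbers.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .datatypes import (
    AtomicModel,
    DenaturationIsotherm,
    KineticTrace,
    PairDistribution,
    ScatteringCurve,
    Spectrum,
    ThermalCurve,
)
from .exceptions import FormatError

PathLike = Union[str, Path]

# effective atomic numbers for Debye weights (q-independent approximation)
_ATOMIC_NUMBER = {
    "H": 1, "C": 6, "N": 7, "O": 8, "P": 15, "S": 16,
    "NA": 11, "MG": 12, "CL": 17, "K": 19, "CA": 20,
    "MN": 25, "FE": 26, "CU": 29, "ZN": 30, "SE": 34,
}


# ---------------------------------------------------------------------------
# CSV tables
# ---------------------------------------------------------------------------

def _read_table(path: PathLike, expected: tuple[str, ...]) -> pd.DataFrame:
    """Read a CSV with optional header; normalize names to the expected ones."""
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    tokens = [t.strip() for t in first.split(",")]

    def is_number(tok: str) -> bool:
        try:
            float(tok)
            return True
        except ValueError:
            return False

    has_header = not all(is_number(t) for t in tokens if t)
    if has_header:
        df = pd.read_csv(path, skipinitialspace=True)
        df.columns = [str(c).strip().lower() for c in df.columns]
        missing = [c for c in expected if c not in df.columns]
        if missing:
            raise FormatError(
                f"{path}: missing column(s) {missing}; found {list(df.columns)}"
            )
        return df
    df = pd.read_csv(path, header=None, skipinitialspace=True)
    if df.shape[1] < len(expected):
        raise FormatError(
            f"{path}: expected {len(expected)} columns, found {df.shape[1]}"
        )
    df = df.iloc[:, : len(expected)]
    df.columns = list(expected)
    return df


def read_spectrum_csv(path: PathLike, label: Optional[str] = None):
    """Read spectra from CSV (wavelength_nm, intensity[, label]).

    A file without a label column yields a single :class:`Spectrum`; with a
    label column it yields a dict keyed by label, unless ``label`` selects
    one.
    """
    df = _read_table(path, ("wavelength_nm", "intensity"))
    if "label" in df.columns:
        groups = {
            str(k): Spectrum(wavelength=g["wavelength_nm"].to_numpy(),
                             intensity=g["intensity"].to_numpy(), label=str(k))
            for k, g in df.groupby("label", sort=False)
        }
        if label is not None:
            return groups[label]
        return groups
    return Spectrum(wavelength=df["wavelength_nm"].to_numpy(),
                    intensity=df["intensity"].to_numpy())


def read_isotherm_csv(path: PathLike, temperature: float = 298.15,
                      label: str = "") -> DenaturationIsotherm:
    """Read an equilibrium isotherm from CSV (denaturant_m, signal)."""
    df = _read_table(path, ("denaturant_m", "signal"))
    return DenaturationIsotherm(
        denaturant=df["denaturant_m"].to_numpy(),
        signal=df["signal"].to_numpy(),
        temperature=temperature, label=label,
    )


def read_melt_csv(path: PathLike, label: str = "") -> ThermalCurve:
    """Read a thermal melt from CSV (temperature_c, ellipticity)."""
    df = _read_table(path, ("temperature_c", "ellipticity"))
    return ThermalCurve(temperature_c=df["temperature_c"].to_numpy(),
                        ellipticity=df["ellipticity"].to_numpy(), label=label)


def read_trace_csv(path: PathLike, denaturant: float = 0.0,
                   temperature: float = 298.15,
                   direction: str = "unfolding") -> KineticTrace:
    """Read a stopped-flow trace from CSV (time_s, signal)."""
    df = _read_table(path, ("time_s", "signal"))
    return KineticTrace(time=df["time_s"].to_numpy(),
                        signal=df["signal"].to_numpy(),
                        denaturant=denaturant, temperature=temperature,
                        direction=direction)


def read_rate_series_csv(path: PathLike, label: str = ""):
    """Read a temperature series of rates from CSV (temperature_k, ln_k)."""
    from .datatypes import EyringSeries

    df = _read_table(path, ("temperature_k", "ln_k"))
    return EyringSeries(temperature=df["temperature_k"].to_numpy(),
                        ln_rate=df["ln_k"].to_numpy(), label=label)


def write_rate_series_csv(series, path: PathLike) -> None:
    pd.DataFrame({"temperature_K": series.temperature,
                  "ln_k": series.ln_rate}).to_csv(path, index=False)


def write_isotherm_csv(iso: DenaturationIsotherm, path: PathLike) -> None:
    pd.DataFrame({"denaturant_M": iso.denaturant, "signal": iso.signal}).to_csv(
        path, index=False
    )


def write_melt_csv(melt: ThermalCurve, path: PathLike) -> None:
    pd.DataFrame({"temperature_C": melt.temperature_c,
                  "ellipticity": melt.ellipticity}).to_csv(path, index=False)


def write_trace_csv(trace: KineticTrace, path: PathLike) -> None:
    pd.DataFrame({"time_s": trace.time, "signal": trace.signal}).to_csv(
        path, index=False
    )


def write_spectrum_csv(spectrum: Spectrum, path: PathLike) -> None:
    pd.DataFrame({"wavelength_nm": spectrum.wavelength,
                  "intensity": spectrum.intensity}).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# SAXS .dat
# ---------------------------------------------------------------------------

def read_saxs_dat(path: PathLike, q_unit: str = "1/A",
                  concentration: Optional[float] = None,
                  label: str = "") -> ScatteringCurve:
    """Read a whitespace-separated (q, I[, σ]) file with ``#`` comments.

    ``q_unit='1/nm'`` converts the momentum-transfer axis to Å⁻¹ on read.
    """
    if q_unit not in ("1/A", "1/nm"):
        raise ValueError("q_unit must be '1/A' or '1/nm'")
    rows = []
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            body = line.split("#", 1)[0].strip()
            if not body:
                continue
            parts = body.split()
            if len(parts) not in (2, 3):
                raise FormatError(
                    f"{path}: line {lineno}: expected 2 or 3 columns, got {len(parts)}"
                )
            try:
                vals = [float(x) for x in parts]
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: non-numeric value") from exc
            if len(vals) == 2:
                vals.append(math.nan)
            rows.append(vals)
    if not rows:
        raise FormatError(f"{path}: no data lines")
    arr = np.asarray(rows)
    q, intensity, sigma = arr[:, 0], arr[:, 1], arr[:, 2]
    if np.all(np.isnan(sigma)):
        sigma = None
    elif np.any(np.isnan(sigma)):
        raise FormatError(f"{path}: σ column present on some lines only")
    if q_unit == "1/nm":
        q = q / 10.0
    return ScatteringCurve(q=q, intensity=intensity, sigma=sigma,
                           concentration=concentration, label=label)


def write_saxs_dat(curve: ScatteringCurve, path: PathLike,
                   header: str = "q(1/A) I sigma") -> None:
    """Write a curve in the same (q, I[, σ]) dialect the reader consumes."""
    with open(path, "w") as fh:
        fh.write(f"# {header}\n")
        for i in range(curve.q.size):
            if curve.sigma is not None:
                fh.write(f"{curve.q[i]:.12e} {curve.intensity[i]:.12e} "
                         f"{curve.sigma[i]:.12e}\n")
            else:
                fh.write(f"{curve.q[i]:.12e} {curve.intensity[i]:.12e}\n")


def write_pr(pr: PairDistribution, path: PathLike) -> None:
    """Write p(r) as two-column text (r_A, p)."""
    with open(path, "w") as fh:
        fh.write("# r(A) p(r)\n")
        for r, p in zip(pr.r, pr.p):
            fh.write(f"{r:.6e} {p:.6e}\n")


# ---------------------------------------------------------------------------
# PDB coordinates
# ---------------------------------------------------------------------------

def read_pdb(path: PathLike, heavy_only: bool = True,
             label: Optional[str] = None) -> AtomicModel:
    """Read ATOM/HETATM sites of the first model into an :class:`AtomicModel`.

    Alternate locations are resolved by highest occupancy; weights are
    q-independent effective atomic numbers. Hydrogens are dropped unless
    ``heavy_only=False``.
    """
    import biotite.structure.io.pdb as pdb_io

    path = Path(path)
    # pre-scan for truncated coordinate records so errors name the line
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(("ATOM", "HETATM")) and len(line.rstrip("\n")) < 54:
                raise FormatError(
                    f"{path}: line {lineno}: truncated coordinate record"
                )
    pdb_file = pdb_io.PDBFile.read(str(path))
    atoms = pdb_file.get_structure(model=1, altloc="occupancy")
    elements = np.char.upper(atoms.element.astype(str))
    if heavy_only:
        keep = elements != "H"
        atoms = atoms[keep]
        elements = elements[keep]
    weights = np.array([_ATOMIC_NUMBER.get(e, 6) for e in elements], dtype=float)
    return AtomicModel(coordinates=atoms.coord, weights=weights,
                       label=label or path.stem)


# ---------------------------------------------------------------------------
# JSON reports
# ---------------------------------------------------------------------------

def write_report(report: dict, path: PathLike) -> None:
    """Deterministic JSON report: sorted keys, fixed float formatting."""
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if hasattr(o, "to_dict"):
            return o.to_dict()
        raise TypeError(f"unserializable object of type {type(o)}")

    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=default,
                  allow_nan=True)
        fh.write("\n")
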