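"""Config-driven pipeline: validated run configuration, stage execution,
deterministic JSON reports and a publication-style parameter summary.

A run configuration names input files, an output directory, a seed and an
ordered list of stages. Stages execute in dependency order (reductions
before fits, fits before comparisons); each writes one JSON report. A stage
failure halts the run, leaves earlier reports in place, and records a
machine-readable error. All numeric outputs carry units and 1-sigma errors
where the underlying fit provides them; wall-clock metadata is segregated
into a sidecar so reports are byte-identical for identical config and seed.
"""

from __future__ import annotations

import logging
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from . import equilibrium, io, kinetics, saxs, spectra
from .exceptions import ProtstabError

logger = logging.getLogger("protstab")

#: execution rank — lower runs first (reductions feed fits feed comparisons)
_STAGE_RANK = {
    "simulate": 0,
    "spectra": 1,
    "equilibrium": 2,
    "melt": 2,
    "kinetics": 2,
    "saxs_reduce": 2,
    "chevron": 3,
    "eyring": 3,
    "saxs_model": 3,
    "compare": 4,
}

_CONFIG_KEYS = {"stages", "inputs", "outdir", "seed", "log_level"}
_STAGE_KEYS = {"name", "params"}


@dataclass
class RunConfig:
    """Validated pipeline configuration."""

    stages: list
    outdir: str
    inputs: dict = field(default_factory=dict)
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_dict(cls, raw: dict, base_dir: Optional[Path] = None) -> "RunConfig":
        unknown = set(raw) - _CONFIG_KEYS
        if unknown:
            raise ProtstabError(f"unknown config key(s): {sorted(unknown)}")
        for required in ("stages", "outdir"):
            if required not in raw:
                raise ProtstabError(f"config is missing required key {required!r}")
        stages = []
        for i, st in enumerate(raw["stages"]):
            if not isinstance(st, dict):
                raise ProtstabError(f"stage {i} must be a mapping")
            bad = set(st) - _STAGE_KEYS
            if bad:
                raise ProtstabError(f"stage {i}: unknown key(s) {sorted(bad)}")
            name = st.get("name")
            if name not in _STAGE_RANK:
                raise ProtstabError(
                    f"stage {i}: unknown stage {name!r}; "
                    f"valid: {sorted(_STAGE_RANK)}"
                )
            stages.append({"name": name, "params": dict(st.get("params") or {})})
        inputs = {}
        for key, p in (raw.get("inputs") or {}).items():
            path = Path(p)
            if base_dir is not None and not path.is_absolute():
                path = base_dir / path
            if not path.exists():
                raise ProtstabError(f"input {key!r}: file not found: {path}")
            inputs[key] = path
        return cls(stages=stages, outdir=str(raw["outdir"]), inputs=inputs,
                   seed=int(raw.get("seed", 0)),
                   log_level=str(raw.get("log_level", "INFO")))

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        path = Path(path)
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw, base_dir=path.parent)


def stage_seed(seed: int, stage_name: str) -> int:
    """Fan a single run seed out to stable, independent per-stage seeds."""
    return zlib.crc32(f"{seed}:{stage_name}".encode()) & 0x7FFFFFFF


# ---------------------------------------------------------------------------
# Stage implementations
# ---------------------------------------------------------------------------

def _require(params: dict, key: str, stage: str):
    if key not in params:
        raise ProtstabError(f"stage {stage!r}: missing parameter {key!r}")
    return params[key]


def _stage_simulate(cfg: RunConfig, params: dict, outdir: Path, seed: int) -> dict:
    """Generate demo fixtures (isotherm, melt, rate series, SAXS curve)."""
    from .synthetic import GroundTruth, gen_eyring_series, gen_isotherm, gen_melt, gen_saxs_body

    fx = outdir / "fixtures"
    fx.mkdir(exist_ok=True)
    grid = np.linspace(0.0, 4.5, 30)
    iso = gen_isotherm(GroundTruth("isotherm", {
        "dG0": 3.7, "m": 3.12, "signal_native": 350.0,
        "signal_denatured": 355.0, "denaturant_grid": grid}, noise_sd=0.025,
        seed=seed))
    io.write_isotherm_csv(iso, fx / "isotherm.csv")
    melt = gen_melt(GroundTruth("melt", {
        "tm": 58.0, "amplitude": 1.0, "slope": 2.0, "baseline": -1.0,
        "temperature_grid": np.linspace(25.0, 90.0, 66)}, noise_sd=0.01,
        seed=seed + 1))
    io.write_melt_csv(melt, fx / "melt.csv")
    series = gen_eyring_series(GroundTruth("eyring_series", {
        "dH": 20.0, "dS": 0.071, "dCp": 0.62, "T0": 298.0,
        "temperature_grid": np.linspace(278.0, 303.0, 6)}, noise_sd=0.01,
        seed=seed + 2))
    io.write_rate_series_csv(series, fx / "rates.csv")
    body = gen_saxs_body(GroundTruth("saxs_body", {
        "body": "prolate_ellipsoid", "rg": 23.4, "dmax": 72.0,
        "q_grid": np.linspace(0.008, 0.30, 120)}, seed=seed + 3))
    io.write_saxs_dat(body, fx / "saxs.dat")
    return {"fixtures": sorted(p.name for p in fx.iterdir()),
            "units": {"isotherm": "M, nm", "melt": "degC, mdeg",
                      "rates": "K, ln(1/s)", "saxs": "1/A, a.u."}}


def _stage_spectra(cfg: RunConfig, params: dict, outdir: Path, seed: int) -> dict:
    key = _require(params, "spectrum", "spectra")
    spec = io.read_spectrum_csv(cfg.inputs[key])
    if isinstance(spec, dict):
        out = {}
        for label, s in spec.items():
            out[label] = {
                "center_of_mass_nm": spectra.center_of_spectral_mass(s, "wavelength"),
                "center_of_mass_cm1": spectra.center_of_spectral_mass(s, "wavenumber"),
                "area_au_nm": spectra.spectral_area(s),
            }
        return out
    return {
        "center_of_mass_nm": spectra.center_of_spectral_mass(spec, "wavelength"),
        "center_of_mass_cm1": spectra.center_of_spectral_mass(spec, "wavenumber"),
        "area_au_nm": spectra.spectral_area(spec),
    }


def _stage_equilibrium(cfg: RunConfig, params: dict, outdir: Path, seed: int) -> dict:
    key = _require(params, "isotherm", "equilibrium")
    iso = io.read_isotherm_csv(
        cfg.inputs[key], temperature=params.get("temperature", 298.15)
    )
    fit = equilibrium.fit_two_state(
        iso, linear_baselines=params.get("linear_baselines", False)
    )
    return {"two_state_fit": fit.to_dict(),
            "units": {"dG0": "kcal/mol", "m_value": "kcal/(mol.M)",
                      "midpoint": "M", "temperature": "K"}}


def _stage_melt(cfg: RunConfig, params: dict, outdir: Path, seed: int) -> dict:
    key = _require(params, "melt", "melt")
    fit = equilibrium.fit_thermal(io.read_melt_csv(cfg.inputs[key]))
    return {"thermal_fit": fit.to_dict(), "units": {"tm": "degC"}}


def _stage_kinetics(cfg: RunConfig, params: dict, outdir: Path, seed: int) -> dict:
    key = _require(params, "trace", "kinetics")
    trace = io.read_trace_csv(
        cfg.inputs[key],
        denaturant=params.get("denaturant", 0.0),
        temperature=params.get("temperature", 298.15),
        direction=params.get("direction", "unfolding"),
    )
    fit = kinetics.fit_exponential(trace)
    out = {"exponential_fit": {k: v for k, v in fit.to_dict().items()
                               if k != "residuals"},
           "units": {"rate": "1/s"}}
    if trace.direction == "refolding":
        out["lag"] = kinetics.detect_lag(trace).to_dict()
        out["units"]["lag_duration"] = "s"
    return out


def _stage_chevron(cfg: RunConfig, params: dict, outdir: Path, seed: int) -> dict:
    points = _require(params, "points", "chevron")
    fits = [(float(p["rate"]), float(p["denaturant"]), str(p["direction"]))
            for p in points]
    fit = kinetics.build_chevron(fits, temperature=params.get("temperature", 298.15))
    d = fit.to_dict()
    for arm in ("unfolding_arm", "refolding_arm"):
        if d.get(arm):
            d[arm].pop("used_mask", None)
    d.pop("denaturant", None)
    d.pop("ln_rate", None)
    d.pop("direction", None)
    return {"chevron": d,
            "units": {"kNU0": "1/s", "kUN0": "1/s", "dG_kinetic": "kcal/mol",
                      "m_ddagger": "kcal/(mol.M)"}}


def _stage_eyring(cfg: RunConfig, params: dict, outdir: Path, seed: int) -> dict:
    key = _require(params, "series", "eyring")
    series = io.read_rate_series_csv(cfg.inputs[key])
    fit = kinetics.fit_eyring_cp(series, T0=params.get("T0", 298.0))
    return {"eyring_fit": fit.to_dict(),
            "units": {"dH": "kcal/mol", "dS": "kcal/(mol.K)",
                      "dCp": "kcal/(mol.K)", "T0": "K"}}


def _stage_saxs_reduce(cfg: RunConfig, params: dict, outdir: Path, seed: int) -> dict:
    key = _require(params, "curve", "saxs_reduce")
    curve = io.read_saxs_dat(cfg.inputs[key],
                             q_unit=params.get("q_unit", "1/A"))
    g = saxs.guinier_fit(curve, qmin_cut=params.get("qmin_cut"))
    pr = saxs.ift_pr(curve, dmax_trial=params.get("dmax"),
                     alpha=params.get("alpha"))
    io.write_pr(pr, outdir / "pr.txt")
    return {
        "guinier": g.to_dict(),
        "pr_summary": {k: v for k, v in pr.to_dict().items()
                       if k not in ("r", "p")},
        "resolution_A": saxs.resolution(float(curve.q[-1])),
        "units": {"Rg": "A", "Dmax": "A", "resolution": "A"},
    }


def _stage_saxs_model(cfg: RunConfig, params: dict, outdir: Path, seed: int) -> dict:
    key = _require(params, "pdb", "saxs_model")
    model = io.read_pdb(cfg.inputs[key])
    q = np.asarray(params.get("q_grid", np.linspace(0.01, 0.3, 100)), dtype=float)
    theo = saxs.debye_intensity(model, q, hist_bin=params.get("hist_bin", 0.5))
    io.write_saxs_dat(theo, outdir / "model_curve.dat")
    out = {"model": {"n_sites": int(model.weights.size),
                     "coordinate_Rg_A": model.radius_of_gyration(),
                     "max_distance_A": model.max_distance()}}
    if "curve" in params:
        data = io.read_saxs_dat(cfg.inputs[params["curve"]])
        out["discrepancy"] = saxs.chi2_discrepancy(data, theo).to_dict()
    return out


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "spectra": _stage_spectra,
    "equilibrium": _stage_equilibrium,
    "melt": _stage_melt,
    "kinetics": _stage_kinetics,
    "chevron": _stage_chevron,
    "eyring": _stage_eyring,
    "saxs_reduce": _stage_saxs_reduce,
    "saxs_model": _stage_saxs_model,
}


# ---------------------------------------------------------------------------
# Summary table
# ---------------------------------------------------------------------------

_SUMMARY_ROWS = (
    # (label, units, report file, dotted path to value, path to error)
    ("dG0", "kcal/mol", "equilibrium", "two_state_fit.dG0", "two_state_fit.dG0_err"),
    ("m", "kcal/(mol.M)", "equilibrium", "two_state_fit.m_value", "two_state_fit.m_err"),
    ("Tm", "degC", "melt", "thermal_fit.tm", "thermal_fit.tm_err"),
    ("dH_act", "kcal/mol", "eyring", "eyring_fit.dH", "eyring_fit.dH_err"),
    ("dS_act", "kcal/(mol.K)", "eyring", "eyring_fit.dS", "eyring_fit.dS_err"),
    ("dCp_act", "kcal/(mol.K)", "eyring", "eyring_fit.dCp", "eyring_fit.dCp_err"),
    ("Rg_guinier", "A", "saxs_reduce", "guinier.Rg", "guinier.Rg_err"),
    ("Rg_real_space", "A", "saxs_reduce", "pr_summary.Rg_real", None),
    ("Dmax", "A", "saxs_reduce", "pr_summary.Dmax", None),
)


def _dig(d: dict, dotted: str):
    for part in dotted.split("."):
        if not isinstance(d, dict) or part not in d:
            return None
        d = d[part]
    return d


def build_summary(reports: dict) -> list[dict]:
    """Parameter-table rows (label, value, 1σ error, units) from stage reports."""
    rows = []
    for label, units, stage, vpath, epath in _SUMMARY_ROWS:
        if stage not in reports:
            continue
        value = _dig(reports[stage], vpath)
        if value is None:
            continue
        err = _dig(reports[stage], epath) if epath else None
        rows.append({"parameter": label, "value": value,
                     "error_1sigma": err, "units": units})
    return rows


# ---------------------------------------------------------------------------
# Runner
# ---------------------------------------------------------------------------

def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the configured stages; returns {stage_name: report}.

    Reports are written as ``<outdir>/<stage>.json`` as each stage finishes;
    a failure writes ``error.json`` and re-raises, preserving prior outputs.
    """
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ordered = sorted(cfg.stages, key=lambda s: _STAGE_RANK[s["name"]])
    reports: dict = {}
    started = time.time()
    for st in ordered:
        name = st["name"]
        logger.info("running stage %s", name)
        try:
            report = _STAGE_FUNCS[name](cfg, st["params"], outdir,
                                        stage_seed(cfg.seed, name))
        except Exception as exc:
            io.write_report(
                {"stage": name, "error": type(exc).__name__, "message": str(exc)},
                outdir / "error.json",
            )
            raise
        reports[name] = report
        io.write_report(report, outdir / f"{name}.json")
        # a simulate stage registers its fixtures as pipeline inputs
        if name == "simulate":
            for f in (outdir / "fixtures").iterdir():
                cfg.inputs.setdefault(f.stem, f)
    summary = build_summary(reports)
    if summary:
        io.write_report({"parameters": summary}, outdir / "summary.json")
        with open(outdir / "summary.txt", "w") as fh:
            fh.write(f"{'parameter':<14}{'value':>14}{'1-sigma':>12}  units\n")
            for row in summary:
                err = ("-" if row["error_1sigma"] is None
                       else f"{row['error_1sigma']:.3g}")
                fh.write(f"{row['parameter']:<14}{row['value']:>14.4g}"
                         f"{err:>12}  {row['units']}\n")
    io.write_report({"elapsed_s": round(time.time() - started, 3),
                     "seed": cfg.seed}, outdir / "run_meta.json")
    return reports
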