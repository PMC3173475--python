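# protstab

Protein stability analysis in Python: equilibrium and kinetic folding
thermodynamics plus small-angle X-ray scattering (SAXS) reduction, built as
scikit-learn-style estimators with a thin CLI on top.

The package targets the standard solution-biophysics workflow for comparing
a free enzyme with its ligand-bound form — the motivating system is human
α-thrombin with and without the covalent active-site inhibitor PPACK:

* **Fluorescence spectra** → center of spectral mass ⟨λ⟩ = ΣλᵢFᵢ/ΣFᵢ and
  integrated area, the observables that track tryptophan solvent exposure.
* **Equilibrium denaturation** → two-state linear extrapolation method
  (LEM): ΔG = ΔG° − m·[den], f_D = 1/(1+exp((ΔG°−m·[den])/RT)), fit for
  (ΔG°, m, S_N, S_D); m-value comparison (Δm ∝ ΔΔASA of binding) and
  stability gain ΔΔG°.
* **Thermal melts** → four-parameter logistic, apparent Tm.
* **Stopped-flow kinetics** → single-exponential fits
  F(t) = F₀ + Amp(e^(−kt) − 1), refolding lag extraction, chevron plots
  with linear-arm extrapolation to water (k_NU(0), k_UN(0), kinetic
  m‡-values, rollover detection), and the two-state consistency check
  ΔG° = −RT·ln(k_NU(0)/k_UN(0)).
* **Activation thermodynamics** → Arrhenius ΔE‡ and the transition-state
  fit with activation heat capacity: ΔH‡(T) = ΔH‡ + ΔCp‡(T−T₀),
  ΔS‡(T) = ΔS‡ + ΔCp‡·ln(T/T₀), read from the curvature of ln k vs 1/T.
* **SAXS** → automatic Guinier fit (qRg ≤ 1.3), Kratky transform,
  regularized indirect Fourier transform for p(r) with Dmax search,
  I(0)/C molecular weight against standards, in-vacuo Debye model
  intensities from PDB or bead coordinates, and error-weighted χ²
  model/data comparison.

A first-class synthetic-data module (`protstab.synthetic`) generates every
input class with known ground truth and controlled Gaussian noise, so the
entire pipeline is validated by parameter recovery with no downloads.
See `docs/methods.md` for the models, conventions and limitations.

## Worked example

```python
import numpy as np
from protstab import (GroundTruth, gen_isotherm, gen_saxs_body,
                      fit_two_state, guinier_fit, ift_pr)

# equilibrium unfolding isotherm at realistic noise
iso = gen_isotherm(GroundTruth("isotherm", {
    "dG0": 3.7, "m": 3.12, "signal_native": 350.0, "signal_denatured": 355.0,
    "denaturant_grid": np.linspace(0.0, 4.5, 30)}, noise_sd=0.025, seed=7))
fit = fit_two_state(iso)
print(f"dG0 = {fit.dG0:.2f} +/- {fit.dG0_err:.2f} kcal/mol")
print(f"m   = {fit.m_value:.2f} +/- {fit.m_err:.2f} kcal/(mol M)")
print(f"midpoint = {fit.midpoint:.2f} M")

# SAXS reduction of a globular particle
curve = gen_saxs_body(GroundTruth("saxs_body", {
    "body": "prolate_ellipsoid", "rg": 23.4, "dmax": 72.0,
    "q_grid": np.linspace(0.008, 0.30, 120)}))
g, pr = guinier_fit(curve), ift_pr(curve)
print(f"Guinier Rg = {g.Rg:.1f} A  (window qmax*Rg = {g.qmax_rg:.2f})")
print(f"p(r): Dmax = {pr.Dmax:.0f} A, real-space Rg = {pr.Rg_real:.1f} A")
```

prints

```
dG0 = 3.72 +/- 0.04 kcal/mol
m   = 3.14 +/- 0.03 kcal/(mol M)
midpoint = 1.18 M
Guinier Rg = 23.5 A  (window qmax*Rg = 0.65)
p(r): Dmax = 72 A, real-space Rg = 23.4 A
```

The isotherm fit recovers the generating free energy of unfolding
(3.7 kcal/mol) and m-value (3.12 kcal/(mol·M)) within their 1σ errors; the
transition midpoint ΔG°/m lands at 1.18 M denaturant. The scattering
reduction recovers the particle's radius of gyration from the Guinier
window and both its real-space Rg and maximum dimension (72 Å) from the
pair-distance distribution.

The fitters are sklearn estimators (`TwoStateUnfolding`, `ThermalMelt`,
`SingleExponential`, `EyringCp`, `GuinierAnalysis`, `PairDistanceIFT`, …)
with `fit`/`predict`, `get_params`/`set_params` and trailing-underscore
fitted attributes, so they compose with sklearn pipelines and model
selection; the `fit_*` module functions are thin wrappers returning typed
result records.

## Command line

```bash
protstab simulate --out demo            # write synthetic fixture set
protstab fit-equilibrium --demo         # two-state LEM fit on a fixture
protstab fit-melt --demo
protstab eyring --demo
protstab saxs-reduce --demo
protstab chevron --demo
protstab run config.yaml                # multi-stage pipeline from config
```

Every subcommand has `--demo` (runs on generated fixtures with no external
input) and writes deterministic JSON reports; `run` executes a config-driven
multi-stage pipeline and emits a publication-style parameter summary table
(ΔG°, m, Tm, ΔH‡, ΔS‡, ΔCp‡, Rg, Dmax with units and 1σ errors).

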