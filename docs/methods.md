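# Methods

This note documents the models implemented in `protstab`, the choices made
where the design was genuinely open, and the limits of what the synthetic
validation shows.

## Equilibrium unfolding by linear extrapolation

A reversible two-state transition N ⇌ D is described by the equilibrium
constant `k_den = [D]/[N]` and the unfolding free energy
`ΔG = −R·T·ln(k_den)`. The linear extrapolation method (LEM) assumes the
free energy varies linearly with denaturant,

    ΔG([den]) = ΔG° − m·[den],

so the denatured fraction is a logistic in concentration,

    f_D = 1 / (1 + exp((ΔG° − m·[den]) / (R·T))),

and the observed spectroscopic signal is `S_obs = S_N·f_N + S_D·f_D`.
`TwoStateUnfolding` fits (ΔG°, m, S_N, S_D) by unweighted nonlinear least
squares, reporting 1σ uncertainties from the Jacobian-based covariance.

Choices:

* **Gas constant.** `R = 1.9872 cal·mol⁻¹·K⁻¹`, the value conventionally
  printed in the folding literature, fixed rather than CODATA so that free
  energies agree digit-for-digit with hand arithmetic at that precision.
* **Baselines.** Denaturant-independent endpoint signals by default — the
  minimal two-state observation model. Real pre/post-transition slopes are
  common, so a Santoro–Bolen-style linear-baseline variant is available via
  `linear_baselines=True` (adds two slope parameters).
* **Initialization.** Deterministic, data-driven: endpoint signals from the
  means of the first/last 10% of points, midpoint from the half-signal
  crossing, m from the maximal signal slope via `dS/dc|_mid = span·m/(4RT)`.
* **Plateau screen.** If either end segment of the isotherm is not flat
  within 5% of the signal swing, the fit proceeds but warns — baselines are
  then poorly determined.
* **Units.** kcal/mol for ΔG°, kcal/(mol·M) for m, Kelvin internally
  (Celsius converted at the boundary).

The m-value comparison (`compare_asa`) reports Δm = m_holo − m_apo, whose
sign tracks the binding-induced change in unfolding ΔASA under a common
unfolded state. The sign is called only when |Δm| exceeds the combined 1σ
error of the two fits — the minimal propagated-error criterion.

## Thermal melts

Irreversible thermal denaturation supports only an apparent transition
temperature. Melts are fit with a four-parameter logistic
`y = baseline + amplitude/(1 + exp(−(T − Tm)/slope))`; Tm is the inflection.
The slope parameter is the transition width in °C (default start: 5% of the
scanned range); amplitude may take either sign.

## Stopped-flow kinetics

Observed transitions follow `F(t) = F0 + Amp·(exp(−k·t) − 1)`: positive
amplitude means decay. The sign convention is fixed here because published
forms of this equation vary; fluorescence quenching on unfolding makes
decay the positive-amplitude case. The rate is constrained positive; a fit
pinned at the bound is flagged rather than silently returned.

**Lag phase.** Refolding through a sequential U→I→N scheme delays the
signal carried by N; the lag is quantified as the time-axis intercept of
the tangent at the maximal-slope point of the rising signal, measured from
the initial signal level. Smoothing (Savitzky–Golay, order 2) is
noise-adaptive: an 11-point window on effectively noiseless data (keeps the
tangent within ~1% of the analytic intercept), widening to ~10% of the
trace when the high-frequency residual exceeds 0.1% of the signal swing.
A trace whose maximal slope falls within half a smoothing window of t = 0
is reported as "no lag" — it is indistinguishable from a monotone
exponential rise. The lag and the first-step rate are reported separately;
no reciprocal relation between them is imposed.

**Chevron analysis.** ln k versus [denaturant] is assembled per direction
and each arm is fit linearly on its linear region only. The linear region
is found by iterative endpoint trimming: while a Wald–Wolfowitz runs test
on the residual signs rejects randomness (p ≤ 0.05), the endpoint deviating
more from the line is dropped (minimum three points). This reproduces the
by-eye exclusion of curved ("rollover") segments without a manual choice;
excluded high-denaturant unfolding points set the rollover flag, and the
smallest excluded concentration is reported as the onset. Because the
screen trims only until curvature stops being statistically detectable, the
reported onset is an upper bound that approaches the true onset as the
curvature strengthens. Arm slopes are converted to kinetic m-values
(m‡ = |slope|·R·T); the 0 M intercepts give k_NU(0) and k_UN(0), and for a
two-state system `−R·T·ln(k_NU(0)/k_UN(0))` must reproduce the equilibrium
ΔG° — exposed as `dG_kinetic` and verified to 2% on simulated systems.

**Activation thermodynamics.** Two nested models:

* Arrhenius: `ln k = ln γ − ΔE‡/(R·T)`, fit as a linear regression on
  1/(R·T); a quadratic term in the same variable supplies a curvature
  t-statistic and p-value, the diagnostic for a temperature-dependent
  activation enthalpy.
* Transition-state with activation heat capacity:

      ln k = ln(k_B·T/h) + ΔS‡(T)/R − ΔH‡(T)/(R·T)
      ΔH‡(T) = ΔH‡ + ΔCp‡(T − T0),  ΔS‡(T) = ΔS‡ + ΔCp‡·ln(T/T0)

  fit by nonlinear least squares with T0 = 298 K by default. A free
  pre-exponential γ would be exactly degenerate with ΔS‡ (both enter as
  additive constants in ln k), so the prefactor is fixed at k_B/h and the
  reported entropy absorbs that convention; ΔS‡ should be compared between
  conditions, not interpreted absolutely. The synthetic generator uses the
  same convention, making parameter recovery well-posed. "1% noise on the
  rate" is implemented as Gaussian noise of sd 0.01 on ln k, since the
  absolute magnitude of ln k depends on the prefactor convention.
  ΔCp‡ identifiability requires a temperature span ≥ 10 K and a finite
  covariance; otherwise the estimate is flagged.

## Small-angle X-ray scattering

q follows the `4π·sin(θ)/λ` convention in Å⁻¹ (a 1/nm conversion flag is
provided at the file boundary). Nominal resolution is reported as 2π/q_max.

**Guinier.** `ln I = ln I0 − (Rg²/3)q²` fit on the widest low-angle window
with q_max·Rg ≤ 1.3, iterated to self-consistency, then trimmed from the
high-q end while a runs test on the residuals detects systematic curvature.
The trim matters for nearly noise-free data, where form-factor curvature
inside the qRg ≤ 1.3 window otherwise biases a sphere's Rg by ~2%; with
the screen the sphere closed form √(3/5)·R is recovered within 0.5%, and
on noisy data the screen leaves the full window in place.

**Kratky.** Pointwise q²·I(q); for a Guinier Gaussian the peak sits at
√3/Rg, and a bell-then-decay shape indicates a compact globular particle.

**Pair-distance distribution.** The IFT solves
`I(q) = 4π ∫ p(r)·sinc(qr) dr` on a fixed r grid (81 points) by
non-negative least squares with hard endpoint constraints
p(0) = p(Dmax) = 0 and a second-difference smoothness penalty. The penalty
weight α is chosen by a discrete L-curve corner search (residual norm vs
penalty norm over a log-spaced α scan). Nonnegativity and endpoint
vanishing therefore hold by construction on every output. Real-space
Rg and I(0) come from the p(r) moments.

**Dmax search.** Trial values scan [2·Rg, 4·Rg] in 1 Å steps (Rg from the
automatic Guinier fit). At each trial a lightly-regularized unconstrained
probe solve (α reduced 100×) measures fit quality: while the trial is below
the true maximum dimension the data cannot be represented and χ² falls by
orders of magnitude per Å; the search takes the last trial showing a strong
drop (factor < 0.25 per step, starting above the χ² floor), extended to the
χ² minimum when substantial improvement remains beyond it. On noiseless
synthetic bodies (spheres, prolate ellipsoids, bead models, Dmax 50–72 Å)
this recovers Dmax within ±2–3 Å. Known limitation: with 2% intensity
noise the faint long-distance tail of anisotropic bodies falls below the
noise floor and Dmax is underestimated by up to ~15%; this is an
information limit of the data, not a solver artifact, and matches the
general experience that Dmax from noisy curves requires judgment. Gnom's
perceptual quality criteria are deliberately not reproduced.

**Molecular weight.** `MW = (I0/C)_sample / mean((I0/C)_ref / MW_ref)` with
I(0) from the Guinier fit of each curve — linear in I0/C, exact on
consistent references.

**Debye model scattering.** `I(q) = Σᵢⱼ wᵢwⱼ·sinc(q·rᵢⱼ)` over
coordinates, in vacuo, with q-independent weights (effective atomic numbers
for PDB atoms, uniform for beads); an optional distance-histogram
acceleration bins pair distances (0.1 Å bins keep the error below 5·10⁻⁴ of
I(0)). No hydration shell and no q-dependent form factors are modeled, so
χ² values against real data are not comparable with Crysol's; the χ²
machinery itself (analytic least-squares scale, error-weighted reduced χ²)
is validated on closed forms. PDB reading takes all non-hydrogen
ATOM/HETATM sites of the first model, resolving alternate locations by
highest occupancy.

## Synthetic data

The generator produces every input class with known ground truth: LEM
isotherms (default parameter sets ΔG° = 3.7 / 15.33 kcal/mol,
m = 3.12 / 4.96 kcal/(mol·M), 30-point grids to 4.5 / 5.5 M), logistic
melts (Tm 58 / 74 °C on a 25–90 °C grid), single-exponential and sequential
U→I→N traces, curved ln k temperature series (278–303 K,
ΔH‡ 20.0 / 23.1 kcal/mol, ΔS‡ 0.071 kcal/(mol·K),
ΔCp‡ 0.62 / 1.00 kcal/(mol·K), T0 = 298 K), and scattering curves of
spheres (exact form factor), prolate ellipsoids (orientation average by
64-point Gauss–Legendre quadrature — deterministic and accurate for smooth
form factors), and bead models (Debye sum; the ellipsoid fill appends the
two poles so the maximum inter-bead distance equals 2c exactly).

Noise is additive Gaussian on the observed channel — signal units for
isotherms/melts/traces, ln-k units for rate series, and relative to I(q)
for scattering (intensities span decades, so absolute noise would be
meaningless at high q). The σ column of scattering curves defaults to 2% of
I(q) plus a small floor. Identical seed and parameters give bit-identical
data; the same seed fans out to independent per-stage streams in the
pipeline via CRC-based child seeds.

What the synthetic validation does **not** show: instrument effects (beam
smearing, detector response, photobleaching), non-Gaussian noise,
baseline drift, hydration-shell scattering, or three-state equilibria — a
populated equilibrium intermediate is handled qualitatively through the
chevron rollover flag and the lag phase, not by a three-state fit.
Parameter-recovery success on these synthetic conditions demonstrates the
estimators are unbiased and correctly implemented under the stated models,
not that real data satisfy those models.

## Problem sizes

Validation uses 200-replicate isotherm ensembles, 50-replicate melt and
rate-series ensembles, 120-point scattering curves and bead models of a few
thousand sites — sizes chosen to make Monte-Carlo means stable to well
inside the reported uncertainties while the whole suite runs in seconds.
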