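# Methods

## Chemical model

One metal (Cu(I) in the motivating experiments) equilibrates with any number
of independent ligands, each forming a single mononuclear complex MLₙ with
n = 1 or 2:

* n = 1: M + L ⇌ ML, K_A = [ML]/([M][L]) (M⁻¹); K_A = 1/K_D exactly.
* n = 2: M + 2L ⇌ ML₂, β₂ = [ML₂]/([M][L]²) (M⁻²), the cumulative formation
  constant (no ML intermediate is modelled — for BCA and for thiol-pair
  peptides the ML₂ step is strongly cooperative and the 1:1 intermediate is
  not populated at the probe concentrations used).

All constants are *conditional* constants for the working buffer (the
titrations this package models were run in 10 mM HEPES pH 7, 20 mM NaCl,
80 mM KCl with 1 mM NH₂OH as reductant). Activity corrections, proton
competition, and Cu(II)/Cu(I) redox speciation are deliberately out of
scope; a constant measured in another buffer must be re-conditioned by the
user. Ternary and polynuclear complexes are rejected at configuration time.
A formation constant of zero denotes a non-binding ligand (used for
cysteine-to-serine mutant controls).

### Speciation solver

Given totals (M_T, {L_T,i}), the free-metal concentration is the unique root
of

    f(M) = M + Σᵢ Kᵢ · M · Lᵢ(M)^{nᵢ} − M_T,

with each free ligand from its own balance in closed form (for n = 2 the
positive quadratic root in the cancellation-free form
L = 2·L_T/(1 + √(1 + 8KM·L_T))). f is strictly increasing in M, and the
bracket [0.5·M_T/(1 + Σ Kᵢ L_T,iⁿ), M_T] provably contains the root, so
Brent's method on log₁₀M cannot fail; the solution is verified against a
relative metal-balance residual of 10⁻¹² (iteration cap 200). Working on
log₁₀M matters because buffered free Cu(I) spans sub-zeptomolar (~10⁻¹⁸ M)
to bench concentrations (~10⁻⁴ M).

Degenerate inputs are handled exactly: zero metal returns all-free ligands;
no (binding) ligands returns free metal = total.

## Withholding and stoichiometry

A competitor tighter than the probe sequesters the first equivalents of
added metal, displacing the probe's isotherm rightward. "Withheld metal" is
operationalised as the *half-maximum horizontal shift*: the difference in
total metal at which the replicate-averaged competition and control curves
cross half of the control's plateau (mean of its top 10% of points), using
piecewise-linear interpolation because titration grids are coarse (1–2 µM
steps). The half-max shift was chosen over the full-saturation breakpoint
because it is robust to plateau noise; in the tight-competitor limit
(constant ≥ 10³× the probe's) both definitions agree with
competitor_total/n to ≤ 1%.

With a competitor only ~10²–10³× tighter than the probe, thermodynamic leak
makes the measured shift a few percent smaller than the ideal total/n (for
14 µM of a 2:1 competitor at 239× the probe's β₂ against 10 µM BCA the shift
is 6.7 µM rather than 7.0). This is a property of the chemistry, not a
numerical artifact; stoichiometry inference therefore rounds the ratio
total/withheld and only warns when it deviates > 20% from an integer.

## Affinity fitting

The unknown constant is fitted on the log₁₀ scale (positivity and
conditioning over ~10¹⁴–10²⁰) by minimising the unweighted residual sum of
squares between observed absorbances and fully simulated isotherms, using
bounded Brent minimisation on log₁₀K ∈ [5, 30] (xatol 10⁻⁷; a noise-free
round trip recovers the generating log₁₀β₂ to < 10⁻⁴). Unweighted least
squares is the default because bench titrations rarely come with a
calibrated error model; an optional per-series additive baseline is
available as a nuisance parameter (closed-form given K).

Uncertainty is a seeded residual bootstrap (default 200 resamples): residuals
are resampled with replacement onto the fitted curve and the fit repeated;
the standard deviation of the bootstrap estimates is reported as
`stderr_log10`. A bootstrap was preferred to asymptotic covariance because n
is small and the model strongly nonlinear near the stoichiometric knee.

The *discrimination envelope* recomputes the RSS with the fitted constant
displaced ×10 and ÷10 (all else fixed) — the standard visual demonstration
that competition data actually pin the affinity. On data generated by the
model at 1% noise, the 10×-weaker RSS is ≥ 5× the fitted RSS and the
10×-tighter RSS ≥ 2× (the weaker side degrades faster because a weaker
competitor frees metal into the probe's steep response region).

### Identifiability

Competition constrains the constant only while the competitor's effective
affinity (K·L_Tⁿ) is within a few orders of the probe's (β₂·L_T²). The fit
flags two regimes:

* **Below the window** (> 10³× weaker): the competitor leaves no signature;
  the result is marked non-converged with an upper-bound-only warning. This
  is the expected outcome for non-binding mutant controls.
* **Above the window** (> 10³× tighter): the stoichiometric displacement
  persists and the constant's signature survives in the *low-signal* region
  before the knee. Whether that region is informative depends on the noise
  structure — it is under signal-proportional noise, which is what anaerobic
  titration scatter (dominated by delivery/concentration error) looks like —
  so the result carries an advisory warning rather than a rejection. The 1:1
  chaperone design (20 µM probe vs. 20 µM competitor binding ~10⁴× more
  effectively) is recovered to ±0.1 log₁₀ at 1% signal-proportional noise.

### 1:1 depletion fit

Thermophoresis-style dilution series are fitted with the exact quadratic
mass-action law for a labeled partner at total T (not in vast excess over
K_D): bound = (L + T + K_D − √((L+T+K_D)² − 4LT))/2, response linear in the
bound fraction between a floor and a ceiling. K_D (log scale), floor and
ceiling are fitted by lmfit least squares. K_D is flagged unidentifiable
when even the smallest positive titrant is predicted above half-saturation
(the series never samples the rising limb, and K_D and the floor trade off
along a flat ridge); non-monotone responses beyond 5× a robust (MAD) noise
scale raise a warning.

## Buffered-availability metalation

Intracellular exchangeable Cu(I) is buffered; a candidate protein
experiences a fixed availability *a* rather than a depletable pool. The
cytosolic value is calibrated by the chaperone ATX1, whose occupancy tracks
the pool: mid-point availability = K_D^ATX1 (identity mapping, with
provenance recorded). Two occupancy definitions are implemented because the
question "do Cu-dependent peptide homodimers form?" can be read two ways:

* `ligand_fraction` (default): fraction of total ligand in the complex,
  n·[MLₙ]/L_T with free L from L + n·K·a·Lⁿ = L_T. This is the default
  because the biological question concerns the fate of the peptide pool.
* `complex_saturation`: K·a·Lⁿ/(1 + K·a·Lⁿ) at equilibrium free L.

Both are closed-form invertible (`threshold_for_occupancy`; round trip to
10⁻⁶ relative). For a 1:1 ligand under buffered metal, `ligand_fraction` is
concentration-independent (K_A·a/(1 + K_A·a)), so no threshold exists and
the package says so rather than returning a misleading number. With
β₂ = 3.79 × 10¹⁹ M⁻² and a = 5.47 × 10⁻¹⁸ M, half-occupancy requires ~4.8 mM
total peptide (`ligand_fraction`) or ~2 M (`complex_saturation`) — under
either definition far above plausible cytosolic peptide concentrations,
which is the biological conclusion the model supports. The closed forms are
cross-checked in the tests against the full speciation solver with an
explicit ×10⁶ buffering pool pinning the free metal (agreement ≤ 10⁻⁴).

## Synthetic data generator

Designs encode the bench conditions of the probe-competition experiments:
probe totals 10–88 µM, competitors 10–44.8 µM (2:1 peptide at
β₂ = 3.79 × 10¹⁹ M⁻², 1:1 chaperone at K_D = 5.47 × 10⁻¹⁸ M, non-binding
mutants at K = 0), n = 2–3 replicates, per-replicate probe batches where the
experiments used them (88.3/84/88.4 µM), and metal grids of 0 → 1.5× the
stoichiometric endpoint in 30 steps unless the experiment used a specific
grid (0–30 µM for the 10 µM-probe design; 0–60 µM in 2 µM steps for the
50 µM-probe design).

Noise is multiplicative Gaussian, A·(1 + ε) with ε ~ N(0, 0.01) by default
(clipped at zero absorbance): scatter in careful anaerobic titrations is
small and dominated by volumetric/concentration error, which scales with the
signal. The random source is numpy's PCG64; a (design, seed) pair reproduces
byte-identical CSV output (6 significant figures). What the generator does
*not* emulate — baseline drift, probe photobleaching, competitor
insolubility, slow Cu(I) exchange kinetics, spectral overlap between
species — bounds what passing tests show about real data: recovery results
demonstrate estimator correctness and precision under the stated noise
model, not robustness to systematic error.

## Problem sizes and numerical choices

Recovery statistics use 50 seeded replicates per design at 1% noise (3
replicate curves × 31 grid points each); bootstrap uncertainty uses 200
resamples. Speciation tolerance 10⁻¹² (relative metal balance), fit
tolerance 10⁻⁷ on log₁₀K, occupancy inversion exact. Ties/degeneracies:
identical isotherms give zero withholding; a grid whose first point is zero
metal anchors the baseline; stoichiometry rounding is to the nearest integer
with a 20% warning band.

## Known limitations

* Only mononuclear 1:1 and 1:2 complexes; no mixed or ternary species.
* Conditional constants only — no pH, ionic-strength, or redox corrections.
* Unweighted least squares by default; replicate-SD weighting is available
  but the default will under-weight the informative low-signal region if the
  real noise is additive.
* The withholding statistic assumes the control reaches a clean plateau
  within the titrated range; truncated titrations raise a range error rather
  than extrapolating.
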