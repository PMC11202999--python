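# Methods

This note documents the models behind each stage, the defaults and why they
were chosen, what the synthetic generators do and do not emulate, and the
numerical choices that a maintainer would otherwise have to reverse-engineer.

## Fluorescence model and correction

All fluorescence stages assume a single fluorophore species P (the ligand)
whose emission is reduced by added DNA (the "quencher" Q in Stern–Volmer
terminology). Measured intensities are attenuated by the sample's absorbance
at the excitation and emission wavelengths (inner-filter effect); the
standard first-order correction `F_corr = F_meas · e^((A_ex+A_em)/2)` is
applied before any fit when absorbances are supplied. The correction is
multiplicative and only valid at moderate absorbance; values above 0.3
trigger a warning rather than an error, since rejecting data is an
analyst's decision. F₀ is always the corrected intensity of the
zero-quencher point, never a fitted intercept: the titration design starts
from ligand alone, so that point is a direct measurement.

## Stern–Volmer and mechanism rules

`F₀/F` vs `[Q]` is fitted by **unweighted** ordinary least squares — the
conventional presentation of these plots, and no replicate variances are
available to weight with. `k_q = K_sv/τ₀` uses the conventional lifetime
τ₀ = 10⁻⁸ s for organic fluorophores (configurable). The mechanism rule is
deliberately strict: *static* requires a strictly decreasing K_sv across
every consecutive temperature pair **and** every k_q above the
diffusion-controlled collisional limit 2.0×10¹⁰ L mol⁻¹ s⁻¹; *dynamic*
requires the mirror image; anything else — ties, non-monotone sequences, a
single temperature — is *indeterminate*. Trends are judged on point
estimates, ignoring error-bar overlap, matching how such tables are read in
practice.

Two K_sv values are called *equivalent* when their difference is within
twice the sum of their standard errors. The literature phrase "negligible
difference" has no number attached; a 2-combined-SE band makes the call
reproducible without being tighter than the reported uncertainties support.

## Binding constant and stoichiometry

The double-log relation is implemented as
`y = n·log₁₀(K_a) + n·x` with `y = log₁₀((F₀−F)/F)` and
`x = log₁₀([Q_t] − (F₀−F)[P_t]/F₀)` — algebraically the same as the
textbook form with its `−n log(1/·)` double negation removed. The abscissa
term is the free-DNA concentration under the assumption that the complex is
completely dark (fully static quenching): then `(F₀−F)/F₀` equals the bound
fraction and the relation is an exact identity for a 1:1 equilibrium, which
is what makes noiseless generator round-trips recover K_a and n to machine
precision. Points with no quenching signal or a non-positive free-DNA term
are excluded and counted; fewer than three usable points is an error that
reports why points were dropped.

## Thermodynamics

`log₁₀(K_a)` vs `1/T` is fitted by least squares; ΔH° = −ln(10)·R·slope
(kJ mol⁻¹), ΔS° = ln(10)·R·intercept (J mol⁻¹ K⁻¹), R = 8.314 J mol⁻¹ K⁻¹.
The exact ln(10) = 2.302585… is used rather than the printed 2.303 so that
the two-temperature case reduces *exactly* to the closed form
ΔH° = −R·ln(K₂/K₁)/(1/T₂ − 1/T₁); the difference is 0.02%, far below any
experimental uncertainty. ΔG°(T) = ΔH° − T·ΔS°/1000 is evaluated at every
input temperature, so the Gibbs map is consistent with (ΔH°, ΔS°) by
construction. Celsius→kelvin uses 273.15 exactly.

Driving-force classification follows the enthalpy/entropy sign heuristic
with one ordering subtlety: a near-zero enthalpy (|ΔH°| < 4 kJ mol⁻¹) with
positive entropy is checked **first** and read as electrostatic, because
the sign rules alone cannot distinguish "negative ΔH°" from "ΔH° ≈ 0", and
the electrostatic case is precisely the one where enthalpy contributes
little to ΔG°. The 4 kJ mol⁻¹ band is a package choice that turns a
qualitative "≈ 0" argument into a testable rule. Note this assignment of
(ΔH°<0, ΔS°>0) to hydrogen bonding + hydrophobic contacts follows the
usage common in the DNA-binding literature; the classical
Ross–Subramanian scheme reads that quadrant differently, and users who
prefer it should treat the verdict as advisory.

## Melting

`f_ss` normalization uses the readings **closest to** 20 and 100 °C as the
folded/denatured baselines, so endpoints are exactly 0 and 1 regardless of
instrument offsets — which also makes T_m invariant under any affine
transform of the absorbance axis. T_m is the linear interpolation of the
first upward crossing of f_ss = 0.5; no sigmoid is fitted, because the
conventional analysis reads the crossing directly off the plot. On logistic
curves sampled every 5 °C (the usual acquisition interval) the
interpolation bias stays below 0.5 °C for transition widths ≥ 2 °C. The
intercalation call uses ΔT_m ≥ +5 °C (inclusive), the low end of the 5–8 °C
stabilisation classical intercalators produce.

## Viscosity

`η = (t−t₀)/t₀` against the buffer flow time, ordinate `(η/η₀)^(1/3)` with
η₀ from the mandatory ligand-free first entry (so the profile starts at
exactly 1), slope by least squares. The class threshold of 0.1 per unit
[ligand]/[DNA] ratio separates "significant" from "small" increases: over a
0–1.2 ratio range an intercalator roughly doubles η ((η/η₀)^(1/3) slope
≈ 0.25) while groove binders stay nearly flat (≈ 0.01); 0.1 sits between
with a wide margin on both sides. Replicate flow times are averaged before
entry.

## Binding-mode classifier

Evidence fields each cast one equal-weight vote through a fixed rule
(documented in the audit trail the classifier emits); a quorum of three
fields is required and ties are indeterminate. Equal weights are the honest
choice: the consensus argument these panels support is qualitative, and any
weighting would be invented. Two asymmetries are intentional:

* electrostatic binding can only *gain* votes from salt dependence or the
  thermodynamic force verdict — the other observables can rule it out but
  not demonstrate it — and salt independence casts a *negative*
  electrostatic vote;
* gel cleavage (nicked/linearized) flags covalent chemistry in the audit
  trail without voting, since strand scission says nothing about a
  non-covalent mode, while an intact plasmid is counted as
  groove-consistent.

The K_a magnitude rule votes groove for 10³–10⁵ L mol⁻¹ (groove binders
cluster there, up to ~1×10⁵ for well-characterised minor-groove agents)
and abstains outside that band.

## Trajectory observables

RMSD uses mass-weighted Kabsch superposition (SVD with the determinant
correction, so reflections are never returned) of each frame onto the
reference before the mass-weighted deviation is taken; RMSF iteratively
superposes all frames onto their running mean structure (converged to
10⁻¹⁰ nm, normally in 2–3 iterations) and reports per-atom fluctuations.
Both accept an atom mask so alignment can use a stable subset (e.g.
backbone) while fluctuations are reported for all atoms; the default is all
atoms with unit masses accepted when masses are unknown. SASA is
Shrake–Rupley with a deterministic Fibonacci sphere lattice (default 960
points, probe 0.14 nm — the standard water probe): deterministic by
construction, converged to <0.5% under point doubling on the test systems.
A point falling exactly on a neighbouring expanded sphere (coincident
atoms) is resolved by an index tie-break so duplicated spheres contribute
their area exactly once. The finite lattice is fixed in space, so SASA is
rotation-invariant only to ~0.1% at 960 points (exactly invariant under
translation); RMSD/RMSF/Rg are rigid-motion invariant to numerical
precision. Readers convert PDB/XYZ ångströms to nm; masses and van der
Waals radii come from small element tables with carbon fallbacks.

This module computes observables on user-supplied or synthetic ensembles
only; it does not run or reproduce molecular-dynamics simulations, and
published trajectory averages from 100 ns production runs are out of its
scope.

## Synthetic generators: what they emulate, and what not

* **Titration**: exact 1:1 mass action (quadratic root of
  `K_a(P−C)(Q−C) = C`) with a completely dark complex, inner-filter
  attenuation that the correction stage inverts exactly, and multiplicative
  Gaussian noise. Defaults emulate the reference design: fluorophore at
  3.28×10⁻⁶ mol L⁻¹, 11-point DNA grid 0→1.1×10⁻⁴ mol L⁻¹ (the
  concentration reached after ten 3.2 µL additions of 7.23×10⁻³ mol L⁻¹
  titrant into a 2 mL cuvette), absorbances growing with titrant via
  effective ε_ex = 2000 and ε_em = 100 L mol⁻¹ cm⁻¹. Fluorophore dilution
  (≤1.6% over the titration) is neglected. Site numbers n ≠ 1 are produced
  phenomenologically by inverting the double-log relation per point
  (Brent's method), since a non-integer n has no single-step mechanism.
  Not emulated: wavelength-resolved spectra, photobleaching, temperature
  drift — so passing tests demonstrate correct *inference given the model*,
  not robustness to instrument artefacts.
* **Melting**: two-state logistic `A(T) = A₂₀ + ΔA·σ((T−t_m)/w)` sampled
  20–100 °C, default width 3 °C. Any symmetric sigmoid would do; the
  logistic has a closed-form midpoint. Real pre/post-transition baselines
  drift linearly; the generator's are flat, which the normalization absorbs
  anyway.
* **Viscosity**: flow times back-computed from a target linear cube-root
  profile (slopes 0.25 / 0.01), uniform timing jitter capped at 0.2 s, the
  ligand-free reference kept exact.
* **Evidence**: the reference vector packages the observations reported for
  IPA–ctDNA (2 nm redshift, K_a = 1.75×10⁴, equivalent iodide quenching,
  ss/ds K_sv ratio 5.09/3.55, no salt effect, ΔT_m = −2.4 °C, flat
  viscosity, slight CD change, H-bond + hydrophobic forces, no cleavage).

All randomness flows through `numpy.random.default_rng(seed)`; a fixed seed
reproduces any synthetic campaign bit-exactly.

## Problem sizes

Test and acceptance computations use the study's own scales: 11-point
titrations, 100-replicate noise campaigns at 1% multiplicative noise,
17-point melting curves, ≤20-atom trajectory fixtures with 960-point SASA
lattices. These sizes were chosen as the smallest at which each statistical
claim (median errors, convergence fractions) is stable across seeds.

## Known limitations

* The Stern–Volmer stage fits the linear model only; upward-curving plots
  (mixed quenching, sphere-of-action) are out of scope and will simply fit
  badly (low r) rather than be detected.
* The melting stage assumes a single two-state transition; multi-domain
  melting is not deconvolved.
* The classifier's equal-weight voting is a transparency choice, not a
  probability model; it reports counts, not confidence.
* SASA treats all atoms as spheres with element-default radii; no
  residue-specific radii sets are bundled.
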