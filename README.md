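# ctbind

Spectroscopic inference of how a small molecule binds double-stranded DNA.

Binding studies of ligands with calf-thymus DNA (ctDNA) rarely rest on a
single measurement: the binding mode — intercalation between base pairs,
lodging in a groove, or electrostatic association with the phosphate
backbone — is argued from a battery of bench experiments read through
standard equations. `ctbind` implements that entire inference chain as a
tested, reusable library and CLI for spectroscopists and food-safety /
toxicology groups who run these panels routinely:

* **Inner-filter correction** of fluorescence titrations,
  `F_corr = F_meas · e^((A_ex + A_em)/2)`.
* **Stern–Volmer analysis**: `F₀/F = 1 + K_sv[Q] = 1 + k_q τ₀ [Q]`, with the
  static/dynamic mechanism call from the temperature trend of K_sv and the
  diffusion limit k_q ≈ 2×10¹⁰ L mol⁻¹ s⁻¹.
* **Binding constant and stoichiometry** from the double-logarithm plot
  `log((F₀−F)/F) = n log K_a + n log([Q_t] − (F₀−F)[P_t]/F₀)`.
* **van't Hoff thermodynamics**: `log K_a = −ΔH°/(2.303 R T) + ΔS°/(2.303 R)`,
  `ΔG° = ΔH° − TΔS°`, and the driving-force verdict from the signs of
  ΔH°/ΔS°.
* **DNA melting**: single-strand fraction `f_ss = (A − A₂₀)/(A₁₀₀ − A₂₀)`,
  T_m at f_ss = 0.5, and the intercalation call from the T_m shift.
* **Viscosity**: `η = (t − t₀)/t₀` and the `(η/η₀)^(1/3)` vs [ligand]/[DNA]
  profile that separates intercalators from groove binders.
* **Binding-mode classifier**: equal-weight voting over up to ten lines of
  qualitative evidence (UV redshift, K_a magnitude, iodide quenching,
  ss/ds quenching, salt dependence, ΔT_m, viscosity class, CD perturbation,
  thermodynamic forces, gel cleavage) with a complete audit trail.
* **Trajectory observables**: standalone RMSD (weighted Kabsch
  superposition), per-atom RMSF, radius of gyration, and Shrake–Rupley
  SASA on a deterministic Fibonacci sphere lattice, for multi-MODEL PDB or
  XYZ ensembles.
* **Synthetic data**: every input above can be generated with known ground
  truth (1:1 mass-action titrations, logistic melting sigmoids, viscosity
  series, evidence vectors), so the pipeline is fully testable without
  instrument files.

## Worked example

The reference system shipped with the package is the plant growth regulator
indole-3-propionic acid (IPA) binding ctDNA. Simulate a titration with
K_a = 1.75×10⁴ L mol⁻¹, correct it, and fit:

```console
$ ctbind simulate titration --ka 17500 --out raw.csv
$ ctbind correct --in raw.csv --out corrected.csv
$ ctbind fit binding --in corrected.csv
Ka = 1.75e+04 L/mol  n = 1.000  r = 1.0000  (10 points)
```

The fit recovers the generator's association constant exactly (noiseless
run) with a binding-site number of 1, i.e. a 1:1 complex. Feeding the three
tabulated binding constants of the IPA–ctDNA system into the van't Hoff
stage:

```console
$ echo '{"298.15": 17500, "304.15": 16200, "310.15": 12700}' > ka.json
$ ctbind thermo --ka-json ka.json
dH = -20.47 kJ/mol  dS = 12.81 J/mol/K  forces: hydrogen_bond_and_hydrophobic
  dG(298.15 K) = -24.29 kJ/mol
  dG(304.15 K) = -24.36 kJ/mol
  dG(310.15 K) = -24.44 kJ/mol
```

A negative enthalpy with positive entropy means hydrogen bonding plus
hydrophobic contacts drive a spontaneous (ΔG° < 0) association. Melting
and mode classification:

```console
$ ctbind simulate melting --tm 83.5 --out free.csv
$ ctbind simulate melting --tm 81.1 --out complex.csv
$ ctbind melt --free free.csv --complex complex.csv
Tm(free) = 83.38 C  Tm(complex) = 81.19 C  dTm = -2.19 C  -> non_intercalative

$ ctbind simulate evidence --out evidence.json
$ ctbind classify --evidence evidence.json
mode: groove  votes: {'intercalation': 0, 'groove': 8, 'electrostatic': -1}
  ...
```

The slightly *lower* T_m of the complex rules out intercalative
stabilisation, and the full evidence vector votes 8–0 for groove binding
(salt independence additionally counts *against* electrostatics), with each
vote traced to its rule in the printed audit trail.

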