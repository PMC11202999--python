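"""Synthetic inputs with known ground truth for every pipeline stage.

The generators emulate the bench experiments the pipeline analyses:

* a 1:1 mass-action fluorescence titration with a completely dark complex
  (static quenching), inner-filter attenuation that the correction stage can
  undo, and seeded multiplicative noise;
* a two-state logistic melting sigmoid sampled on the conventional
  20-100 C / 5 C grid;
* Ubbelohde flow-time series whose cube-root viscosity profile rises with
  the slope of an intercalator or stays flat like a groove binder;
* the qualitative evidence vector reported for the indole-3-propionic
  acid / calf-thymus-DNA system, used as the reference fixture for the
  binding-mode classifier.

All randomness flows through ``numpy.random.default_rng(seed)``: a fixed
seed reproduces any synthetic campaign bit-exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit

from ctbind.core_io import (
    MeltingCurve,
    TitrationPoint,
    TitrationSeries,
    ViscositySeries,
)
from ctbind.correction import inner_filter_factor
from ctbind.errors import ValidationError
from ctbind.mode_classifier import EvidenceSet

#: Default titration design: fluorophore at 3.28e-6 mol/L titrated with DNA
#: up to ~1.1e-4 mol/L over 11 points (fluorophore dilution neglected).
DEFAULT_LIGAND_CONC = 3.28e-6
DEFAULT_QUENCHER_MAX = 1.1e-4
DEFAULT_GRID_POINTS = 11

#: Effective molar attenuation (L mol^-1 cm^-1) of the DNA titrant at the
#: excitation (282 nm) and emission (367 nm) wavelengths, used to emulate
#: inner-filter absorbances growing with titrant concentration.
EPSILON_EX = 2000.0
EPSILON_EM = 100.0

#: Cube-root viscosity profile slopes per unit [ligand]/[DNA] ratio.
VISCOSITY_SLOPES = {"intercalative": 0.25, "groove": 0.01}
DEFAULT_DNA_CONC_VISC = 2.73e-5


@dataclass
class TitrationGroundTruth:
    """Known parameters behind a simulated titration.

    ``n`` = 1 uses exact 1:1 mass action; other values are produced by
    inverting the double-log relation per point (phenomenological, since a
    non-integer site number has no single-step mechanism).
    """

    ka: float
    n: float = 1.0
    f0: float = 1000.0
    ligand_conc: float = DEFAULT_LIGAND_CONC
    quencher_grid: Optional[Sequence[float]] = None
    inner_filter_per_point: Optional[Sequence[tuple]] = None
    noise_sd_fraction: float = 0.0
    seed: int = 0
    temperature: float = 298.15

    def __post_init__(self) -> None:
        if self.ka < 0:
            raise ValidationError("ka must be non-negative")
        if self.noise_sd_fraction < 0:
            raise ValidationError("noise_sd_fraction must be >= 0")
        if self.quencher_grid is None:
            self.quencher_grid = np.linspace(
                0.0, DEFAULT_QUENCHER_MAX, DEFAULT_GRID_POINTS
            ).tolist()
        if self.quencher_grid[0] != 0:
            raise ValidationError("quencher_grid must start at 0")
        if self.inner_filter_per_point is None:
            self.inner_filter_per_point = [
                (EPSILON_EX * q, EPSILON_EM * q) for q in self.quencher_grid
            ]
        if len(self.inner_filter_per_point) != len(self.quencher_grid):
            raise ValidationError(
                "inner_filter_per_point must match quencher_grid length"
            )


def complex_concentration(ka: float, p_total: float, q_total: float) -> float:
    """Exact 1:1 complex concentration from the mass-action quadratic.

    Root of ka*(P-C)*(Q-C) = C with 0 <= C <= min(P, Q).
    """
    if ka == 0 or p_total == 0 or q_total == 0:
        return 0.0
    s = p_total + q_total + 1.0 / ka
    disc = s * s - 4.0 * p_total * q_total
    assert disc >= 0, "mass-action discriminant must be non-negative"
    return (s - np.sqrt(disc)) / 2.0


def _bound_fraction(truth: TitrationGroundTruth, q_total: float) -> float:
    """Fraction of fluorophore quenched at one titration point."""
    p = truth.ligand_conc
    if q_total == 0 or truth.ka == 0:
        return 0.0
    if truth.n == 1.0:
        return complex_concentration(truth.ka, p, q_total) / p
    # phenomenological inversion of the double-log relation:
    # b/(1-b) = (ka * (q_total - b*p))**n  with 0 < b < min(1, q_total/p)
    upper = min(1.0, q_total / p)

    def g(b: float) -> float:
        free_q = q_total - b * p
        return np.log(b / (1.0 - b)) - truth.n * np.log(truth.ka * free_q)

    lo, hi = 1e-15, upper - 1e-15
    return brentq(g, lo, hi, xtol=1e-15, rtol=1e-14)


def simulate_titration(truth: TitrationGroundTruth) -> TitrationSeries:
    """Generate a measured titration series from known ground truth.

    The true intensity is f0*(1 - bound_fraction) (the complex is dark);
    the recorded value is divided by the inner-filter factor — so that the
    correction stage restores the truth — and then multiplied by
    (1 + noise_sd_fraction * N(0, 1)) with the stated seed.
    """
    rng = np.random.default_rng(truth.seed)
    points = []
    for q_total, (a_ex, a_em) in zip(
        truth.quencher_grid, truth.inner_filter_per_point
    ):
        f_true = truth.f0 * (1.0 - _bound_fraction(truth, q_total))
        f_measured = f_true / inner_filter_factor(a_ex, a_em)
        if truth.noise_sd_fraction > 0:
            f_measured *= 1.0 + truth.noise_sd_fraction * rng.standard_normal()
            f_measured = max(f_measured, 1e-12)
        points.append(
            TitrationPoint(
                quencher_conc=float(q_total),
                f_measured=float(f_measured),
                a_ex=float(a_ex),
                a_em=float(a_em),
            )
        )
    return TitrationSeries(
        points=points,
        temperature=truth.temperature,
        ligand_conc=truth.ligand_conc,
        label=f"synthetic ka={truth.ka:g} n={truth.n:g} seed={truth.seed}",
    )


def simulate_melting(
    tm: float,
    width: float,
    a20: float = 0.5,
    a100: float = 1.0,
    sample_interval: float = 5.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> MeltingCurve:
    """Two-state logistic melting curve sampled over 20-100 C.

    A(T) = a20 + (a100 - a20) * logistic((T - tm)/width) plus seeded
    Gaussian absorbance noise.  ``width`` is the logistic scale in Celsius;
    hyperchromic melting requires a100 > a20.
    """
    if width <= 0:
        raise ValidationError("width must be positive")
    if a100 <= a20:
        raise ValidationError("hyperchromic melting requires a100 > a20")
    rng = np.random.default_rng(seed)
    temperatures = np.arange(20.0, 100.0 + 1e-9, sample_interval)
    absorbances = a20 + (a100 - a20) * expit((temperatures - tm) / width)
    if noise_sd > 0:
        absorbances = absorbances + rng.normal(0.0, noise_sd, absorbances.shape)
    return MeltingCurve(
        temperatures=temperatures.tolist(),
        absorbances=absorbances.tolist(),
        label=f"synthetic tm={tm:g} width={width:g} seed={seed}",
    )


def simulate_viscosity(
    mode: str,
    buffer_time: float = 100.0,
    base_eta: float = 0.5,
    ratios: Optional[Sequence[float]] = None,
    seed: int = 0,
    jitter_s: float = 0.0,
    dna_conc: float = DEFAULT_DNA_CONC_VISC,
) -> ViscositySeries:
    """Flow-time series with an intercalative or groove cube-root profile.

    The target ordinate is (eta/eta0)^(1/3) = 1 + slope*ratio with slope
    0.25 (intercalative) or 0.01 (groove); flow times are back-computed from
    the eta profile and jittered by at most ``jitter_s`` seconds (seeded,
    capped at 0.2 s).
    """
    if mode not in VISCOSITY_SLOPES:
        raise ValidationError(f"mode must be one of {sorted(VISCOSITY_SLOPES)}")
    if ratios is None:
        ratios = np.linspace(0.0, 1.2, 11)
    ratios = np.asarray(ratios, dtype=float)
    if ratios[0] != 0:
        raise ValidationError("ratios must start at 0")
    jitter_s = min(jitter_s, 0.2)
    rng = np.random.default_rng(seed)
    ordinates = 1.0 + VISCOSITY_SLOPES[mode] * ratios
    etas = base_eta * ordinates**3
    flow_times = buffer_time * (1.0 + etas)
    if jitter_s > 0:
        jitter = rng.uniform(-jitter_s, jitter_s, flow_times.shape)
        jitter[0] = 0.0  # keep the ligand-free reference exact
        flow_times = flow_times + jitter
    return ViscositySeries(
        buffer_time=buffer_time,
        flow_times=flow_times.tolist(),
        ligand_concs=(ratios * dna_conc).tolist(),
        dna_conc=dna_conc,
    )


def make_reference_evidence() -> EvidenceSet:
    """The evidence vector reported for indole-3-propionic acid with ctDNA.

    Small (2 nm) UV redshift, Ka of 1.75e4 L/mol, equivalent iodide
    quenching of free and bound ligand, stronger quenching by single- than
    double-stranded DNA (Ksv 5.09e3 vs 3.55e3), no salt dependence, a
    -2.4 C melting shift, a flat viscosity profile, slight CD perturbation,
    enthalpy/entropy signs pointing to hydrogen bonding plus hydrophobic
    contacts, and no plasmid cleavage.
    """
    return EvidenceSet(
        redshift_nm=2.0,
        ka=1.75e4,
        ki_equivalence="equivalent",
        ss_over_ds_ksv=5.09e3 / 3.55e3,
        salt_effect="none",
        delta_tm=-2.4,
        viscosity_class="non_intercalative",
        cd_perturbation="slight",
        force_verdict="hydrogen_bond_and_hydrophobic",
        gel_cleavage="none",
    )
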