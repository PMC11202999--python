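"""Binding constant, stoichiometry and van't Hoff thermodynamics.

For a fluorophore P quenched by formation of a non-fluorescent 1:1 complex
with DNA (total concentration [Q_t]), the double-logarithm analysis

    log10((F0 - F)/F) = n*log10(Ka) + n*log10([Q_t] - (F0 - F)[P_t]/F0)

yields the association constant Ka (L mol^-1) from the intercept and the
binding-site number n from the slope.  The abscissa term is the free DNA
concentration: (F0 - F)[P_t]/F0 is the amount of ligand bound (and hence
DNA consumed) when the complex is dark.

The temperature dependence of Ka gives the binding enthalpy and entropy via
the linear van't Hoff relation

    log10(Ka) = -dH/(2.303*R*T) + dS/(2.303*R)

and the Gibbs energy via dG = dH - T*dS.  The sign pattern of (dH, dS)
identifies the dominant driving force: dH < 0 with dS > 0 points to a mix
of hydrogen bonding and hydrophobic contacts, dH > 0 with dS > 0 to
hydrophobic burial, dH < 0 with dS < 0 to hydrogen bonds plus van der
Waals packing, and a near-zero enthalpy with positive entropy to
electrostatics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np

from ctbind.core_io import AnalysisConfig, TitrationSeries
from ctbind.errors import InsufficientDataError, ValidationError
from ctbind.quenching import _ols

#: Exact base-10 conversion factor (conventionally printed as 2.303).
LOG10_FACTOR = math.log(10.0)

#: |dH| below this (kJ mol^-1) counts as "approximately zero" for the
#: electrostatic driving-force rule.
ELECTROSTATIC_DH_BAND = 4.0


@dataclass
class BindingFitResult:
    """Double-log fit at one temperature: Ka (L mol^-1), site number n."""

    ka: float
    n: float
    r: float
    temperature: float
    n_points_used: int


@dataclass
class ThermoResult:
    """van't Hoff thermodynamics of the binding equilibrium.

    ``delta_h`` in kJ mol^-1, ``delta_s`` in J mol^-1 K^-1 and
    ``delta_g_by_temperature`` mapping each input temperature (K) to
    dG = dH - T*dS/1000 in kJ mol^-1.
    """

    delta_h: float
    delta_s: float
    delta_g_by_temperature: dict
    fit_r: float
    force_verdict: str


def binding_fit(series: TitrationSeries) -> BindingFitResult:
    """Fit Ka and n from the double-logarithm plot.

    Points with zero quencher, F >= F0, or a non-positive free-quencher term
    [Q_t] - (F0 - F)[P_t]/F0 are excluded (and counted); at least three
    usable points are required.
    """
    f0 = series.f0
    pt = series.ligand_conc
    xs, ys = [], []
    excluded = {"zero_quencher": 0, "no_quenching": 0, "nonpositive_free_dna": 0}
    for point in series.points:
        if point.quencher_conc == 0:
            excluded["zero_quencher"] += 1
            continue
        f = point.fluorescence
        if f >= f0:
            excluded["no_quenching"] += 1
            continue
        bound = (f0 - f) * pt / f0
        free_q = point.quencher_conc - bound
        if free_q <= 0:
            excluded["nonpositive_free_dna"] += 1
            continue
        ys.append(math.log10((f0 - f) / f))
        xs.append(math.log10(free_q))
    if len(xs) < 3:
        detail = ", ".join(f"{k}={v}" for k, v in excluded.items() if v)
        raise InsufficientDataError(
            f"double-log fit needs >= 3 usable points, got {len(xs)}"
            + (f" (excluded: {detail})" if detail else "")
        )
    slope, intercept, r, _ = _ols(np.array(xs), np.array(ys))
    if slope <= 0:
        raise ValidationError(
            f"double-log slope (binding-site number) is non-positive: {slope}"
        )
    return BindingFitResult(
        ka=10.0 ** (intercept / slope),
        n=slope,
        r=r,
        temperature=series.temperature,
        n_points_used=len(xs),
    )


def gibbs(delta_h: float, delta_s: float, temperature: float) -> float:
    """Gibbs energy dG = dH - T*dS (dH in kJ mol^-1, dS in J mol^-1 K^-1)."""
    if temperature <= 0:
        raise ValidationError("temperature must be positive")
    return delta_h - temperature * delta_s / 1000.0


def classify_forces(delta_h: float, delta_s: float) -> str:
    """Assign the dominant driving force from the signs of dH and dS.

    A near-zero enthalpy (|dH| < 4 kJ mol^-1) with positive entropy is
    checked first and read as electrostatic; otherwise the sign pattern
    decides as described in the module docstring.
    """
    if abs(delta_h) < ELECTROSTATIC_DH_BAND and delta_s > 0:
        return "electrostatic"
    if delta_h < 0 and delta_s > 0:
        return "hydrogen_bond_and_hydrophobic"
    if delta_h > 0 and delta_s > 0:
        return "hydrophobic"
    if delta_h < 0 and delta_s < 0:
        return "hbond_vdw"
    return "indeterminate"


def vant_hoff(
    ka_by_temperature: Mapping[float, float],
    config: Optional[AnalysisConfig] = None,
) -> ThermoResult:
    """Linear van't Hoff fit of log10(Ka) against 1/T.

    dH = -2.303*R*slope (reported in kJ mol^-1) and dS = 2.303*R*intercept
    (J mol^-1 K^-1); dG is evaluated at every input temperature.  With
    exactly two temperatures the fit reduces to the closed form
    dH = -R*ln(K2/K1)/(1/T2 - 1/T1).
    """
    config = config or AnalysisConfig()
    if len(ka_by_temperature) < 2:
        raise InsufficientDataError(
            "van't Hoff analysis needs Ka at >= 2 temperatures"
        )
    temperatures = np.array(sorted(ka_by_temperature), dtype=float)
    ka = np.array([ka_by_temperature[t] for t in temperatures], dtype=float)
    if np.any(temperatures <= 0):
        raise ValidationError("temperatures must be positive (kelvin)")
    if np.any(ka <= 0):
        raise ValidationError("all Ka values must be positive")
    slope, intercept, r, _ = _ols(1.0 / temperatures, np.log10(ka))
    delta_h = -LOG10_FACTOR * config.gas_constant * slope / 1000.0  # kJ/mol
    delta_s = LOG10_FACTOR * config.gas_constant * intercept  # J/mol/K
    delta_g = {
        float(t): gibbs(delta_h, delta_s, float(t)) for t in temperatures
    }
    return ThermoResult(
        delta_h=delta_h,
        delta_s=delta_s,
        delta_g_by_temperature=delta_g,
        fit_r=r,
        force_verdict=classify_forces(delta_h, delta_s),
    )
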