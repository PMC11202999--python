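"""Relative viscosity and the cube-root profile that flags intercalation.

Intercalation separates adjacent base pairs and lengthens the duplex, which
raises the relative specific viscosity of a DNA solution; groove and
electrostatic binders leave the contour length — and hence the viscosity —
essentially unchanged.  Flow times t through an Ubbelohde capillary give
eta = (t - t0)/t0 against the buffer time t0, and the discriminating plot
is (eta/eta0)^(1/3) versus the [ligand]/[DNA] ratio, linear in contour
length by the classical rod model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from ctbind.core_io import ViscositySeries
from ctbind.errors import ValidationError
from ctbind.quenching import _ols

#: Slope of (eta/eta0)^(1/3) per unit concentration ratio above which the
#: rise is called intercalative; classical intercalators roughly double the
#: viscosity over a 0-1 ratio range while groove binders stay nearly flat.
INTERCALATION_SLOPE_THRESHOLD = 0.1


@dataclass
class ViscosityResult:
    """Cube-root viscosity profile and its linear slope."""

    eta0: float
    profile: list  # ([ligand]/[DNA] ratio, (eta/eta0)^(1/3)) pairs
    slope: float
    viscosity_class: str  # "intercalative" | "non_intercalative"


def relative_viscosity(flow_time: float, buffer_time: float) -> float:
    """Relative specific viscosity eta = (t - t0)/t0."""
    if flow_time <= 0 or buffer_time <= 0:
        raise ValidationError("flow times must be positive")
    if flow_time <= buffer_time:
        raise ValidationError(
            "flow_time must exceed buffer_time: a polymer solution cannot "
            "flow faster than the buffer"
        )
    return (flow_time - buffer_time) / buffer_time


def viscosity_profile(series: ViscositySeries) -> ViscosityResult:
    """Build the (eta/eta0)^(1/3) versus [ligand]/[DNA] profile and classify.

    The first entry must be the ligand-free solution (defines eta0, ordinate
    exactly 1).  The profile slope comes from ordinary least squares and the
    run is called intercalative iff it reaches the threshold slope.
    """
    if len(series.flow_times) < 3:
        raise ValidationError("viscosity profile needs >= 3 entries")
    if series.ligand_concs[0] != 0:
        raise ValidationError(
            "first entry must have ligand_conc = 0 (defines eta0)"
        )
    etas = np.array(
        [relative_viscosity(t, series.buffer_time) for t in series.flow_times]
    )
    eta0 = etas[0]
    ratios = np.asarray(series.ligand_concs, dtype=float) / series.dna_conc
    ordinates = np.cbrt(etas / eta0)
    slope, _, _, _ = _ols(ratios, ordinates)
    viscosity_class = (
        "intercalative"
        if slope >= INTERCALATION_SLOPE_THRESHOLD
        else "non_intercalative"
    )
    return ViscosityResult(
        eta0=float(eta0),
        profile=list(zip(ratios.tolist(), ordinates.tolist())),
        slope=slope,
        viscosity_class=viscosity_class,
    )
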