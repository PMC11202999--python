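"""Inner-filter correction of measured fluorescence.

At finite chromophore absorbance part of the excitation beam is attenuated
before reaching the observation volume and part of the emitted light is
reabsorbed on the way out.  The standard first-order correction restores the
true intensity as

    F_corrected = F_measured * exp((A_ex + A_em) / 2)

where A_ex and A_em are the sample absorbances at the excitation and
emission wavelengths.  The correction is only trustworthy at moderate
absorbance; values above ~0.3 are flagged with a warning.
"""

from __future__ import annotations

import dataclasses
import logging
import math

from ctbind.core_io import TitrationSeries
from ctbind.errors import ValidationError

logger = logging.getLogger("ctbind")

#: Absorbance above which the first-order correction becomes unreliable.
ABSORBANCE_WARNING_THRESHOLD = 0.3


def inner_filter_factor(a_ex: float, a_em: float) -> float:
    """Multiplicative correction factor exp((a_ex + a_em)/2)."""
    return math.exp((a_ex + a_em) / 2.0)


def apply_inner_filter(series: TitrationSeries) -> TitrationSeries:
    """Return a new series with ``f_corrected`` filled on every point.

    Every point must carry both absorbances; point order, concentrations and
    raw intensities are unchanged.  Raises :class:`ValidationError` naming
    the first point that lacks an absorbance.
    """
    corrected_points = []
    for index, point in enumerate(series.points):
        if point.a_ex is None or point.a_em is None:
            raise ValidationError(
                f"point {index} is missing absorbances (a_ex/a_em); "
                "inner-filter correction requires both"
            )
        if max(point.a_ex, point.a_em) > ABSORBANCE_WARNING_THRESHOLD:
            logger.warning(
                "point %d has absorbance above %.2f; the first-order "
                "inner-filter correction may be inaccurate",
                index,
                ABSORBANCE_WARNING_THRESHOLD,
            )
        corrected_points.append(
            dataclasses.replace(
                point,
                f_corrected=point.f_measured
                * inner_filter_factor(point.a_ex, point.a_em),
            )
        )
    return dataclasses.replace(series, points=corrected_points)
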