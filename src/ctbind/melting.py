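"""DNA melting-curve normalization and melting-temperature extraction.

Thermal denaturation is followed by the hyperchromic rise of the 258 nm
absorbance.  The curve is normalized to the single-strand fraction

    fss(T) = (A(T) - A_low) / (A_high - A_low)

using the readings closest to 20 and 100 degrees C as the folded and
denatured baselines, and the melting temperature Tm is the temperature at
which fss first crosses 0.5 on the way up (linear interpolation between the
bracketing samples).  A melting-temperature increase of about 5 degrees C
or more on complexation signals intercalative stabilisation of the duplex;
smaller or negative shifts are consistent with groove or external binding.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from ctbind.core_io import AnalysisConfig, MeltingCurve
from ctbind.errors import DegenerateCurveError, ValidationError


@dataclass
class MeltingResult:
    """Normalized melting curve and extracted melting temperature (Celsius)."""

    tm: Optional[float]
    fss: list  # (temperature_C, single-strand fraction) pairs
    delta_tm: Optional[float] = None  # complex minus free, degrees C
    shift_class: str = "unassigned"


def compute_fss(curve: MeltingCurve) -> MeltingResult:
    """Normalize a melting curve to single-strand fractions.

    The baselines A_low/A_high are the absorbances at the readings closest
    to 20 and 100 degrees C, so fss is exactly 0 and 1 at those points.
    """
    t = np.asarray(curve.temperatures, dtype=float)
    a = np.asarray(curve.absorbances, dtype=float)
    a_low = a[np.argmin(np.abs(t - 20.0))]
    a_high = a[np.argmin(np.abs(t - 100.0))]
    if a_high == a_low:
        raise DegenerateCurveError(
            "flat melting curve: identical absorbance at the 20 and "
            "100 degree C baselines"
        )
    fss = (a - a_low) / (a_high - a_low)
    return MeltingResult(tm=None, fss=list(zip(t.tolist(), fss.tolist())))


def melting_temperature(result: MeltingResult) -> float:
    """Tm from the first upward crossing of fss = 0.5 (linear interpolation).

    Also stores the value on ``result.tm``.  Raises if the normalized curve
    never brackets 0.5 from below.
    """
    pairs = result.fss
    for (t_lo, f_lo), (t_hi, f_hi) in zip(pairs, pairs[1:]):
        if f_lo == 0.5:
            result.tm = float(t_lo)
            return result.tm
        if f_lo < 0.5 <= f_hi:
            tm = t_lo + (0.5 - f_lo) * (t_hi - t_lo) / (f_hi - f_lo)
            result.tm = float(tm)
            return result.tm
    raise ValidationError("curve does not bracket Tm (no upward 0.5 crossing)")


def tm_shift(
    free: MeltingResult,
    complexed: MeltingResult,
    config: Optional[AnalysisConfig] = None,
) -> MeltingResult:
    """Fill ``delta_tm`` (complex minus free) and its class on the complex result."""
    if free.tm is None:
        melting_temperature(free)
    if complexed.tm is None:
        melting_temperature(complexed)
    complexed.delta_tm = complexed.tm - free.tm
    complexed.shift_class = classify_tm_shift(complexed.delta_tm, config)
    return complexed


def classify_tm_shift(
    delta_tm: float, config: Optional[AnalysisConfig] = None
) -> str:
    """"intercalative" iff the Tm shift reaches the threshold (default +5 C)."""
    config = config or AnalysisConfig()
    if delta_tm >= config.tm_intercalation_shift:
        return "intercalative"
    return "non_intercalative"
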