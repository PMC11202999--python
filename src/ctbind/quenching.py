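"""Stern-Volmer quenching analysis and mechanism classification.

The Stern-Volmer relation F0/F = 1 + Ksv[Q] = 1 + kq*tau0*[Q] links the
drop of fluorophore intensity F at quencher concentration [Q] to the
quenching constant Ksv (L mol^-1) and, through the excited-state lifetime
tau0, to the bimolecular quenching rate constant kq (L mol^-1 s^-1).

Mechanism discrimination uses two classical signatures: static quenching
(ground-state complex formation) shows Ksv falling with temperature and an
apparent kq far above the diffusion-controlled collisional limit
(~2e10 L mol^-1 s^-1), while dynamic (collisional) quenching shows the
opposite trend with kq at or below that limit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from ctbind.core_io import AnalysisConfig, TitrationSeries
from ctbind.errors import InsufficientDataError, ValidationError


@dataclass
class SternVolmerResult:
    """Linear Stern-Volmer fit at one temperature.

    ``ksv`` and ``ksv_stderr`` in L mol^-1, ``kq = ksv / tau0`` in
    L mol^-1 s^-1, ``r`` the Pearson correlation of the regression.
    """

    ksv: float
    ksv_stderr: float
    intercept: float
    r: float
    kq: float
    temperature: float


@dataclass
class MechanismVerdict:
    """Quenching mechanism inferred from the temperature trend of Ksv."""

    mechanism: str  # "static" | "dynamic" | "indeterminate"
    ksv_trend: str  # "decreasing" | "increasing" | "flat"
    kq_exceeds_diffusion_limit: bool
    note: str = ""


@dataclass
class QuenchingComparison:
    """Outcome of comparing two Stern-Volmer constants."""

    verdict: str  # "equivalent" | "a_greater" | "b_greater"
    ratio: float
    difference: float
    equivalence_band: float


def _ols(x: np.ndarray, y: np.ndarray):
    """Ordinary least squares returning (slope, intercept, r, slope_stderr).

    Degenerate responses (zero variance in y) yield a flat line with r = 0
    rather than a NaN correlation.
    """
    if np.ptp(y) == 0.0:
        return 0.0, float(y[0]), 0.0, 0.0
    fit = stats.linregress(x, y)
    return float(fit.slope), float(fit.intercept), float(fit.rvalue), float(fit.stderr)


def stern_volmer_fit(
    series: TitrationSeries, config: Optional[AnalysisConfig] = None
) -> SternVolmerResult:
    """Fit F0/F versus [Q] by unweighted ordinary least squares.

    F0 is the fluorescence of the zero-quencher point; corrected intensities
    are used whenever the correction stage has filled them.  The slope is
    Ksv and kq = Ksv / tau0.
    """
    config = config or AnalysisConfig()
    if len(series) < 3:
        raise InsufficientDataError(
            f"Stern-Volmer fit needs >= 3 points, got {len(series)}"
        )
    f = np.array([p.fluorescence for p in series.points], dtype=float)
    if np.any(f <= 0):
        raise ValidationError("all fluorescence intensities must be positive")
    q = np.array([p.quencher_conc for p in series.points], dtype=float)
    ratio = series.f0 / f
    slope, intercept, r, stderr = _ols(q, ratio)
    return SternVolmerResult(
        ksv=slope,
        ksv_stderr=stderr,
        intercept=intercept,
        r=r,
        kq=slope / config.tau0,
        temperature=series.temperature,
    )


def _trend(values: Sequence[float]) -> str:
    diffs = np.diff(values)
    if len(diffs) and np.all(diffs < 0):
        return "decreasing"
    if len(diffs) and np.all(diffs > 0):
        return "increasing"
    return "flat"


def classify_mechanism(
    results_by_temperature: Sequence[SternVolmerResult],
    config: Optional[AnalysisConfig] = None,
) -> MechanismVerdict:
    """Classify quenching as static, dynamic or indeterminate.

    Static: Ksv strictly decreasing with temperature and every kq above the
    diffusion limit.  Dynamic: Ksv strictly increasing and every kq at or
    below the limit.  Anything else (including a single temperature) is
    indeterminate.  Trends are judged on point estimates only.
    """
    config = config or AnalysisConfig()
    results = sorted(results_by_temperature, key=lambda res: res.temperature)
    if not results:
        raise InsufficientDataError("no Stern-Volmer results supplied")
    kq_values = [res.kq for res in results]
    exceeds = all(kq > config.kq_static_threshold for kq in kq_values)
    if len(results) == 1:
        return MechanismVerdict(
            mechanism="indeterminate",
            ksv_trend="flat",
            kq_exceeds_diffusion_limit=exceeds,
            note="single temperature: the Ksv trend cannot be assessed",
        )
    trend = _trend([res.ksv for res in results])
    below = all(kq <= config.kq_static_threshold for kq in kq_values)
    if trend == "decreasing" and exceeds:
        mechanism = "static"
    elif trend == "increasing" and below:
        mechanism = "dynamic"
    else:
        mechanism = "indeterminate"
    return MechanismVerdict(
        mechanism=mechanism,
        ksv_trend=trend,
        kq_exceeds_diffusion_limit=exceeds,
    )


def compare_quenching(
    result_a: SternVolmerResult, result_b: SternVolmerResult
) -> QuenchingComparison:
    """Compare two Ksv values within a 2-combined-standard-error band.

    The constants are "equivalent" when |Ksv_a - Ksv_b| does not exceed
    twice the sum of their standard errors; otherwise the larger one wins
    the verdict.  The ratio Ksv_a / Ksv_b is always reported.
    """
    band = 2.0 * (result_a.ksv_stderr + result_b.ksv_stderr)
    difference = result_a.ksv - result_b.ksv
    if abs(difference) <= band:
        verdict = "equivalent"
    elif difference > 0:
        verdict = "a_greater"
    else:
        verdict = "b_greater"
    ratio = result_a.ksv / result_b.ksv if result_b.ksv != 0 else math.inf
    return QuenchingComparison(
        verdict=verdict,
        ratio=ratio,
        difference=difference,
        equivalence_band=band,
    )
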