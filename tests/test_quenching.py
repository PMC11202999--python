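"""Stern-Volmer fitting, mechanism rules and Ksv comparisons."""

import numpy as np
import pytest

from ctbind.core_io import AnalysisConfig, TitrationPoint, TitrationSeries
from ctbind.errors import InsufficientDataError, ValidationError
from ctbind.quenching import (
    SternVolmerResult,
    classify_mechanism,
    compare_quenching,
    stern_volmer_fit,
)
from ctbind.synthetic_data import TitrationGroundTruth, simulate_titration


def _sv_result(ksv, temperature, stderr=0.0, tau0=1e-8):
    return SternVolmerResult(
        ksv=ksv,
        ksv_stderr=stderr,
        intercept=1.0,
        r=1.0,
        kq=ksv / tau0,
        temperature=temperature,
    )


def _linear_quench_series(ksv, f0=1000.0, qmax=3.23e-2, n_points=11):
    """Series obeying F = F0/(1 + ksv*[Q]) exactly."""
    grid = np.linspace(0.0, qmax, n_points)
    points = [
        TitrationPoint(float(q), float(f0 / (1.0 + ksv * q))) for q in grid
    ]
    return TitrationSeries(points=points, temperature=298.15, ligand_conc=2.46e-6)


def test_noiseless_linear_series_recovers_ksv_exactly():
    series = _linear_quench_series(ksv=3.55e3)
    result = stern_volmer_fit(series)
    assert result.ksv == pytest.approx(3.55e3, rel=1e-12)
    assert result.intercept == pytest.approx(1.0, rel=1e-12)
    assert result.r == pytest.approx(1.0, abs=1e-12)


def test_kq_is_ksv_over_tau0():
    series = _linear_quench_series(ksv=3.55e3)
    result = stern_volmer_fit(series)
    assert result.kq == pytest.approx(3.55e11, rel=1e-12)
    # kq scales inversely with tau0: halving tau0 doubles kq
    half = stern_volmer_fit(series, AnalysisConfig(tau0=0.5e-8))
    assert half.kq == pytest.approx(2 * result.kq, rel=1e-12)


def test_constant_fluorescence_gives_zero_slope_flat_trend():
    points = [
        TitrationPoint(float(q), 500.0) for q in np.linspace(0, 1e-2, 6)
    ]
    series = TitrationSeries(points=points, temperature=298.15, ligand_conc=1e-6)
    result = stern_volmer_fit(series)
    assert result.ksv == 0.0
    verdict = classify_mechanism([result, _sv_result(0.0, 310.15)])
    assert verdict.ksv_trend == "flat"
    assert verdict.mechanism == "indeterminate"


def test_too_few_points_rejected():
    points = [TitrationPoint(0.0, 100.0), TitrationPoint(1e-3, 90.0)]
    series = TitrationSeries(points=points, temperature=298.15, ligand_conc=1e-6)
    with pytest.raises(InsufficientDataError):
        stern_volmer_fit(series)


def test_weak_binding_limit_ksv_approaches_ka():
    """1:1 equilibrium simulator with Ka*[P_t] << 1: fitted Ksv -> Ka within 1%."""
    truth = TitrationGroundTruth(
        ka=3.55e3,
        ligand_conc=3.28e-6,
        quencher_grid=np.linspace(0, 3.23e-2, 11).tolist(),
        inner_filter_per_point=[(0.0, 0.0)] * 11,
    )
    result = stern_volmer_fit(simulate_titration(truth))
    assert result.ksv == pytest.approx(3.55e3, rel=0.01)


def test_table_trend_classifies_static():
    """Decreasing Ksv with temperature and kq far above the collisional
    limit is the static-quenching signature."""
    results = [
        _sv_result(3.55e3, 298.15),
        _sv_result(3.39e3, 304.15),
        _sv_result(3.16e3, 310.15),
    ]
    verdict = classify_mechanism(results)
    assert verdict.mechanism == "static"
    assert verdict.ksv_trend == "decreasing"
    assert verdict.kq_exceeds_diffusion_limit


def test_increasing_trend_below_limit_is_dynamic():
    results = [
        _sv_result(1.0e2, 298.15),
        _sv_result(1.2e2, 304.15),
        _sv_result(1.4e2, 310.15),
    ]
    verdict = classify_mechanism(results)
    assert verdict.mechanism == "dynamic"
    assert not verdict.kq_exceeds_diffusion_limit


def test_non_monotone_trend_is_indeterminate():
    results = [
        _sv_result(3.0e3, 298.15),
        _sv_result(3.5e3, 304.15),
        _sv_result(3.2e3, 310.15),
    ]
    assert classify_mechanism(results).mechanism == "indeterminate"


def test_single_temperature_gives_note_not_error():
    verdict = classify_mechanism([_sv_result(3.55e3, 298.15)])
    assert verdict.mechanism == "indeterminate"
    assert "single temperature" in verdict.note


def test_iodide_quenching_free_vs_bound_equivalent():
    """Free-ligand and complex Ksv within the 2-combined-stderr band."""
    free = _sv_result(8.76, 298.15, stderr=0.21)
    bound = _sv_result(8.70, 298.15, stderr=0.12)
    comparison = compare_quenching(free, bound)
    assert comparison.verdict == "equivalent"


def test_single_vs_double_stranded_comparison():
    ds = _sv_result(3.55e3, 298.15, stderr=0.06e3)
    ss = _sv_result(5.09e3, 298.15, stderr=0.08e3)
    comparison = compare_quenching(ds, ss)
    assert comparison.verdict == "b_greater"
    assert comparison.ratio == pytest.approx(0.698, abs=1e-3)


def test_identical_results_are_equivalent_with_unit_ratio():
    a = _sv_result(1.0e3, 298.15, stderr=0.0)
    comparison = compare_quenching(a, a)
    assert comparison.verdict == "equivalent"
    assert comparison.ratio == 1.0
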