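"""CSV/JSON round-trips, metadata parsing and type invariants."""

import math

import pytest

from ctbind.core_io import (
    AnalysisConfig,
    MeltingCurve,
    TitrationPoint,
    TitrationSeries,
    ViscositySeries,
    celsius_to_kelvin,
    read_melting_csv,
    read_result_json,
    read_titration_csv,
    read_viscosity_csv,
    write_melting_csv,
    write_result_json,
    write_titration_csv,
    write_viscosity_csv,
)
from ctbind.errors import ValidationError
from ctbind.quenching import SternVolmerResult

TITRATION_CSV = """\
# temperature_K=298.15
# ligand_conc_M=3.28e-06
quencher_mol_per_L,F_measured,A_ex,A_em
0.0,1000.0,0.0,0.0
0.0033,912.0,0.05,0.01
0.0066,840.0,0.1,0.02
0.0099,778.0,0.15,0.03
0.0132,724.0,0.2,0.04
0.0164,679.0,0.25,0.05
0.0196,639.0,0.3,0.06
0.0228,603.0,0.35,0.07
0.026,571.0,0.4,0.08
0.0291,543.0,0.45,0.09
0.0323,517.0,0.5,0.1
"""


@pytest.fixture
def titration_path(tmp_path):
    path = tmp_path / "titration.csv"
    path.write_text(TITRATION_CSV)
    return path


def test_read_titration_echoes_input(titration_path):
    series = read_titration_csv(titration_path)
    assert len(series) == 11
    assert series.f0 == 1000.0
    assert series.temperature == 298.15
    assert series.ligand_conc == 3.28e-6
    assert series.points[-1].quencher_conc == 0.0323
    assert series.has_absorbances


def test_titration_roundtrip_bit_exact(titration_path, tmp_path):
    series = read_titration_csv(titration_path)
    out = tmp_path / "copy.csv"
    write_titration_csv(series, out)
    again = read_titration_csv(out)
    assert again == series


def test_repeated_zero_concentration_rejected(tmp_path):
    path = tmp_path / "bad.csv"
    path.write_text(
        "# ligand_conc_M=1e-6\n"
        "quencher_mol_per_L,F_measured\n0.0,100\n0.0,90\n0.001,80\n"
    )
    with pytest.raises(ValidationError, match="non-increasing concentration at row 2"):
        read_titration_csv(path)


def test_missing_required_column_names_it(tmp_path):
    path = tmp_path / "bad.csv"
    path.write_text("# ligand_conc_M=1e-6\nquencher_mol_per_L\n0.0\n")
    with pytest.raises(ValidationError, match="F_measured"):
        read_titration_csv(path)


def test_nonpositive_fluorescence_names_row_and_column(tmp_path):
    path = tmp_path / "bad.csv"
    path.write_text(
        "# ligand_conc_M=1e-6\n"
        "quencher_mol_per_L,F_measured\n0.0,100\n0.001,-5\n0.002,80\n"
    )
    with pytest.raises(ValidationError, match="row 2.*F_measured"):
        read_titration_csv(path)


def test_absorbance_columns_optional(tmp_path):
    path = tmp_path / "noabs.csv"
    path.write_text(
        "# ligand_conc_M=1e-6\n"
        "quencher_mol_per_L,F_measured\n0.0,100\n0.001,90\n0.002,80\n"
    )
    series = read_titration_csv(path)
    assert not series.has_absorbances
    assert series.points[0].a_ex is None


def test_titration_point_invariants():
    with pytest.raises(ValidationError):
        TitrationPoint(quencher_conc=-1e-3, f_measured=10)
    with pytest.raises(ValidationError):
        TitrationPoint(quencher_conc=0, f_measured=0)
    with pytest.raises(ValidationError):
        TitrationPoint(quencher_conc=0, f_measured=10, a_ex=-0.1, a_em=0.0)


def test_series_requires_zero_first_point():
    points = [
        TitrationPoint(quencher_conc=0.001, f_measured=100),
        TitrationPoint(quencher_conc=0.002, f_measured=90),
    ]
    with pytest.raises(ValidationError, match="quencher_conc = 0"):
        TitrationSeries(points=points, temperature=298.15, ligand_conc=1e-6)


def test_melting_csv_roundtrip(tmp_path):
    curve = MeltingCurve(
        temperatures=[20.0, 40.0, 60.0, 80.0, 100.0],
        absorbances=[0.5, 0.52, 0.7, 0.95, 1.0],
        label="free",
    )
    path = tmp_path / "melt.csv"
    write_melting_csv(curve, path)
    assert read_melting_csv(path) == curve


def test_viscosity_csv_roundtrip(tmp_path):
    series = ViscositySeries(
        buffer_time=100.0,
        flow_times=[150.0, 151.0, 152.0],
        ligand_concs=[0.0, 1e-5, 2e-5],
        dna_conc=2.73e-5,
    )
    path = tmp_path / "visc.csv"
    write_viscosity_csv(series, path)
    assert read_viscosity_csv(path) == series


def test_result_json_roundtrip_bit_exact(tmp_path):
    result = SternVolmerResult(
        ksv=3550.0,
        ksv_stderr=60.0,
        intercept=1.0000001,
        r=0.9977,
        kq=3.55e11,
        temperature=298.15,
    )
    path = tmp_path / "sv.json"
    write_result_json(result, path)
    assert read_result_json(path) == result


def test_result_json_rejects_unknown_type(tmp_path):
    with pytest.raises(TypeError):
        write_result_json({"not": "a result"}, tmp_path / "x.json")


def test_celsius_conversion_is_exact():
    assert celsius_to_kelvin(25.0) == 298.15
    assert math.isclose(celsius_to_kelvin(37.0), 310.15)


def test_config_rejects_nonpositive_values():
    with pytest.raises(ValidationError):
        AnalysisConfig(tau0=0.0)
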