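"""Domain types, file readers/writers and analysis configuration.

Units are fixed package-wide: concentrations in mol L^-1, temperatures in
kelvin everywhere except melting curves (which are acquired and reported in
degrees Celsius), times in seconds, enthalpies in kJ mol^-1 and entropies in
J mol^-1 K^-1.  CSV fixtures are UTF-8 with "." as the decimal separator;
lines starting with "#" are comments and may carry ``# key=value`` metadata.
"""

from __future__ import annotations

import dataclasses
import io
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from ctbind.errors import ValidationError

logger = logging.getLogger("ctbind")

SCHEMA_VERSION = 1


@dataclass(frozen=True)
class AnalysisConfig:
    """Physical constants and decision thresholds used across the pipeline.

    Parameters
    ----------
    tau0 : float
        Fluorophore excited-state lifetime in seconds.  The conventional
        value for organic fluorophores without a measured lifetime is 1e-8 s;
        it converts the Stern-Volmer constant into the bimolecular quenching
        rate constant ``kq = ksv / tau0``.
    gas_constant : float
        Universal gas constant R in J mol^-1 K^-1.
    celsius_offset : float
        Additive offset for the Celsius -> kelvin conversion (273.15).
    kq_static_threshold : float
        Diffusion-controlled collisional quenching limit in L mol^-1 s^-1.
        An apparent kq above ~2e10 cannot arise from diffusive collisions and
        indicates ground-state complex formation (static quenching).
    redshift_intercalation_nm : float
        Minimum UV absorption redshift (nm) on complexation that is taken as
        evidence of intercalation; smaller shifts point to groove or external
        binding.
    tm_intercalation_shift : float
        Minimum duplex melting-temperature increase (degrees C) attributed to
        intercalative stabilisation; classical intercalators raise Tm by
        roughly 5-8 degrees C.
    """

    tau0: float = 1e-8
    gas_constant: float = 8.314
    celsius_offset: float = 273.15
    kq_static_threshold: float = 2.0e10
    redshift_intercalation_nm: float = 10.0
    tm_intercalation_shift: float = 5.0

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            if getattr(self, f.name) <= 0:
                raise ValidationError(f"AnalysisConfig.{f.name} must be positive")

    def snapshot(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class TitrationPoint:
    """One titration point: quencher concentration and fluorescence readout.

    ``a_ex``/``a_em`` are the sample absorbances at the excitation and
    emission wavelengths; they drive the inner-filter correction and are
    optional (series without them can be fitted but not corrected).
    ``f_corrected`` is filled by the correction stage.
    """

    quencher_conc: float
    f_measured: float
    a_ex: Optional[float] = None
    a_em: Optional[float] = None
    f_corrected: Optional[float] = None

    def __post_init__(self) -> None:
        if self.quencher_conc < 0:
            raise ValidationError(
                f"quencher_conc must be >= 0, got {self.quencher_conc}"
            )
        if self.f_measured <= 0:
            raise ValidationError(f"f_measured must be > 0, got {self.f_measured}")
        for name in ("a_ex", "a_em"):
            val = getattr(self, name)
            if val is not None and val < 0:
                raise ValidationError(f"{name} must be >= 0 when present, got {val}")

    @property
    def fluorescence(self) -> float:
        """Corrected intensity when available, else the raw reading."""
        return self.f_corrected if self.f_corrected is not None else self.f_measured


@dataclass
class TitrationSeries:
    """An ordered quencher titration at a single temperature.

    The first point must have zero quencher concentration: its (corrected)
    fluorescence defines F0.  ``ligand_conc`` is the fixed fluorophore
    concentration [P_t] in mol L^-1.
    """

    points: list[TitrationPoint]
    temperature: float
    ligand_conc: float
    label: str = ""

    def __post_init__(self) -> None:
        if not self.points:
            raise ValidationError("titration series has no points")
        if self.temperature <= 0:
            raise ValidationError("temperature (K) must be positive")
        if self.ligand_conc <= 0:
            raise ValidationError("ligand_conc must be positive")
        if self.points[0].quencher_conc != 0:
            raise ValidationError(
                "first point must have quencher_conc = 0 (defines F0)"
            )
        concs = [p.quencher_conc for p in self.points]
        for i in range(1, len(concs)):
            if concs[i] <= concs[i - 1]:
                raise ValidationError(f"non-increasing concentration at row {i + 1}")

    def __len__(self) -> int:
        return len(self.points)

    @property
    def f0(self) -> float:
        """Fluorescence of the zero-quencher point (corrected if available)."""
        return self.points[0].fluorescence

    @property
    def has_absorbances(self) -> bool:
        return all(p.a_ex is not None and p.a_em is not None for p in self.points)

    @property
    def is_corrected(self) -> bool:
        return all(p.f_corrected is not None for p in self.points)


@dataclass
class MeltingCurve:
    """Absorbance (258 nm) versus temperature for a thermal denaturation run.

    Temperatures are in degrees Celsius and must increase strictly; the curve
    should span the transition so that the single-strand fraction brackets
    0.5 on its way up.
    """

    temperatures: list[float]
    absorbances: list[float]
    label: str = ""

    def __post_init__(self) -> None:
        if len(self.temperatures) != len(self.absorbances):
            raise ValidationError("temperatures and absorbances differ in length")
        if len(self.temperatures) < 2:
            raise ValidationError("melting curve needs at least 2 readings")
        for i in range(1, len(self.temperatures)):
            if self.temperatures[i] <= self.temperatures[i - 1]:
                raise ValidationError(
                    f"non-increasing temperature at row {i + 1}"
                )


@dataclass
class ViscositySeries:
    """Ubbelohde flow times over a ligand titration at fixed DNA concentration.

    ``buffer_time`` is the buffer-alone flow time t0 in seconds; each entry of
    ``flow_times`` is the mean flow time t at the matching ligand
    concentration (replicates are averaged before this point).
    """

    buffer_time: float
    flow_times: list[float]
    ligand_concs: list[float]
    dna_conc: float

    def __post_init__(self) -> None:
        if self.buffer_time <= 0:
            raise ValidationError("buffer_time must be positive")
        if self.dna_conc <= 0:
            raise ValidationError("dna_conc must be positive")
        if len(self.flow_times) != len(self.ligand_concs):
            raise ValidationError("flow_times and ligand_concs differ in length")
        if any(t <= 0 for t in self.flow_times):
            raise ValidationError("all flow times must be positive")


# ---------------------------------------------------------------------------
# CSV readers
# ---------------------------------------------------------------------------

def _read_csv_with_metadata(path) -> tuple[pd.DataFrame, dict]:
    """Read a '#'-commented CSV, harvesting ``# key=value`` metadata lines."""
    meta: dict[str, str] = {}
    body_lines = []
    text = Path(path).read_text(encoding="utf-8")
    for line in text.splitlines():
        stripped = line.strip()
        if stripped.startswith("#"):
            payload = stripped.lstrip("#").strip()
            if "=" in payload:
                key, _, value = payload.partition("=")
                meta[key.strip()] = value.strip()
            continue
        if stripped:
            body_lines.append(line)
    if not body_lines:
        raise ValidationError(f"{path}: no data rows")
    frame = pd.read_csv(io.StringIO("\n".join(body_lines)))
    return frame, meta


def read_titration_csv(path) -> TitrationSeries:
    """Read a titration table into a validated :class:`TitrationSeries`.

    Required columns: ``quencher_mol_per_L`` and ``F_measured``; optional
    ``A_ex``/``A_em`` absorbance columns.  Metadata comments
    ``# temperature_K=...`` and ``# ligand_conc_M=...`` set the series
    temperature (default 298.15 K) and fluorophore concentration (required).
    """
    frame, meta = _read_csv_with_metadata(path)
    for col in ("quencher_mol_per_L", "F_measured"):
        if col not in frame.columns:
            raise ValidationError(f"{path}: missing required column '{col}'")
    if "ligand_conc_M" not in meta:
        raise ValidationError(f"{path}: missing '# ligand_conc_M=' metadata line")
    temperature = float(meta.get("temperature_K", 298.15))
    ligand_conc = float(meta["ligand_conc_M"])
    has_aex = "A_ex" in frame.columns
    has_aem = "A_em" in frame.columns
    has_corrected = "F_corrected" in frame.columns

    points = []
    for row_no, row in enumerate(frame.itertuples(index=False), start=1):
        record = row._asdict()
        q = record["quencher_mol_per_L"]
        fm = record["F_measured"]
        if not pd.notna(q) or q < 0:
            raise ValidationError(
                f"{path}: invalid quencher concentration at row {row_no}, "
                "column quencher_mol_per_L"
            )
        if not pd.notna(fm) or fm <= 0:
            raise ValidationError(
                f"{path}: non-positive fluorescence at row {row_no}, "
                "column F_measured"
            )
        a_ex = record["A_ex"] if has_aex and pd.notna(record["A_ex"]) else None
        a_em = record["A_em"] if has_aem and pd.notna(record["A_em"]) else None
        f_corr = (
            record["F_corrected"]
            if has_corrected and pd.notna(record["F_corrected"])
            else None
        )
        points.append(
            TitrationPoint(
                quencher_conc=float(q),
                f_measured=float(fm),
                a_ex=None if a_ex is None else float(a_ex),
                a_em=None if a_em is None else float(a_em),
                f_corrected=None if f_corr is None else float(f_corr),
            )
        )
    return TitrationSeries(
        points=points,
        temperature=temperature,
        ligand_conc=ligand_conc,
        label=meta.get("label", ""),
    )


def write_titration_csv(series: TitrationSeries, path) -> None:
    """Write a series back to the CSV dialect read by :func:`read_titration_csv`."""
    lines = [
        f"# temperature_K={series.temperature!r}",
        f"# ligand_conc_M={series.ligand_conc!r}",
    ]
    if series.label:
        lines.append(f"# label={series.label}")
    cols = ["quencher_mol_per_L", "F_measured"]
    if series.has_absorbances:
        cols += ["A_ex", "A_em"]
    if series.is_corrected:
        cols += ["F_corrected"]
    lines.append(",".join(cols))
    for p in series.points:
        row = [repr(p.quencher_conc), repr(p.f_measured)]
        if series.has_absorbances:
            row += [repr(p.a_ex), repr(p.a_em)]
        if series.is_corrected:
            row += [repr(p.f_corrected)]
        lines.append(",".join(row))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_melting_csv(path) -> MeltingCurve:
    """Read a melting curve CSV with columns ``temperature_C``, ``A258``."""
    frame, meta = _read_csv_with_metadata(path)
    for col in ("temperature_C", "A258"):
        if col not in frame.columns:
            raise ValidationError(f"{path}: missing required column '{col}'")
    return MeltingCurve(
        temperatures=[float(v) for v in frame["temperature_C"]],
        absorbances=[float(v) for v in frame["A258"]],
        label=meta.get("label", ""),
    )


def write_melting_csv(curve: MeltingCurve, path) -> None:
    lines = []
    if curve.label:
        lines.append(f"# label={curve.label}")
    lines.append("temperature_C,A258")
    for t, a in zip(curve.temperatures, curve.absorbances):
        lines.append(f"{t!r},{a!r}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_viscosity_csv(path) -> ViscositySeries:
    """Read flow times: columns ``ligand_conc_M``, ``flow_time_s``; metadata
    ``# buffer_time_s=`` and ``# dna_conc_M=``."""
    frame, meta = _read_csv_with_metadata(path)
    for col in ("ligand_conc_M", "flow_time_s"):
        if col not in frame.columns:
            raise ValidationError(f"{path}: missing required column '{col}'")
    for key in ("buffer_time_s", "dna_conc_M"):
        if key not in meta:
            raise ValidationError(f"{path}: missing '# {key}=' metadata line")
    return ViscositySeries(
        buffer_time=float(meta["buffer_time_s"]),
        flow_times=[float(v) for v in frame["flow_time_s"]],
        ligand_concs=[float(v) for v in frame["ligand_conc_M"]],
        dna_conc=float(meta["dna_conc_M"]),
    )


def write_viscosity_csv(series: ViscositySeries, path) -> None:
    lines = [
        f"# buffer_time_s={series.buffer_time!r}",
        f"# dna_conc_M={series.dna_conc!r}",
        "ligand_conc_M,flow_time_s",
    ]
    for c, t in zip(series.ligand_concs, series.flow_times):
        lines.append(f"{c!r},{t!r}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# JSON result serialization
# ---------------------------------------------------------------------------

def _result_registry() -> dict:
    # late imports: the result types live in their stage modules
    from ctbind.binding_thermo import BindingFitResult, ThermoResult
    from ctbind.melting import MeltingResult
    from ctbind.mode_classifier import ModeVerdict
    from ctbind.quenching import (
        MechanismVerdict,
        QuenchingComparison,
        SternVolmerResult,
    )
    from ctbind.viscosity import ViscosityResult

    return {
        "stern_volmer": SternVolmerResult,
        "mechanism": MechanismVerdict,
        "quenching_comparison": QuenchingComparison,
        "binding_fit": BindingFitResult,
        "thermodynamics": ThermoResult,
        "melting": MeltingResult,
        "viscosity": ViscosityResult,
        "binding_mode": ModeVerdict,
    }


def write_result_json(result, path, config: Optional[AnalysisConfig] = None) -> None:
    """Serialize any stage result to JSON with a ``stage`` tag.

    The document carries ``schema_version``, the stage name, the result
    fields (SI units as documented on each type) and a snapshot of the
    analysis configuration in force.
    """
    registry = _result_registry()
    stage = None
    for name, cls in registry.items():
        if type(result) is cls:
            stage = name
            break
    if stage is None:
        raise TypeError(
            f"cannot serialize object of type {type(result).__name__}: "
            "not a known stage result"
        )
    payload = dataclasses.asdict(result)
    doc = {
        "schema_version": SCHEMA_VERSION,
        "stage": stage,
        "result": payload,
        "config": (config or AnalysisConfig()).snapshot(),
    }
    Path(path).write_text(
        json.dumps(doc, indent=2, sort_keys=True), encoding="utf-8"
    )


def read_result_json(path):
    """Read back a result written by :func:`write_result_json`.

    Returns the reconstructed stage-result object; float-keyed maps (e.g.
    Gibbs energies by temperature) have their keys restored to floats.
    """
    doc = json.loads(Path(path).read_text(encoding="utf-8"))
    registry = _result_registry()
    stage = doc.get("stage")
    if stage not in registry:
        raise ValidationError(f"{path}: unknown stage tag {stage!r}")
    cls = registry[stage]
    payload = dict(doc["result"])
    if stage == "thermodynamics":
        payload["delta_g_by_temperature"] = {
            float(k): v for k, v in payload["delta_g_by_temperature"].items()
        }
    if stage == "binding_mode":
        from ctbind.mode_classifier import Contribution

        payload["contributions"] = [
            Contribution(**c) for c in payload["contributions"]
        ]
    if stage == "melting":
        payload["fss"] = [tuple(pair) for pair in payload["fss"]]
    if stage == "viscosity":
        payload["profile"] = [tuple(pair) for pair in payload["profile"]]
    return cls(**payload)


def celsius_to_kelvin(t_celsius: float, config: Optional[AnalysisConfig] = None) -> float:
    """Convert a Celsius reading to kelvin at the I/O boundary."""
    offset = (config or AnalysisConfig()).celsius_offset
    return t_celsius + offset
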