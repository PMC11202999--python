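"""Evidence aggregation into a binding-mode verdict.

Each bench experiment votes for a binding mode through a fixed qualitative
rule; equal-weight votes are tallied and the winning mode is returned with
a complete audit trail.  Electrostatic binding can only gain votes from a
salt-dependence experiment or a thermodynamic force assignment, because the
other observables cannot positively identify it.  At least three evidence
fields are required for any verdict (quorum), and tied tallies are
indeterminate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Optional

from ctbind.core_io import AnalysisConfig
from ctbind.errors import InsufficientEvidenceError, ValidationError

MODES = ("intercalation", "groove", "electrostatic")

EVIDENCE_QUORUM = 3

#: Upper Ka bound (L mol^-1) for a groove-binding vote: groove binders sit
#: around 1e3-1e5 while classical intercalators bind orders of magnitude
#: tighter.
KA_GROOVE_LOWER = 1e3
KA_GROOVE_UPPER = 1e5

_ENUM_FIELDS = {
    "ki_equivalence": {"equivalent", "a_greater", "b_greater"},
    "salt_effect": {"none", "decreasing_binding"},
    "viscosity_class": {"intercalative", "non_intercalative"},
    "cd_perturbation": {"none", "slight", "strong"},
    "force_verdict": {
        "hydrogen_bond_and_hydrophobic",
        "hydrophobic",
        "hbond_vdw",
        "electrostatic",
        "indeterminate",
    },
    "gel_cleavage": {"none", "nicked", "linearized"},
}


@dataclass
class EvidenceSet:
    """Per-experiment feature vector; every field is optional.

    ``redshift_nm`` — UV peak shift of the ligand on complexation;
    ``ka`` — association constant (L mol^-1); ``ki_equivalence`` — outcome
    of comparing iodide quenching of the free versus DNA-bound ligand;
    ``ss_over_ds_ksv`` — ratio of single- to double-stranded DNA quenching
    constants; ``salt_effect`` — response of the complex to added NaCl;
    ``delta_tm`` — melting-temperature shift (complex minus free, Celsius);
    ``viscosity_class`` — cube-root viscosity profile class;
    ``cd_perturbation`` — degree of circular-dichroism change;
    ``force_verdict`` — thermodynamic driving-force class;
    ``gel_cleavage`` — plasmid cleavage pattern on a gel.
    """

    redshift_nm: Optional[float] = None
    ka: Optional[float] = None
    ki_equivalence: Optional[str] = None
    ss_over_ds_ksv: Optional[float] = None
    salt_effect: Optional[str] = None
    delta_tm: Optional[float] = None
    viscosity_class: Optional[str] = None
    cd_perturbation: Optional[str] = None
    force_verdict: Optional[str] = None
    gel_cleavage: Optional[str] = None

    def __post_init__(self) -> None:
        for name, allowed in _ENUM_FIELDS.items():
            value = getattr(self, name)
            if value is not None and value not in allowed:
                raise ValidationError(
                    f"{name}={value!r} not in {sorted(allowed)}"
                )
        for name in ("redshift_nm", "ka", "ss_over_ds_ksv"):
            value = getattr(self, name)
            if value is not None and value < 0:
                raise ValidationError(f"{name} must be non-negative")

    def present_fields(self) -> list[str]:
        return [f.name for f in fields(self) if getattr(self, f.name) is not None]

    @classmethod
    def from_json(cls, path) -> "EvidenceSet":
        data = json.loads(Path(path).read_text(encoding="utf-8"))
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown evidence fields: {sorted(unknown)}")
        return cls(**data)

    def to_json(self, path) -> None:
        data = {name: getattr(self, name) for name in self.present_fields()}
        Path(path).write_text(json.dumps(data, indent=2), encoding="utf-8")


@dataclass
class Contribution:
    """One audited rule application: which evidence voted for which mode."""

    evidence: str
    vote: Optional[str]  # mode name, "anti:electrostatic", or None (no vote)
    rule: str


@dataclass
class ModeVerdict:
    """Aggregated binding-mode decision with full audit trail."""

    mode: str  # "intercalation" | "groove" | "electrostatic" | "indeterminate"
    votes: dict
    contributions: list


def _apply_rules(evidence: EvidenceSet, config: AnalysisConfig):
    """Yield a Contribution for every present evidence field, in a fixed order."""
    out: list[Contribution] = []

    if evidence.redshift_nm is not None:
        if evidence.redshift_nm > config.redshift_intercalation_nm:
            vote = "intercalation"
            rule = (
                f"UV redshift > {config.redshift_intercalation_nm:g} nm: "
                "pi-stacking with base pairs lowers the pi-pi* transition energy"
            )
        else:
            vote = "groove"
            rule = (
                "small UV redshift: spectra barely perturbed, consistent with "
                "groove or external binding rather than intercalation"
            )
        out.append(Contribution("redshift_nm", vote, rule))

    if evidence.ka is not None:
        if KA_GROOVE_LOWER <= evidence.ka <= KA_GROOVE_UPPER:
            out.append(
                Contribution(
                    "ka",
                    "groove",
                    "Ka in the 1e3-1e5 L/mol range typical of groove binders, "
                    "well below intercalator affinities",
                )
            )
        else:
            out.append(
                Contribution(
                    "ka",
                    None,
                    "Ka outside the groove-typical range: magnitude alone "
                    "does not assign a mode",
                )
            )

    if evidence.ki_equivalence is not None:
        if evidence.ki_equivalence == "equivalent":
            out.append(
                Contribution(
                    "ki_equivalence",
                    "groove",
                    "iodide quenches the bound ligand as readily as the free "
                    "one: the fluorophore is solvent-exposed, not sandwiched "
                    "between base pairs",
                )
            )
        elif evidence.ki_equivalence == "a_greater":
            out.append(
                Contribution(
                    "ki_equivalence",
                    "intercalation",
                    "the DNA-bound ligand is shielded from anionic iodide, as "
                    "expected when it is buried between base pairs",
                )
            )
        else:
            out.append(
                Contribution(
                    "ki_equivalence",
                    None,
                    "bound ligand quenched more strongly than free: not a "
                    "recognised mode signature",
                )
            )

    if evidence.ss_over_ds_ksv is not None:
        if evidence.ss_over_ds_ksv > 1:
            out.append(
                Contribution(
                    "ss_over_ds_ksv",
                    "groove",
                    "single-stranded DNA quenches more strongly than duplex: "
                    "groove binders gain access on unfolding while "
                    "intercalation requires the duplex",
                )
            )
        else:
            out.append(
                Contribution(
                    "ss_over_ds_ksv",
                    None,
                    "duplex quenches at least as strongly as single strands: "
                    "no groove preference detected",
                )
            )

    if evidence.salt_effect is not None:
        if evidence.salt_effect == "decreasing_binding":
            out.append(
                Contribution(
                    "salt_effect",
                    "electrostatic",
                    "added Na+ weakens the complex by competing for the "
                    "phosphate backbone",
                )
            )
        else:
            out.append(
                Contribution(
                    "salt_effect",
                    "anti:electrostatic",
                    "ionic strength leaves the complex unchanged, ruling out "
                    "a dominant electrostatic contribution",
                )
            )

    if evidence.delta_tm is not None:
        if evidence.delta_tm >= config.tm_intercalation_shift:
            out.append(
                Contribution(
                    "delta_tm",
                    "intercalation",
                    f"Tm raised by >= {config.tm_intercalation_shift:g} C: "
                    "base-pair stacking stabilised as in intercalation",
                )
            )
        else:
            out.append(
                Contribution(
                    "delta_tm",
                    "groove",
                    "no substantial duplex stabilisation: the helix length "
                    "and stacking are unchanged, as for groove binding",
                )
            )

    if evidence.viscosity_class is not None:
        if evidence.viscosity_class == "intercalative":
            out.append(
                Contribution(
                    "viscosity_class",
                    "intercalation",
                    "relative viscosity rises steeply: the helix is "
                    "lengthened at intercalation sites",
                )
            )
        else:
            out.append(
                Contribution(
                    "viscosity_class",
                    "groove",
                    "relative viscosity essentially flat: the DNA contour "
                    "length is unchanged",
                )
            )

    if evidence.cd_perturbation is not None:
        if evidence.cd_perturbation == "strong":
            out.append(
                Contribution(
                    "cd_perturbation",
                    "intercalation",
                    "strong CD perturbation: base stacking and helicity "
                    "bands reshaped by helix elongation/distortion",
                )
            )
        else:
            out.append(
                Contribution(
                    "cd_perturbation",
                    "groove",
                    "at most slight CD perturbation: the B-form secondary "
                    "structure is retained",
                )
            )

    if evidence.force_verdict is not None:
        if evidence.force_verdict == "electrostatic":
            out.append(
                Contribution(
                    "force_verdict",
                    "electrostatic",
                    "thermodynamics dominated by a near-zero enthalpy with "
                    "positive entropy, the electrostatic signature",
                )
            )
        else:
            out.append(
                Contribution(
                    "force_verdict",
                    None,
                    f"driving force '{evidence.force_verdict}': consistent "
                    "with non-electrostatic binding but not mode-specific",
                )
            )

    if evidence.gel_cleavage is not None:
        if evidence.gel_cleavage == "none":
            out.append(
                Contribution(
                    "gel_cleavage",
                    "groove",
                    "no plasmid cleavage or form conversion: the backbone is "
                    "intact, consistent with benign groove association",
                )
            )
        else:
            out.append(
                Contribution(
                    "gel_cleavage",
                    None,
                    f"plasmid {evidence.gel_cleavage}: cleavage chemistry "
                    "flagged; not a non-covalent mode discriminator",
                )
            )

    return out


def classify_binding_mode(
    evidence: EvidenceSet, config: Optional[AnalysisConfig] = None
) -> ModeVerdict:
    """Tally one equal-weight vote per present evidence field.

    Requires at least three evidence fields.  ``anti:electrostatic`` votes
    subtract from the electrostatic tally.  The verdict is the unique mode
    with the highest tally; ties give "indeterminate".
    """
    config = config or AnalysisConfig()
    present = evidence.present_fields()
    if len(present) < EVIDENCE_QUORUM:
        raise InsufficientEvidenceError(
            f"need >= {EVIDENCE_QUORUM} evidence fields for a verdict, "
            f"got {len(present)}: {present}"
        )
    contributions = _apply_rules(evidence, config)
    votes = {mode: 0 for mode in MODES}
    for contribution in contributions:
        if contribution.vote in votes:
            votes[contribution.vote] += 1
        elif contribution.vote == "anti:electrostatic":
            votes["electrostatic"] -= 1
    best = max(votes.values())
    winners = [mode for mode, count in votes.items() if count == best]
    mode = winners[0] if len(winners) == 1 else "indeterminate"
    return ModeVerdict(mode=mode, votes=votes, contributions=contributions)
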