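"""Physiological and compound parameterization of the whole-body PBPK model.

The model body is described by arterial and venous blood pools, a lung
compartment in series with the circulation, and a configurable set of tissue
compartments perfused in parallel.  Each tissue (and the lung) is split into a
vascular and an extravascular sub-compartment exchanging unbound drug through
a permeability-surface area product (PS).  Elimination is hepatic only, as a
constant (unbound intrinsic) clearance acting on the liver extravascular
compartment.

Parameters are loaded from a strict YAML schema with explicit units in the
key names; unknown keys are rejected so that typos cannot silently drop a
parameter.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import yaml

__all__ = [
    "CompoundProperties",
    "TissueParameters",
    "PBPKParameters",
    "DosingRegimen",
    "ParameterValidationError",
    "load_pbpk_parameters",
    "human_parameters",
    "rat_parameters",
]

#: Relative tolerance for the flow-balance invariant (sum of tissue blood
#: flows must equal cardiac output).
FLOW_BALANCE_RTOL = 1e-6


class ParameterValidationError(ValueError):
    """Raised when a parameter set violates a physiological invariant."""


@dataclass(frozen=True)
class CompoundProperties:
    """Physicochemical and binding properties of the modeled compound.

    Attributes
    ----------
    molecular_weight : float
        Molar mass in g/mol.
    fu_plasma : float
        Unbound fraction in plasma, in (0, 1].
    blood_plasma_ratio : float
        Whole blood to plasma concentration ratio (dimensionless, > 0).
    name : str
        Compound label used in reports.
    """

    molecular_weight: float
    fu_plasma: float
    blood_plasma_ratio: float = 1.0
    name: str = "compound"

    def __post_init__(self) -> None:
        if not self.molecular_weight > 0:
            raise ParameterValidationError("molecular_weight must be > 0")
        if not 0 < self.fu_plasma <= 1:
            raise ParameterValidationError("fu_plasma must be in (0, 1]")
        if not self.blood_plasma_ratio > 0:
            raise ParameterValidationError("blood_plasma_ratio must be > 0")

    @property
    def fu_blood(self) -> float:
        """Unbound fraction referred to whole blood (fu_plasma / B:P ratio)."""
        return self.fu_plasma / self.blood_plasma_ratio


@dataclass(frozen=True)
class TissueParameters:
    """One permeability-limited tissue: volumes, perfusion, PS and binding."""

    name: str
    volume_vascular: float  # L
    volume_tissue: float  # L
    blood_flow: float  # L/h
    ps: float  # L/h, permeability-surface area product
    fu_tissue: float  # unbound fraction in the extravascular space

    def __post_init__(self) -> None:
        if self.volume_vascular <= 0 or self.volume_tissue <= 0:
            raise ParameterValidationError(
                f"{self.name}: sub-compartment volumes must be > 0"
            )
        if self.blood_flow < 0 or self.ps < 0:
            raise ParameterValidationError(
                f"{self.name}: blood_flow and ps must be >= 0"
            )
        if not 0 < self.fu_tissue <= 1:
            raise ParameterValidationError(
                f"{self.name}: fu_tissue must be in (0, 1]"
            )


@dataclass(frozen=True)
class PBPKParameters:
    """Complete parameterization of the whole-body model.

    ``tissues`` holds the systemically perfused compartments (their blood
    flows must sum to ``cardiac_output``); ``lung`` sits in series between the
    venous and arterial pools and receives the whole cardiac output.
    """

    body_weight: float  # kg
    cardiac_output: float  # L/h
    volume_arterial: float  # L
    volume_venous: float  # L
    lung: TissueParameters
    tissues: tuple[TissueParameters, ...]
    hepatic_clearance: float  # L/h, applied to unbound liver tissue conc
    compound: CompoundProperties
    eliminating_tissue: str = "liver"
    species: str = "human"

    def __post_init__(self) -> None:
        if self.body_weight <= 0:
            raise ParameterValidationError("body_weight must be > 0")
        if self.cardiac_output <= 0:
            raise ParameterValidationError("cardiac_output must be > 0")
        if self.volume_arterial <= 0 or self.volume_venous <= 0:
            raise ParameterValidationError("blood pool volumes must be > 0")
        if self.hepatic_clearance < 0:
            raise ParameterValidationError("hepatic_clearance must be >= 0")
        names = [t.name for t in self.tissues]
        if len(set(names)) != len(names):
            raise ParameterValidationError("duplicate tissue names")
        flow_sum = sum(t.blood_flow for t in self.tissues)
        if abs(flow_sum - self.cardiac_output) > FLOW_BALANCE_RTOL * self.cardiac_output:
            raise ParameterValidationError(
                "tissue blood flows must sum to cardiac output "
                f"(got {flow_sum:.6g} vs {self.cardiac_output:.6g} L/h)"
            )
        if self.hepatic_clearance > 0 and self.eliminating_tissue not in names:
            raise ParameterValidationError(
                f"eliminating tissue {self.eliminating_tissue!r} not among tissues"
            )

    def tissue(self, name: str) -> TissueParameters:
        for t in self.tissues:
            if t.name == name:
                return t
        raise KeyError(name)

    def with_tissue(self, name: str, **changes) -> "PBPKParameters":
        """Return a copy with one tissue's parameters replaced."""
        new = tuple(
            replace(t, **changes) if t.name == name else t for t in self.tissues
        )
        if name == self.lung.name:
            return replace(self, lung=replace(self.lung, **changes), tissues=new)
        return replace(self, tissues=new)


@dataclass(frozen=True)
class DosingRegimen:
    """Intravenous dosing schedule.

    A bolus (``infusion_duration == 0``) is applied as an instantaneous
    increment of the venous amount; an infusion as a zero-order input over
    ``infusion_duration`` hours.  ``n_doses`` administrations are spaced
    ``interval`` hours apart starting at t = 0.
    """

    dose: float  # mg per administration
    infusion_duration: float = 0.0  # h; 0 = bolus
    interval: float = 24.0  # h between administrations
    n_doses: int = 1
    route: str = "intravenous"

    def __post_init__(self) -> None:
        if self.dose < 0:
            raise ParameterValidationError("dose must be >= 0")
        if self.infusion_duration < 0:
            raise ParameterValidationError("infusion_duration must be >= 0")
        if self.n_doses < 1:
            raise ParameterValidationError("n_doses must be >= 1")
        if self.n_doses > 1 and self.interval <= 0:
            raise ParameterValidationError("interval must be > 0 for repeated dosing")
        if self.route != "intravenous":
            raise ParameterValidationError("only intravenous input is supported")
        if self.n_doses > 1 and self.infusion_duration > self.interval:
            raise ParameterValidationError("infusion longer than dosing interval")

    @property
    def span(self) -> float:
        """Time of the last administration's end, in hours."""
        return (self.n_doses - 1) * self.interval + self.infusion_duration

    @property
    def total_dose(self) -> float:
        return self.dose * self.n_doses


# ---------------------------------------------------------------------------
# YAML schema
# ---------------------------------------------------------------------------

_SCHEMA = "ivive-pbpk-1"

_TISSUE_KEYS = {
    "volume_vascular_L",
    "volume_tissue_L",
    "blood_flow_L_per_h",
    "ps_L_per_h",
    "fu_tissue",
}
_TOP_KEYS = {
    "schema",
    "species",
    "description",
    "body_weight_kg",
    "cardiac_output_L_per_h",
    "blood",
    "compound",
    "hepatic_clearance_L_per_h",
    "eliminating_tissue",
    "lung",
    "tissues",
}
_BLOOD_KEYS = {"volume_arterial_L", "volume_venous_L"}
_COMPOUND_KEYS = {
    "name",
    "molecular_weight_g_per_mol",
    "fu_plasma",
    "blood_plasma_ratio",
}


def _check_keys(mapping: Mapping, allowed: set, where: str) -> None:
    unknown = set(mapping) - allowed
    if unknown:
        raise ParameterValidationError(
            f"unknown key(s) {sorted(unknown)} in {where}"
        )


def _tissue_from_mapping(name: str, raw: Mapping, flow: float | None = None) -> TissueParameters:
    allowed = _TISSUE_KEYS if flow is None else _TISSUE_KEYS - {"blood_flow_L_per_h"}
    _check_keys(raw, allowed, f"tissue {name!r}")
    missing = allowed - set(raw)
    if missing:
        raise ParameterValidationError(f"tissue {name!r} missing key(s) {sorted(missing)}")
    return TissueParameters(
        name=name,
        volume_vascular=float(raw["volume_vascular_L"]),
        volume_tissue=float(raw["volume_tissue_L"]),
        blood_flow=float(raw["blood_flow_L_per_h"]) if flow is None else flow,
        ps=float(raw["ps_L_per_h"]),
        fu_tissue=float(raw["fu_tissue"]),
    )


def parameters_from_dict(raw: Mapping) -> PBPKParameters:
    """Build :class:`PBPKParameters` from a parsed YAML mapping (strict)."""
    _check_keys(raw, _TOP_KEYS, "top level")
    if raw.get("schema") != _SCHEMA:
        raise ParameterValidationError(
            f"expected schema {_SCHEMA!r}, got {raw.get('schema')!r}"
        )
    blood = raw["blood"]
    _check_keys(blood, _BLOOD_KEYS, "blood")
    comp_raw = raw["compound"]
    _check_keys(comp_raw, _COMPOUND_KEYS, "compound")
    compound = CompoundProperties(
        molecular_weight=float(comp_raw["molecular_weight_g_per_mol"]),
        fu_plasma=float(comp_raw["fu_plasma"]),
        blood_plasma_ratio=float(comp_raw.get("blood_plasma_ratio", 1.0)),
        name=str(comp_raw.get("name", "compound")),
    )
    cardiac_output = float(raw["cardiac_output_L_per_h"])
    lung = _tissue_from_mapping("lung", raw["lung"], flow=cardiac_output)
    tissues = tuple(
        _tissue_from_mapping(name, t) for name, t in raw["tissues"].items()
    )
    return PBPKParameters(
        body_weight=float(raw["body_weight_kg"]),
        cardiac_output=cardiac_output,
        volume_arterial=float(blood["volume_arterial_L"]),
        volume_venous=float(blood["volume_venous_L"]),
        lung=lung,
        tissues=tissues,
        hepatic_clearance=float(raw["hepatic_clearance_L_per_h"]),
        compound=compound,
        eliminating_tissue=str(raw.get("eliminating_tissue", "liver")),
        species=str(raw.get("species", "unspecified")),
    )


def load_pbpk_parameters(path: str | Path) -> PBPKParameters:
    """Load and validate a PBPK parameter file (strict YAML schema)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, Mapping):
        raise ParameterValidationError(f"{path}: not a mapping")
    return parameters_from_dict(raw)


def _packaged(name: str) -> PBPKParameters:
    ref = resources.files("ivive.data").joinpath(name)
    raw = yaml.safe_load(ref.read_text())
    return parameters_from_dict(raw)


def human_parameters() -> PBPKParameters:
    """The shipped representative human parameter fixture (73 kg subject)."""
    return _packaged("human_pbpk.yaml")


def rat_parameters() -> PBPKParameters:
    """The shipped representative rat parameter fixture (0.25 kg animal)."""
    return _packaged("rat_pbpk.yaml")
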