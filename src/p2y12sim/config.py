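"""Parameter bundle I/O: schema-validated YAML/JSON configuration.

One file carries the full model parameterisation: per-drug PK blocks,
per-drug binding blocks, receptor-system constants, and the PD link. The
shipped default configuration is the frozen output of the calibration in
:mod:`p2y12sim.reference` and lives in the package data directory.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import yaml

from .binding import BindingParameterSet, DrugBinding, SystemParameters
from .dosing import Drug
from .pdlink import PDLinkParameters
from .pk import DrugPK, PKParameterSet

__all__ = ["ModelParameters", "load_parameters", "default_parameters_path"]

_PK_FIELDS = ("model", "ka", "lag_h", "V_c", "CL", "Q", "V_p", "f_m", "k_me")
_BINDING_FIELDS = ("mode", "k_on", "k_off", "K_T")


@dataclass(frozen=True)
class ModelParameters:
    """The full calibrated PK + binding + system + PD-link bundle."""

    pk: PKParameterSet
    binding: BindingParameterSet
    system: SystemParameters
    pdlink: PDLinkParameters
    provenance: dict | None = None

    def to_dict(self) -> dict:
        out: dict = {"drugs": {}, "system": {}, "pdlink": {}}
        for drug in (Drug.SELATOGREL, Drug.CLOPIDOGREL, Drug.PRASUGREL, Drug.TICAGRELOR):
            pk = self.pk.get(drug)
            b = self.binding.get(drug)
            if pk is None and b is None:
                continue
            block: dict = {}
            if pk is not None:
                block["pk"] = {f: getattr(pk, f) for f in _PK_FIELDS}
            if b is not None:
                block["binding"] = {f: getattr(b, f) for f in _BINDING_FIELDS}
            out["drugs"][drug.value] = block
        out["system"] = {
            "k_out": self.system.k_out,
            "R0": self.system.R0,
            "PRU0": self.system.PRU0,
            "weight_kg": self.system.weight_kg,
        }
        out["pdlink"] = {"PRU0": self.pdlink.PRU0, "gamma_pru": self.pdlink.gamma_pru}
        if self.provenance:
            out["provenance"] = self.provenance
        return out

    @staticmethod
    def from_dict(data: dict) -> "ModelParameters":
        if "drugs" not in data or "system" not in data:
            raise ValueError("parameter config must contain 'drugs' and 'system' blocks")
        pk_entries: dict[Drug, DrugPK] = {}
        binding_entries: dict[Drug, DrugBinding] = {}
        for name, block in data["drugs"].items():
            drug = Drug(name)
            if "pk" in block:
                unknown = set(block["pk"]) - set(_PK_FIELDS)
                if unknown:
                    raise ValueError(f"unknown PK fields for {name}: {sorted(unknown)}")
                pk_entries[drug] = DrugPK(**block["pk"])
            if "binding" in block:
                unknown = set(block["binding"]) - set(_BINDING_FIELDS)
                if unknown:
                    raise ValueError(
                        f"unknown binding fields for {name}: {sorted(unknown)}"
                    )
                binding_entries[drug] = DrugBinding(**block["binding"])
        system = SystemParameters(**data["system"])
        pdlink = PDLinkParameters(**data.get("pdlink", {}))
        return ModelParameters(
            pk=PKParameterSet(pk_entries),
            binding=BindingParameterSet(binding_entries),
            system=system,
            pdlink=pdlink,
            provenance=data.get("provenance"),
        )

    def canonical_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True, default_flow_style=False)

    def sha256(self) -> str:
        """Hash of the canonical serialisation (embedded in outputs)."""
        return hashlib.sha256(self.canonical_yaml().encode()).hexdigest()

    def save(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix == ".json":
            path.write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))
        else:
            path.write_text(self.canonical_yaml())


def default_parameters_path() -> Path:
    """Location of the shipped calibrated configuration."""
    return Path(resources.files("p2y12sim") / "data" / "default_params.yaml")


def load_parameters(path: str | Path | None = None) -> ModelParameters:
    """Load a parameter config; the shipped calibrated set by default."""
    path = Path(path) if path is not None else default_parameters_path()
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return ModelParameters.from_dict(data)
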