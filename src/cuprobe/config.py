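"""Flat, hand-editable run configuration (YAML).

Concentrations appear in uM at this interface (bench convention) and are
converted to molar at the boundary; equilibrium constants are molar-scale
scientific notation. A run re-executed from its serialized config reproduces
its outputs, so the config round-trips exactly (write -> read -> write is
idempotent).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml

from . import constants
from .metalation import LIGAND_FRACTION
from .speciation import BindingModel
from .titration import OpticalModel

__all__ = ["RunConfig"]


@dataclass(frozen=True)
class RunConfig:
    """Probe constants, optics, and run controls for the pipeline commands."""

    probe_name: str = "BCA"
    probe_ligands_per_complex: int = 2
    probe_formation_constant: float = constants.BCA_BETA2
    epsilon_probe_complex: float = constants.BCA_EPSILON_358
    wavelength_nm: float = constants.BCA_WAVELENGTH_NM
    path_length_cm: float = 1.0
    baseline: float = 0.0
    occupancy_definition: str = LIGAND_FRACTION
    bootstrap_resamples: int = 200
    seed: int = 0

    def probe_model(self) -> BindingModel:
        return BindingModel(
            self.probe_name, self.probe_ligands_per_complex, self.probe_formation_constant
        )

    def optical_model(self) -> OpticalModel:
        return OpticalModel(
            epsilon_probe_complex=self.epsilon_probe_complex,
            wavelength_nm=self.wavelength_nm,
            path_length_cm=self.path_length_cm,
            baseline=self.baseline,
            probe_ligand=self.probe_name,
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(self.to_dict(), sort_keys=True, default_flow_style=False),
            encoding="utf-8",
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        if unknown := set(raw) - known:
            raise ValueError(f"unknown config keys: {sorted(unknown)}; known keys: {sorted(known)}")
        return cls(**raw)
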