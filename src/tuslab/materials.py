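"""Tissue material tables mapping segmentation labels to physical properties.

The default table (``src/tuslab/data/materials.yml``) carries
literature-typical acoustic and thermal values at 500 kHz; it is a
user-editable substitute for a study-specific property table, not a
reproduction of any measured set.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping

import yaml

from .errors import ValidationError

#: Label integers used in every labelled phantom volume.
LABELS = {
    "water": 0,
    "bone": 1,
    "soft_tissue_csf": 2,
    "brain": 3,
    "electrode": 4,
}
LABEL_NAMES = {v: k for k, v in LABELS.items()}

_REQUIRED_FIELDS = (
    "sound_speed",
    "density",
    "absorption",
    "thermal_conductivity",
    "specific_heat",
    "perfusion_rate",
)


@dataclass(frozen=True)
class Material:
    """Acoustic + thermal properties of one tissue class."""

    sound_speed: float  # m/s
    density: float  # kg/m^3
    absorption: float  # Np/m at the carrier frequency
    thermal_conductivity: float  # W/(m K)
    specific_heat: float  # J/(kg K)
    perfusion_rate: float  # 1/s

    def __post_init__(self) -> None:
        if self.sound_speed <= 0 or self.density <= 0 or self.specific_heat <= 0:
            raise ValidationError(
                "sound_speed, density and specific_heat must be > 0"
            )
        if self.absorption < 0 or self.perfusion_rate < 0:
            raise ValidationError("absorption and perfusion_rate must be >= 0")
        if self.thermal_conductivity < 0:
            raise ValidationError("thermal_conductivity must be >= 0")


class MaterialTable(dict):
    """Mapping from label name to :class:`Material`."""

    def __init__(self, materials: Mapping[str, Material]):
        missing = set(LABELS) - set(materials)
        if missing:
            raise ValidationError(
                f"material table missing labels: {sorted(missing)}"
            )
        super().__init__(materials)

    @classmethod
    def from_dict(cls, raw: Mapping[str, Mapping[str, float]]) -> "MaterialTable":
        mats = {}
        for name, props in raw.items():
            missing = [f for f in _REQUIRED_FIELDS if f not in props]
            if missing:
                raise ValidationError(
                    f"material '{name}' missing fields: {missing}"
                )
            mats[name] = Material(**{f: float(props[f]) for f in _REQUIRED_FIELDS})
        return cls(mats)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "MaterialTable":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path: str | Path) -> None:
        raw = {
            name: {f: float(getattr(mat, f)) for f in _REQUIRED_FIELDS}
            for name, mat in self.items()
        }
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)


def default_materials() -> MaterialTable:
    """Load the packaged literature-default material table."""
    ref = resources.files("tuslab").joinpath("data/materials.yml")
    return MaterialTable.from_dict(yaml.safe_load(ref.read_text()))
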