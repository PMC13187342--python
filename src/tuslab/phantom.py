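"""Synthetic labelled head phantoms for desk-scale planning runs.

A phantom is a concentric-layer head immersed in coupling water: a scalp
ring of soft tissue, a bone shell whose thickness carries a sinusoidal
aberration perturbation, a brain interior, and an embedded electrode.
It stands in for a segmented CT (bone / soft-tissue-CSF / electrode) at a
reduced desk scale; the geometry is deterministic given the spec seed.

Coordinates are 0-based voxel indices; world position (mm) = origin +
index * spacing. Axis 0 is lateral (x), the last axis is axial (y/z) with
the transducer side at high coordinate values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Tuple

import nibabel as nib
import numpy as np

from ._rand import child_rng
from .errors import ValidationError
from .materials import LABELS, MaterialTable


@dataclass(frozen=True)
class LabelledVolume:
    """Per-voxel tissue labels on a regular grid.

    ``labels`` holds integers from :data:`tuslab.materials.LABELS`;
    ``spacing`` is isotropic in mm, ``origin`` the world position of voxel
    (0, ..., 0) in mm.
    """

    labels: np.ndarray
    spacing: float
    origin: np.ndarray

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ValidationError("spacing must be > 0")
        object.__setattr__(self, "labels", np.asarray(self.labels))
        object.__setattr__(
            self, "origin", np.asarray(self.origin, dtype=float)
        )
        if self.origin.shape != (self.labels.ndim,):
            raise ValidationError("origin length must match volume rank")
        valid = set(LABELS.values())
        if not set(np.unique(self.labels)) <= valid:
            raise ValidationError("volume contains unknown label values")

    @property
    def shape(self) -> Tuple[int, ...]:
        return self.labels.shape

    def mask(self, name: str) -> np.ndarray:
        return self.labels == LABELS[name]

    def world_to_index(self, position_mm) -> Tuple[int, ...]:
        idx = np.round((np.asarray(position_mm, float) - self.origin) / self.spacing)
        return tuple(int(i) for i in idx)

    def index_to_world(self, index) -> np.ndarray:
        return self.origin + np.asarray(index, float) * self.spacing

    def contains(self, position_mm) -> bool:
        idx = self.world_to_index(position_mm)
        return all(0 <= i < n for i, n in zip(idx, self.shape))

    # --- NIfTI round trip -------------------------------------------------
    def to_nifti(self, path: str | Path) -> None:
        """Write labels as a NIfTI volume (spacing in the affine, mm)."""
        arr = self.labels
        if arr.ndim == 2:  # store 2D phantoms as a single-slice 3D volume
            arr = arr[:, :, None]
        affine = np.diag([self.spacing] * 3 + [1.0])
        affine[: self.origin.size, 3] = self.origin
        nib.save(nib.Nifti1Image(arr.astype(np.int16), affine), str(path))

    @classmethod
    def from_nifti(cls, path: str | Path, ndim: int | None = None) -> "LabelledVolume":
        img = nib.load(str(path))
        arr = np.asarray(img.dataobj).astype(np.int16)
        spacing = float(img.header.get_zooms()[0])
        origin = np.asarray(img.affine[:3, 3], float)
        if ndim == 2 or (ndim is None and arr.shape[-1] == 1):
            arr = arr[:, :, 0]
            origin = origin[:2]
        return cls(labels=arr, spacing=spacing, origin=origin)


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry of the synthetic head phantom.

    All positions are mm world coordinates. ``skull_aberration_amplitude``
    perturbs the skull thickness sinusoidally around the shell
    (``aberration_cycles`` periods, phase drawn from ``seed``), emulating
    the focal aberration a real calvarium induces.
    """

    grid_shape: Tuple[int, ...] = (192, 160)
    spacing: float = 0.5
    head_centre: Tuple[float, ...] = (48.0, 36.0)
    outer_radius: float = 28.0
    scalp_thickness: float = 3.0
    skull_thickness: float = 4.0
    skull_aberration_amplitude: float = 1.2
    aberration_cycles: int = 5
    electrode_position: Tuple[float, ...] = (52.0, 32.0)
    electrode_radius: float = 0.75
    target_gpi: Tuple[float, ...] = (44.0, 30.0)
    target_ventricle: Tuple[float, ...] = (50.0, 40.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ValidationError("spacing must be > 0")
        nd = len(self.grid_shape)
        if nd not in (2, 3):
            raise ValidationError("grid_shape must be 2D or 3D")
        for name in ("head_centre", "electrode_position", "target_gpi", "target_ventricle"):
            if len(getattr(self, name)) != nd:
                raise ValidationError(f"{name} must have {nd} coordinates")
        if tuple(self.target_gpi) == tuple(self.target_ventricle):
            raise ValidationError("target_gpi must differ from target_ventricle")
        if self.skull_thickness <= 0 or self.outer_radius <= 0:
            raise ValidationError("radii and thicknesses must be > 0")


def generate_head_phantom(spec: PhantomSpec):
    """Build the labelled phantom and its target annotations.

    Returns ``(volume, annotations)`` where annotations carry the mm
    positions of both targets and the electrode, plus a suggested receiver
    line/plane coordinate in the coupling water above the head.

    Raises :class:`ValidationError` if the electrode or either target does
    not fall inside the brain compartment.
    """
    nd = len(spec.grid_shape)
    rng = child_rng(spec.seed, "phantom")
    phase = rng.uniform(0, 2 * np.pi)

    idx = np.indices(spec.grid_shape, dtype=float)
    coords = [idx[d] * spec.spacing for d in range(nd)]  # world mm, origin 0
    centre = np.asarray(spec.head_centre, float)
    offs = [coords[d] - centre[d] for d in range(nd)]
    r = np.sqrt(sum(o**2 for o in offs))

    # angular coordinate for the thickness perturbation
    if nd == 2:
        theta = np.arctan2(offs[1], offs[0])
    else:
        theta = np.arctan2(offs[2], np.hypot(offs[0], offs[1]))
    thickness = spec.skull_thickness + spec.skull_aberration_amplitude * np.sin(
        spec.aberration_cycles * theta + phase
    )
    thickness = np.clip(thickness, 1.0, None)

    skull_outer = spec.outer_radius - spec.scalp_thickness
    labels = np.full(spec.grid_shape, LABELS["water"], dtype=np.int16)
    labels[r <= spec.outer_radius] = LABELS["soft_tissue_csf"]
    labels[r <= skull_outer] = LABELS["bone"]
    labels[r <= skull_outer - thickness] = LABELS["brain"]

    r_elec = np.sqrt(
        sum((coords[d] - spec.electrode_position[d]) ** 2 for d in range(nd))
    )
    elec_mask = r_elec <= spec.electrode_radius
    if not np.all(labels[elec_mask] == LABELS["brain"]):
        raise ValidationError("electrode not fully inside brain compartment")
    labels[elec_mask] = LABELS["electrode"]

    volume = LabelledVolume(labels=labels, spacing=spec.spacing, origin=np.zeros(nd))
    for name, pos in (
        ("target_gpi", spec.target_gpi),
        ("target_ventricle", spec.target_ventricle),
    ):
        tidx = volume.world_to_index(pos)
        if not volume.contains(pos) or labels[tidx] != LABELS["brain"]:
            raise ValidationError(f"{name} not inside brain compartment")

    head_top = centre[-1] + spec.outer_radius
    annotations = {
        "target_gpi": np.asarray(spec.target_gpi, float),
        "target_ventricle": np.asarray(spec.target_ventricle, float),
        "electrode": np.asarray(spec.electrode_position, float),
        "head_centre": centre,
        "receiver_coordinate": float(head_top + 8.0),  # mm, in coupling water
        "seed": spec.seed,
    }
    return volume, annotations


@dataclass(frozen=True)
class PropertyMaps:
    """Gridded material property maps derived from a labelled volume."""

    sound_speed: np.ndarray
    density: np.ndarray
    absorption: np.ndarray
    thermal_conductivity: np.ndarray
    specific_heat: np.ndarray
    perfusion_rate: np.ndarray
    spacing: float
    origin: np.ndarray = field(default_factory=lambda: np.zeros(2))


def property_maps(volume: LabelledVolume, materials: MaterialTable) -> PropertyMaps:
    """Expand per-label material properties onto the phantom grid."""
    maps = {}
    for prop in (
        "sound_speed",
        "density",
        "absorption",
        "thermal_conductivity",
        "specific_heat",
        "perfusion_rate",
    ):
        lut = np.zeros(max(LABELS.values()) + 1)
        for name, value in LABELS.items():
            lut[value] = getattr(materials[name], prop)
        maps[prop] = lut[volume.labels]
    return PropertyMaps(spacing=volume.spacing, origin=volume.origin, **maps)
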