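"""Phase-conjugate acoustic lens design and focal verification.

The planning chain follows the time-reversal principle: a backward
simulation from a point source at the deep-brain target yields amplitude
and phase on a receiver plane in the coupling water; the transducer is
placed where the aperture-averaged amplitude is maximal; the receiver
phase over the aperture is conjugated and encoded as a thickness map of a
slow-sounding lens material (PDMS-like); a forward simulation with the
lens applied as a phase screen then verifies focusing, and the field is
rescaled so the in-brain peak equals the protocol target pressure.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Tuple

import numpy as np
from scipy import ndimage

from .errors import ValidationError
from .protocol import PulseProtocol
from .solver import (
    AcousticMedium,
    ComplexField,
    ReceiverField,
    SolverConfig,
    SourceSpec,
    simulate_field,
)

#: Coupling-medium (degassed water) sound speed used for lens wrap thickness.
WATER_SOUND_SPEED = 1482.0


@dataclass(frozen=True)
class TransducerPose:
    """Aperture centre (mm), inward normal, and aperture diameter (mm)."""

    centre: np.ndarray
    normal: np.ndarray
    aperture_diameter: float = 64.0
    tie: bool = False  # True when the placement objective had equal maxima

    def __post_init__(self) -> None:
        object.__setattr__(self, "centre", np.asarray(self.centre, float))
        n = np.asarray(self.normal, float)
        norm = np.linalg.norm(n)
        if norm == 0:
            raise ValidationError("normal must be a nonzero vector")
        object.__setattr__(self, "normal", n / norm)
        if self.aperture_diameter <= 0:
            raise ValidationError("aperture_diameter must be > 0")


@dataclass(frozen=True)
class LensMaterial:
    """Lens casting material; default is PDMS-like silicone."""

    sound_speed: float = 1030.0  # m/s
    name: str = "PDMS"
    base_thickness: float = 2.0  # mm
    max_thickness: float = 12.0  # mm

    def __post_init__(self) -> None:
        if self.sound_speed <= 0:
            raise ValidationError("lens sound_speed must be > 0")


def wrap_thickness(material: LensMaterial, frequency: float,
                   medium_speed: float = WATER_SOUND_SPEED) -> float:
    """One-wavelength (2*pi) wrap thickness t_2pi in mm.

    ``t_2pi = 1 / (f * |1/c_lens - 1/c_medium|)``: the extra lens thickness
    that delays the transmitted wave by one full period relative to the
    coupling medium.
    """
    if material.sound_speed == medium_speed:
        raise ValidationError(
            "lens sound speed equals coupling-medium sound speed: "
            "no phase control possible"
        )
    slowness = abs(1.0 / material.sound_speed - 1.0 / medium_speed)
    return 1.0 / (frequency * slowness) * 1e3


@dataclass(frozen=True)
class LensDesign:
    """Aperture phase map and the thickness map realising it."""

    phase_map: np.ndarray  # rad, in (-pi, pi]
    thickness_map: np.ndarray  # mm
    t_2pi: float  # mm
    element_positions: np.ndarray  # (n, ndim) mm
    frequency: float
    base_thickness: float

    def __post_init__(self) -> None:
        if np.any(self.phase_map > np.pi) or np.any(self.phase_map <= -np.pi):
            raise ValidationError("phase_map must lie in (-pi, pi]")
        tmin, tmax = self.thickness_map.min(), self.thickness_map.max()
        if tmin < self.base_thickness - 1e-9 or tmax >= self.base_thickness + self.t_2pi:
            raise ValidationError("thickness outside [base, base + t_2pi)")

    def to_csv(self, path) -> None:
        np.savetxt(path, np.atleast_2d(self.thickness_map), delimiter=",")

    def to_nifti(self, path, spacing: float = 0.5) -> None:
        """Thickness map (mm) as a NIfTI plane at the aperture sampling."""
        import nibabel as nib

        plane = np.atleast_2d(self.thickness_map)[:, :, None]
        affine = np.diag([spacing, spacing, spacing, 1.0])
        nib.save(nib.Nifti1Image(plane.astype(np.float32), affine), str(path))


@dataclass(frozen=True)
class FocalMetrics:
    """Verification metrics of a focused field."""

    peak_pressure_brain: float  # Pa
    peak_location: np.ndarray  # mm
    targeting_error: float  # mm
    focal_region: np.ndarray  # -6 dB connected-component mask
    focal_extent: float  # mm^2 (2D) or mm^3 (3D)
    electrode_clearance: float  # mm
    drive_scale: float


def _footprint_indices(receiver: ReceiverField, centre_idx, radius_vox: float):
    """In-plane receiver indices whose distance to centre <= radius."""
    grids = np.meshgrid(
        *[np.arange(n) for n in receiver.amplitude.shape], indexing="ij"
    )
    d2 = sum((g - c) ** 2 for g, c in zip(grids, np.atleast_1d(centre_idx)))
    return d2 <= radius_vox**2


def place_transducer(
    receiver: ReceiverField, aperture_diameter: float = 64.0
) -> TransducerPose:
    """Centre the aperture where mean receiver amplitude is maximal.

    Exhaustive search over every candidate centre on the receiver grid
    whose aperture footprint fits inside the plane. Ties are broken to the
    lexicographically first index and flagged on the returned pose.
    """
    amp = receiver.amplitude
    radius_vox = aperture_diameter / 2.0 / receiver.spacing
    half = int(np.floor(radius_vox))
    if any(n <= 2 * half for n in amp.shape):
        raise ValidationError("aperture larger than the receiver plane")

    # centred footprint kernel; objective = mean amplitude over footprint
    kgrids = np.meshgrid(
        *[np.arange(2 * half + 1) for _ in range(amp.ndim)], indexing="ij"
    )
    kernel = (
        sum((g - half) ** 2 for g in kgrids) <= radius_vox**2
    ).astype(float)
    kernel /= kernel.sum()
    means = ndimage.convolve(amp, kernel, mode="constant", cval=np.nan)
    valid = np.isfinite(means)
    sl = tuple(slice(half, n - half) for n in amp.shape)
    mask = np.zeros_like(valid)
    mask[sl] = True
    means = np.where(mask, means, -np.inf)
    best = float(np.nanmax(means))
    winners = np.argwhere(np.isclose(means, best, rtol=1e-12, atol=0.0))
    centre_idx = tuple(winners[0])
    tie = len(winners) > 1

    in_plane = [receiver.coords[d][centre_idx[d]] for d in range(amp.ndim)]
    nd = amp.ndim + 1
    centre = np.empty(nd)
    normal = np.zeros(nd)
    j = 0
    for d in range(nd):
        if d == receiver.plane_axis:
            centre[d] = receiver.plane_coordinate
        else:
            centre[d] = in_plane[j]
            j += 1
    # normal points into the head: towards decreasing plane coordinate
    normal[receiver.plane_axis] = -1.0
    return TransducerPose(
        centre=centre,
        normal=normal,
        aperture_diameter=aperture_diameter,
        tie=tie,
    )


def design_lens(
    receiver: ReceiverField,
    pose: TransducerPose,
    material: LensMaterial = LensMaterial(),
    frequency: float | None = None,
    medium_speed: float = WATER_SOUND_SPEED,
) -> LensDesign:
    """Phase-conjugate lens for the given pose.

    The aperture phase map is the negated receiver phase re-referenced to
    its mean (only relative aberration matters for focusing); the
    thickness map encodes that phase modulo 2*pi in units of the wrap
    thickness on top of the base thickness.
    """
    t2p = wrap_thickness(material, frequency or receiver.frequency, medium_speed)
    amp = receiver.amplitude
    nd = amp.ndim
    # indices of aperture elements on the receiver grid
    centre_in_plane = [
        pose.centre[d] for d in range(nd + 1) if d != receiver.plane_axis
    ]
    centre_idx = [
        int(round((c - receiver.coords[d][0]) / receiver.spacing))
        for d, c in enumerate(centre_in_plane)
    ]
    radius_vox = pose.aperture_diameter / 2.0 / receiver.spacing
    footprint = _footprint_indices(receiver, centre_idx, radius_vox)
    if not footprint.any():
        raise ValidationError("pose footprint outside receiver plane")
    idx = np.argwhere(footprint)
    for d in range(nd):
        if idx[:, d].min() < 0 or idx[:, d].max() >= amp.shape[d]:
            raise ValidationError("pose footprint outside receiver plane")

    psi = receiver.phase[footprint]
    # conjugate and re-reference to the (circular) mean aperture phase
    mean_phase = np.angle(np.mean(np.exp(1j * psi)))
    phase = -(psi - mean_phase)
    phase = np.angle(np.exp(1j * phase))  # wrap to (-pi, pi]
    phase = np.where(phase <= -np.pi, np.pi, phase)
    # sign: a slower lens (PDMS in water) delays, so thickness encodes +phase;
    # a faster material advances and must encode -phase
    s = 1.0 if material.sound_speed < medium_speed else -1.0
    thickness = (
        material.base_thickness
        + (np.mod(s * phase, 2 * np.pi) / (2 * np.pi)) * t2p
    )

    positions = np.empty((idx.shape[0], nd + 1))
    j = 0
    for d in range(nd + 1):
        if d == receiver.plane_axis:
            positions[:, d] = receiver.plane_coordinate
        else:
            positions[:, d] = receiver.coords[j][idx[:, j]]
            j += 1
    return LensDesign(
        phase_map=phase,
        thickness_map=thickness,
        t_2pi=t2p,
        element_positions=positions,
        frequency=frequency or receiver.frequency,
        base_thickness=material.base_thickness,
    )


def lens_phase_screen(design: LensDesign, material: LensMaterial,
                      medium_speed: float = WATER_SOUND_SPEED) -> np.ndarray:
    """Drive phases realised by transmitting through the thickness map.

    Recovered from the thickness (not the stored phase) so that the wrap
    quantisation of a physically cast lens is what verification sees.
    """
    extra_mm = design.thickness_map - design.base_thickness
    delay = (extra_mm * 1e-3) * (1.0 / material.sound_speed - 1.0 / medium_speed)
    # slower lens material (positive delay) retards the wave: phase -w*delay
    sign = 1.0 if material.sound_speed < medium_speed else -1.0
    return sign * 2.0 * np.pi * design.frequency * np.abs(delay)


def focal_metrics(
    field_: ComplexField,
    brain_mask: np.ndarray,
    target_mm,
    electrode_mask: Optional[np.ndarray] = None,
    drive_scale: float = 1.0,
) -> FocalMetrics:
    """Peak localisation, -6 dB focal region, and electrode clearance.

    The peak is the maximum-amplitude voxel over the brain mask (ties:
    first in lexicographic index order); the focal region is the connected
    component containing the peak where amplitude >= half the peak.
    """
    if brain_mask.shape != field_.pressure.shape:
        raise ValidationError("brain mask does not align with field grid")
    amp = field_.amplitude
    masked = np.where(brain_mask, amp, -np.inf)
    peak_flat = int(np.argmax(masked))
    peak_idx = np.unravel_index(peak_flat, amp.shape)
    peak = amp[peak_idx]
    if not peak > 0:
        raise ValidationError("field is zero over the brain mask")
    peak_loc = field_.index_to_world(peak_idx)
    target = np.asarray(target_mm, float)
    err = float(np.linalg.norm(peak_loc - target))

    above = amp >= 0.5 * peak
    labels, _ = ndimage.label(above)
    region = labels == labels[peak_idx]
    voxel = field_.spacing ** amp.ndim
    extent = float(region.sum()) * voxel

    clearance = np.inf
    if electrode_mask is not None and electrode_mask.any():
        dist = ndimage.distance_transform_edt(
            ~electrode_mask, sampling=field_.spacing
        )
        clearance = float(dist[region].min())
    return FocalMetrics(
        peak_pressure_brain=float(peak),
        peak_location=peak_loc,
        targeting_error=err,
        focal_region=region,
        focal_extent=extent,
        electrode_clearance=clearance,
        drive_scale=drive_scale,
    )


def forward_verify(
    medium: AcousticMedium,
    pose: TransducerPose,
    design: LensDesign,
    protocol: PulseProtocol,
    brain_mask: np.ndarray,
    target_mm,
    electrode_mask: Optional[np.ndarray] = None,
    material: LensMaterial = LensMaterial(),
    config: SolverConfig = SolverConfig(),
    apply_lens: bool = True,
) -> Tuple[ComplexField, FocalMetrics]:
    """Forward simulation through the lens, rescaled to the target pressure.

    The lens acts as a thin phase screen on the aperture elements. The
    returned field is linearly rescaled (``drive_scale``) so its in-brain
    peak equals ``protocol.peak_pressure_brain``, and is flagged ``scaled``
    for downstream thermal use. With ``apply_lens=False`` the aperture is
    driven unphased (flat lens), for aberration-benefit comparisons.
    """
    if not brain_mask.any():
        raise ValidationError("empty brain mask")
    phases = lens_phase_screen(design, material) if apply_lens else 0.0
    source = SourceSpec(
        kind="aperture",
        positions=design.element_positions,
        frequency=design.frequency,
        amplitude=1.0,
        phase=phases,
    )
    field_ = simulate_field(medium, source, config)
    amp_brain = np.where(brain_mask, field_.amplitude, 0.0)
    peak = float(amp_brain.max())
    if peak <= 0:
        raise ValidationError("forward field vanished over brain mask")
    scale = protocol.peak_pressure_brain / peak
    scaled = replace(field_, pressure=field_.pressure * scale, scaled=True)
    metrics = focal_metrics(
        scaled, brain_mask, target_mm, electrode_mask, drive_scale=scale
    )
    return scaled, metrics
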