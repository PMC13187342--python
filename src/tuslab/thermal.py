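"""Pennes bioheat simulation of the stimulation protocol's heating.

The verified (pressure-scaled) acoustic field is converted into a
volumetric heat source with the plane-wave absorption relation
``Q = alpha * |p|^2 / (rho * c)`` and fed into an explicit finite-
difference solve of

    rho C dT/dt = div(k grad T) + Q - rho_b C_b w (T - T_a)

on the phantom grid. Temperature is tracked as the rise above the
arterial baseline, so the safety question is simply whether the global
maximum rise stays below the guideline limit (< 2 degC) and the focal
region clears the electrode by more than 5 mm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import ValidationError
from .lens import FocalMetrics
from .phantom import PropertyMaps
from .protocol import PulseProtocol, protocol_timing
from .solver import AcousticMedium, ComplexField


@dataclass(frozen=True)
class ThermalMedium:
    """Gridded thermal properties for the Pennes equation.

    Blood density/specific-heat in the perfusion sink default to the local
    tissue values (configurable via ``blood_rho_c``).
    """

    conductivity: np.ndarray  # W/(m K)
    density: np.ndarray  # kg/m^3
    specific_heat: np.ndarray  # J/(kg K)
    perfusion_rate: np.ndarray  # 1/s
    spacing: float  # mm
    baseline_temperature: float = 37.0  # degC, also arterial
    blood_rho_c: Optional[np.ndarray] = None  # J/(m^3 K); None -> local rho*C

    def __post_init__(self) -> None:
        shapes = {
            self.conductivity.shape,
            self.density.shape,
            self.specific_heat.shape,
            self.perfusion_rate.shape,
        }
        if len(shapes) != 1:
            raise ValidationError("thermal maps must share one shape")
        if np.any(self.density <= 0) or np.any(self.specific_heat <= 0):
            raise ValidationError("density and specific_heat must be > 0")
        if np.any(self.conductivity < 0) or np.any(self.perfusion_rate < 0):
            raise ValidationError("conductivity and perfusion must be >= 0")
        if self.spacing <= 0:
            raise ValidationError("spacing must be > 0")

    @classmethod
    def from_property_maps(cls, maps: PropertyMaps, **kw) -> "ThermalMedium":
        return cls(
            conductivity=maps.thermal_conductivity,
            density=maps.density,
            specific_heat=maps.specific_heat,
            perfusion_rate=maps.perfusion_rate,
            spacing=maps.spacing,
            **kw,
        )


@dataclass(frozen=True)
class QField:
    """Volumetric heat deposition map, W/m^3."""

    q: np.ndarray
    spacing: float
    mode: str  # 'pulse_peak' (on-time heating) or 'duty_averaged'

    def __post_init__(self) -> None:
        if np.any(self.q < 0):
            raise ValidationError("heat deposition must be >= 0 everywhere")
        if self.mode not in ("pulse_peak", "duty_averaged"):
            raise ValidationError("mode must be 'pulse_peak' or 'duty_averaged'")


@dataclass(frozen=True)
class ThermalResult:
    """Outcome of a bioheat solve (temperatures as rises above baseline)."""

    max_rise: float  # degC, global over space and time
    final_rise: np.ndarray  # degC field at the end of the timeline
    trace: np.ndarray  # degC rise at the hottest voxel vs time
    trace_times: np.ndarray  # s
    hottest_location: np.ndarray  # mm


@dataclass(frozen=True)
class SafetyLimits:
    """ITRUSST-style planning gates."""

    max_delta_t: float = 2.0  # degC
    min_electrode_clearance: float = 5.0  # mm

    def __post_init__(self) -> None:
        if self.max_delta_t <= 0 or self.min_electrode_clearance <= 0:
            raise ValidationError("safety limits must be > 0")


@dataclass(frozen=True)
class SafetyReport:
    thermal_pass: bool
    clearance_pass: bool
    overall_pass: bool
    max_rise: float
    electrode_clearance: float
    limits: SafetyLimits


def heat_source(
    field_: ComplexField,
    medium: AcousticMedium,
    protocol: PulseProtocol,
    mode: str = "duty_averaged",
) -> QField:
    """Heat deposition from a pressure-scaled field and pulsing protocol.

    ``pulse_peak`` is the instantaneous on-time heating
    ``alpha |p|^2 / (rho c)``; ``duty_averaged`` multiplies by the
    within-train duty cycle and the train on-fraction (0.003744 for the
    default protocol).
    """
    if not field_.scaled:
        raise ValidationError(
            "heat source requires a pressure-scaled field (run forward_verify "
            "or set the scaled flag after applying drive_scale)"
        )
    q = (
        medium.absorption
        * np.abs(field_.pressure) ** 2
        / (medium.density * medium.sound_speed)
    )
    if mode == "duty_averaged":
        timing = protocol_timing(protocol)
        q = q * timing.duty_averaged_factor
    elif mode != "pulse_peak":
        raise ValidationError("mode must be 'pulse_peak' or 'duty_averaged'")
    return QField(q=q, spacing=field_.spacing, mode=mode)


@dataclass(frozen=True)
class BioheatConfig:
    """Explicit-scheme controls: fraction of the stability bound and the
    minimum number of steps resolving each pulse train."""

    dt_fraction: float = 0.9
    min_steps_per_train: int = 8
    max_dt: Optional[float] = None

    def __post_init__(self) -> None:
        if not (0 < self.dt_fraction <= 1):
            raise ValidationError("dt_fraction must be in (0, 1]")
        if self.min_steps_per_train < 1:
            raise ValidationError("min_steps_per_train must be >= 1")


def stable_time_step(medium: ThermalMedium) -> float:
    """Largest stable explicit step for the diffusion + perfusion terms."""
    dx = medium.spacing * 1e-3
    rho_c = medium.density * medium.specific_heat
    diffusive = rho_c * dx**2 / (2.0 * medium.conductivity.ndim * np.maximum(medium.conductivity, 1e-30))
    blood = medium.blood_rho_c if medium.blood_rho_c is not None else rho_c
    w = medium.perfusion_rate
    with np.errstate(divide="ignore"):
        perfusive = np.where(w > 0, rho_c / (blood * w), np.inf)
    return float(min(diffusive.min(), perfusive.min()))


def _laplacian_var_k(t: np.ndarray, k: np.ndarray, dx: float) -> np.ndarray:
    """div(k grad T) with face-averaged conductivity, zero-flux edges."""
    out = np.zeros_like(t)
    for d in range(t.ndim):
        k_face = 0.5 * (k + np.roll(k, -1, axis=d))
        flux = k_face * (np.roll(t, -1, axis=d) - t)  # at face i+1/2
        # zero flux through the high boundary; the roll below then wraps
        # this zero to the low boundary, closing both ends
        sl = [slice(None)] * t.ndim
        sl[d] = -1
        flux[tuple(sl)] = 0.0
        out += (flux - np.roll(flux, 1, axis=d)) / dx**2
    return out


def simulate_bioheat(
    q: QField,
    medium: ThermalMedium,
    duration: float,
    mode: str = "duty_averaged",
    protocol: Optional[PulseProtocol] = None,
    config: BioheatConfig = BioheatConfig(),
    initial_rise: Optional[np.ndarray] = None,
) -> ThermalResult:
    """Solve the Pennes equation for ``duration`` seconds.

    ``duty_averaged`` applies the (already duty-scaled) Q continuously;
    ``train_resolved`` gates a pulse-peak Q on for ``train_duration`` out
    of every ``train_period`` (scaled by the within-train duty cycle, i.e.
    pulses inside a train are averaged, trains are resolved).
    """
    if mode not in ("duty_averaged", "train_resolved"):
        raise ValidationError("mode must be 'duty_averaged' or 'train_resolved'")
    if mode == "duty_averaged" and q.mode != "duty_averaged":
        raise ValidationError("duty_averaged timeline requires a duty_averaged Q")
    if mode == "train_resolved":
        if protocol is None:
            raise ValidationError("train_resolved timeline requires the protocol")
        if q.mode != "pulse_peak":
            raise ValidationError("train_resolved timeline requires a pulse_peak Q")

    dx = medium.spacing * 1e-3
    rho_c = medium.density * medium.specific_heat
    blood = medium.blood_rho_c if medium.blood_rho_c is not None else rho_c
    sink = blood * medium.perfusion_rate  # W/(m^3 K)

    dt = config.dt_fraction * stable_time_step(medium)
    if mode == "train_resolved":
        dt = min(dt, protocol.train_duration / config.min_steps_per_train)
    if config.max_dt is not None:
        if config.max_dt > stable_time_step(medium):
            raise ValidationError(
                f"requested dt {config.max_dt:.4g}s exceeds stable bound "
                f"{stable_time_step(medium):.4g}s"
            )
        dt = min(dt, config.max_dt)
    n_steps = max(1, int(math.ceil(duration / dt)))
    dt = duration / n_steps

    if mode == "train_resolved":
        timing = protocol_timing(protocol)
        q_on = q.q * timing.duty_cycle_within_train
    else:
        q_on = q.q
    decay = np.exp(-sink * dt / rho_c)

    if initial_rise is not None:
        t_field = np.array(initial_rise, dtype=float)
        if t_field.shape != q.q.shape:
            raise ValidationError("initial_rise shape mismatch")
    else:
        t_field = np.zeros_like(q.q, dtype=float)
    max_rise = float(t_field.max()) if t_field.size else 0.0
    # hottest voxel tracked at the Q maximum (trace location fixed up-front)
    hot_idx = np.unravel_index(int(np.argmax(q.q + t_field)), q.q.shape)
    trace = np.empty(n_steps + 1)
    trace[0] = t_field[hot_idx]
    times = np.arange(n_steps + 1) * dt

    for n in range(n_steps):
        t_now = n * dt
        if mode == "train_resolved":
            on = (t_now % protocol.train_period) < protocol.train_duration
            q_step = q_on if on else 0.0
        else:
            q_step = q_on
        lap = _laplacian_var_k(t_field, medium.conductivity, dx)
        # explicit diffusion + source, exact exponential perfusion sink
        t_field = (t_field + dt * (lap + q_step) / rho_c) * decay
        step_max = float(t_field.max())
        if step_max > max_rise:
            max_rise = step_max
        trace[n + 1] = t_field[hot_idx]

    hottest = np.asarray(hot_idx, float) * medium.spacing
    return ThermalResult(
        max_rise=max_rise,
        final_rise=t_field,
        trace=trace,
        trace_times=times,
        hottest_location=hottest,
    )


def safety_report(
    thermal: ThermalResult,
    focal: FocalMetrics,
    limits: SafetyLimits = SafetyLimits(),
) -> SafetyReport:
    """Apply the planning gates: max rise strictly below the temperature
    limit, electrode clearance strictly above the distance limit."""
    thermal_pass = thermal.max_rise < limits.max_delta_t
    clearance_pass = focal.electrode_clearance > limits.min_electrode_clearance
    return SafetyReport(
        thermal_pass=thermal_pass,
        clearance_pass=clearance_pass,
        overall_pass=thermal_pass and clearance_pass,
        max_rise=thermal.max_rise,
        electrode_clearance=focal.electrode_clearance,
        limits=limits,
    )
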