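"""Pulsed ultrasound stimulation protocol and its timing arithmetic.

The default protocol mirrors clinical deep-brain-stimulation timing:
90 µs pulses at a 130 Hz pulse repetition frequency, delivered in 800 ms
trains repeated every 2.5 s (a 1.7 s cooling gap), within 5-minute blocks,
with the field scaled to a 600 kPa peak pressure in brain tissue.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ValidationError


@dataclass(frozen=True)
class PulseProtocol:
    """Timing and target pressure of a pulsed-ultrasound stimulation protocol.

    Attributes
    ----------
    fundamental_frequency : float
        Carrier frequency in Hz.
    pulse_duration : float
        Duration of one ultrasound pulse in seconds.
    prf : float
        Pulse repetition frequency within a train, Hz.
    train_duration : float
        On-time of one pulse train, seconds.
    train_period : float
        Interval between train onsets, seconds. ``train_period ==
        train_duration`` means continuous pulsing (no train gating).
    block_duration : float
        Duration of one stimulation block, seconds.
    peak_pressure_brain : float
        Target peak pressure in brain tissue, Pa.
    """

    fundamental_frequency: float = 500e3
    pulse_duration: float = 90e-6
    prf: float = 130.0
    train_duration: float = 0.8
    train_period: float = 2.5
    block_duration: float = 300.0
    peak_pressure_brain: float = 600e3

    def __post_init__(self) -> None:
        for name in (
            "fundamental_frequency",
            "pulse_duration",
            "prf",
            "train_duration",
            "train_period",
            "block_duration",
            "peak_pressure_brain",
        ):
            if not getattr(self, name) > 0:
                raise ValidationError(f"PulseProtocol.{name} must be > 0")
        if self.pulse_duration > 1.0 / self.prf:
            raise ValidationError(
                "pulse_duration must not exceed the pulse period 1/prf"
            )
        if self.train_duration > self.train_period:
            raise ValidationError("train_duration must not exceed train_period")
        duty = self.pulse_duration * self.prf
        if not (0.0 < duty <= 1.0):
            raise ValidationError(
                f"within-train duty cycle {duty:.4g} outside (0, 1]"
            )


@dataclass(frozen=True)
class ProtocolTiming:
    """Derived timing summary of a :class:`PulseProtocol`."""

    duty_cycle_within_train: float
    pulses_per_train: int
    train_on_fraction: float
    intertrain_gap: float
    duty_averaged_factor: float = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "duty_averaged_factor",
            self.duty_cycle_within_train * self.train_on_fraction,
        )


def protocol_timing(protocol: PulseProtocol) -> ProtocolTiming:
    """Compute duty cycle, pulse count and gap timing for a protocol.

    For the default protocol this yields the familiar numbers: a 1.17 %
    within-train duty cycle (90 µs × 130 Hz), 104 pulses per 800 ms train,
    and a 1.7 s inter-train cooling gap.
    """
    import math

    return ProtocolTiming(
        duty_cycle_within_train=protocol.pulse_duration * protocol.prf,
        pulses_per_train=math.floor(protocol.train_duration * protocol.prf),
        train_on_fraction=protocol.train_duration / protocol.train_period,
        intertrain_gap=protocol.train_period - protocol.train_duration,
    )


#: 5 Hz "theta" positive-control protocol used for artefact characterisation:
#: 20 ms pulses at 5 Hz PRF, continuous (no train gating).
THETA_CONTROL_PROTOCOL = PulseProtocol(
    pulse_duration=20e-3,
    prf=5.0,
    train_duration=2.5,
    train_period=2.5,
)
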