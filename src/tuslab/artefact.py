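"""Mechanical pulsed-ultrasound artefact as seen by an implanted electrode.

When a DBS electrode tip is sonicated directly, the pulse train couples
into the recording as a periodic signal whose Fourier content sits at
harmonics of the pulse repetition frequency. The recording hardware
applies a low-pass (100 Hz in the modelled device) before sampling at
250 Hz. This produces a sharp dichotomy: a 5 Hz PRF places harmonics at
5, 10, 15, ... Hz — squarely inside the beta band — while a 130 Hz PRF
has its fundamental above the hardware cutoff, so nothing coherent lands
in band (the residual 130 Hz component aliases to 120 Hz, outside beta,
and is already filter-attenuated).

The coupling physics is not identified, so both a linear-in-pressure and
a pressure-squared coupling are provided (quadratic default, matching a
radiation-force-like dose response).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from ._rand import child_rng
from .bands import BANDS, Band
from .ephys import WelchConfig, band_power, welch_psd
from .errors import ValidationError
from .protocol import PulseProtocol


@dataclass(frozen=True)
class CouplingModel:
    """Map from peak pressure to the recorded artefact amplitude."""

    mode: str = "pressure_squared"  # or 'linear_pressure'
    gain: float = 1e-11  # recording units per Pa (or per Pa^2)

    def __post_init__(self) -> None:
        if self.mode not in ("linear_pressure", "pressure_squared"):
            raise ValidationError("coupling mode unknown")
        if self.gain < 0:
            raise ValidationError("coupling gain must be >= 0")

    def amplitude(self, pressure_pa: float) -> float:
        if self.mode == "linear_pressure":
            return self.gain * pressure_pa
        return self.gain * pressure_pa**2


@dataclass(frozen=True)
class HardwareChain:
    """Device front-end: low-pass filter then decimation to the ADC rate."""

    lpf_cutoff: float = 100.0  # Hz
    lpf_order: int = 2
    sampling_rate: float = 250.0  # Hz
    internal_rate: float = 10e3  # simulation rate before decimation
    lpf_enabled: bool = True

    def __post_init__(self) -> None:
        if self.lpf_cutoff >= self.sampling_rate:
            raise ValidationError("lpf cutoff must be below the sampling rate")
        if self.lpf_order < 1:
            raise ValidationError("lpf order must be >= 1")


@dataclass(frozen=True)
class ArtefactResult:
    recording: np.ndarray  # at the chain sampling rate
    rate: float
    baseline: np.ndarray  # noise-only recording with the same seed
    protocol: PulseProtocol
    pressure: float


def harmonic_series(
    pulse_duration: float, prf: float, n_harmonics: int
) -> np.ndarray:
    """Fourier magnitudes of the unit rectangular pulse train.

    Returns rows ``(frequency = k*prf, magnitude)`` for k = 1..n, with
    magnitude ``2 * d * |sinc(k d)|`` (d = duty = pulse_duration * prf),
    i.e. the peak amplitude of the k-th cosine component of a unit-height
    train. Nulls fall where ``k * d`` is an integer.
    """
    if n_harmonics < 1:
        raise ValidationError("n_harmonics must be >= 1")
    d = pulse_duration * prf
    k = np.arange(1, n_harmonics + 1)
    mags = 2.0 * d * np.abs(np.sinc(k * d))
    return np.column_stack([k * prf, mags])


def artefact_timeseries(
    protocol: PulseProtocol,
    pressure: float,
    coupling: CouplingModel = CouplingModel(),
    chain: HardwareChain = HardwareChain(),
    duration: float = 30.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> ArtefactResult:
    """Simulate an electrode recording during direct sonication.

    The continuous-time model is a rectangular pulse train (width =
    pulse duration, period = 1/PRF, amplitude from the coupling model)
    gated by the train envelope, run at the chain's internal rate,
    low-pass filtered, then decimated by bare subsampling — residual
    aliasing is intentional, as in the hardware. Baseline noise is added
    from the seed; the matching noise-only baseline is returned too.
    """
    if duration < 5.0:
        raise ValidationError("duration must be >= 5 s")
    if chain.internal_rate < 10 * protocol.prf:
        raise ValidationError(
            "internal rate must be >= 10x the pulse repetition frequency"
        )
    fs = chain.internal_rate
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    amp = coupling.amplitude(pressure)
    in_pulse = (t % (1.0 / protocol.prf)) < protocol.pulse_duration
    in_train = (t % protocol.train_period) < protocol.train_duration
    x = amp * (in_pulse & in_train).astype(float)

    if chain.lpf_enabled:
        sos = sps.butter(
            chain.lpf_order, chain.lpf_cutoff, btype="low", fs=fs, output="sos"
        )
        x = sps.sosfilt(sos, x)

    step = fs / chain.sampling_rate
    if abs(step - round(step)) > 1e-9:
        raise ValidationError(
            "internal rate must be an integer multiple of the sampling rate"
        )
    x = x[:: int(round(step))]

    rng = child_rng(seed, "artefact-noise")
    noise = noise_sd * rng.standard_normal(x.size) if noise_sd > 0 else np.zeros(x.size)
    return ArtefactResult(
        recording=x + noise,
        rate=chain.sampling_rate,
        baseline=noise.copy(),
        protocol=protocol,
        pressure=pressure,
    )


def artefact_beta_change(
    recording: np.ndarray,
    baseline: np.ndarray,
    rate: float = 250.0,
    welch_config: WelchConfig = WelchConfig(normalise=False),
    band: Band | str = BANDS["beta"],
) -> float:
    """Band power of the recording relative to the baseline recording."""
    if recording.size != baseline.size:
        raise ValidationError("recording and baseline must have equal length")
    p_rec = band_power(welch_psd(recording, rate, welch_config), band)
    p_base = band_power(welch_psd(baseline, rate, welch_config), band)
    if p_base <= 0:
        raise ValidationError("baseline band power is zero")
    return p_rec / p_base


def artefact_session(
    protocol: PulseProtocol,
    pressure: float,
    coupling: CouplingModel = CouplingModel(),
    chain: HardwareChain = HardwareChain(),
    block_duration: float = 30.0,
    noise_sd: float = 0.1,
    eeg_rate: float = 512.0,
    seed: int = 0,
):
    """Wrap a bench artefact experiment in the standard session format.

    The left electrode channels carry the sonication artefact in the
    active blocks and baseline noise in the sham blocks; right and EEG
    channels are baseline noise throughout. The result flows through the
    spectral pipeline unchanged, so the artefact's effect on the sham-
    normalised beta contrast can be quantified with the same code that
    analyses physiological sessions.
    """
    from .signals import (
        Block,
        DAYS,
        EEG_CHANNELS,
        LFP_CHANNELS,
        RecordingSession,
    )

    gap = 5.0
    blocks = []
    t = 0.0
    for day in DAYS:
        for condition in ("sham", "active"):
            blocks.append(Block(day, condition, "rest", t, block_duration))
            t += block_duration + gap
    duration = t

    rng = child_rng(seed, "artefact-session")
    n_lfp = int(round(duration * chain.sampling_rate))
    channels = {}
    for ch in LFP_CHANNELS:
        channels[ch] = noise_sd * rng.standard_normal(n_lfp)
    for ch in EEG_CHANNELS:
        channels[ch] = noise_sd * rng.standard_normal(int(round(duration * eeg_rate)))

    # sonicate the left electrode during active blocks only
    for ib, block in enumerate(blocks):
        if block.condition != "active":
            continue
        res = artefact_timeseries(
            protocol, pressure, coupling, chain, block.duration,
            noise_sd=0.0, seed=child_seed_for_block(seed, ib),
        )
        i0 = int(round(block.start * chain.sampling_rate))
        for ch in ("Left_0-2", "Left_1-3"):
            seg = channels[ch][i0 : i0 + res.recording.size]
            seg += res.recording[: seg.size]

    rates = {ch: chain.sampling_rate for ch in LFP_CHANNELS}
    rates.update({ch: eeg_rate for ch in EEG_CHANNELS})
    sync = {
        "lfp": np.array([0.5, 1.0, 1.7]),
        "eeg": np.array([0.5, 1.0, 1.7]),
    }
    return RecordingSession(
        channels=channels, rates=rates, sync_events=sync, blocks=blocks
    )


def child_seed_for_block(seed: int, block_index: int) -> int:
    from ._rand import child_seed

    return child_seed(seed, "artefact-block", block_index)


def inband_artefact_power(
    protocol: PulseProtocol,
    pressure: float,
    coupling: CouplingModel = CouplingModel(),
    chain: HardwareChain = HardwareChain(),
    duration: float = 30.0,
    band: Band | str = BANDS["beta"],
) -> float:
    """Noiseless in-band artefact power for a protocol (dichotomy probe)."""
    res = artefact_timeseries(
        protocol, pressure, coupling, chain, duration, noise_sd=0.0
    )
    psd = welch_psd(res.recording, res.rate, WelchConfig(normalise=False))
    return band_power(psd, band)
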