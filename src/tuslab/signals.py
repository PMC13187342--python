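"""Synthetic multi-rate electrophysiology sessions with known ground truth.

Each virtual participant yields a two-day recording (GPi day, Ventricle
day), each day a sham rest block followed by an active rest block, across
four bipolar subthalamic LFP channels at 250 Hz and two bipolar motor-
cortex EEG channels at 4096 Hz. Channels are built from three parts:

* an aperiodic 1/f background plus white noise, synthesised by random-
  phase spectral shaping so its realised spectrum (hence any band power)
  is known exactly;
* narrowband oscillations (low/high beta, optional 4-6 Hz tremor):
  band-pass-filtered white noise carriers multiplied by a slowly varying
  log-normal gain, giving controllable spectral peaks and block-level
  power co-fluctuation;
* planted condition effects: active blocks scale beta amplitudes by a
  per-band suppression factor on the targeted day, and the left M1
  channel shares a fraction (``ipsilateral_coupling``) of the left STN
  log-gain process.

Every realised component variance is recorded per block, so the returned
:class:`GroundTruth` states the exact planted relative band-power change
the analysis pipeline should recover.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dfield
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import signal as sps

from ._rand import child_rng
from .bands import ANALYSIS, BANDS, classify_peak
from .errors import ValidationError
from .filters import two_pass_power_response

LFP_CHANNELS = ("Left_0-2", "Left_1-3", "Right_0-2", "Right_1-3")
EEG_CHANNELS = ("C3Cz", "C4Cz")
LFP_RATE = 250.0

CHANNEL_GROUPS = {
    "stn_left": ("Left_0-2", "Left_1-3"),
    "stn_right": ("Right_0-2", "Right_1-3"),
    "m1_left": ("C3Cz",),
    "m1_right": ("C4Cz",),
}
GROUP_OF_CHANNEL = {
    ch: grp for grp, chans in CHANNEL_GROUPS.items() for ch in chans
}
DAYS = ("GPi_day", "Ventricle_day")


@dataclass(frozen=True)
class Peak:
    """One oscillatory spectral peak: centre (Hz), amplitude (signal
    units of standard deviation), and -3 dB bandwidth (Hz)."""

    centre_hz: float
    amplitude: float
    bandwidth_hz: float

    def __post_init__(self) -> None:
        if self.bandwidth_hz <= 0:
            raise ValidationError("peak bandwidth must be > 0")
        if self.amplitude < 0:
            raise ValidationError("peak amplitude must be >= 0")

    @property
    def band(self) -> str:
        return classify_peak(self.centre_hz)


def _default_peaks() -> Dict[str, Tuple[Peak, ...]]:
    stn = (Peak(17.0, 0.55, 3.0), Peak(25.0, 0.40, 4.0))
    m1 = (Peak(17.0, 0.35, 3.0), Peak(25.0, 0.30, 4.0))
    return {
        "stn_left": stn,
        "stn_right": stn,
        "m1_left": m1,
        "m1_right": m1,
    }


def _default_suppression() -> Dict[Tuple[str, str, str], float]:
    # amplitude factor on left-STN beta during GPi-day active blocks,
    # calibrated so the expected site-contrasted relative beta-power
    # reduction sits at the ~10.3% group level: with the default beta
    # share the contrast slope is ~31 pp per (1 - s^2), giving s ~ 0.82
    return {
        ("stn_left", "low_beta", "GPi_day"): 0.82,
        ("stn_left", "high_beta", "GPi_day"): 0.82,
    }


@dataclass(frozen=True)
class ParticipantSpec:
    """Generative model of one virtual participant's oscillatory activity."""

    aperiodic_slope: float = 1.5
    aperiodic_offset: float = 1.0
    noise_sd: float = 0.3
    peaks: Dict[str, Tuple[Peak, ...]] = dfield(default_factory=_default_peaks)
    suppression: Dict[Tuple[str, str, str], float] = dfield(
        default_factory=_default_suppression
    )
    ipsilateral_coupling: float = 0.9
    tremor: Optional[Tuple[float, float]] = None  # (centre Hz in 4-6, amplitude)
    day_drift: float = 1.1  # amplitude multiplier applied on the second day
    gain_sd: float = 0.4  # sd of the log-gain process
    gain_timescale_s: float = 5.0
    eeg_rate: float = 4096.0
    seed: int = 0

    def __post_init__(self) -> None:
        for key, s in self.suppression.items():
            if not (0.0 < s <= 1.0):
                raise ValidationError(f"suppression factor {key} outside (0, 1]")
        if not (0.0 <= self.ipsilateral_coupling <= 1.0):
            raise ValidationError("ipsilateral_coupling must be in [0, 1]")
        if self.tremor is not None and not (4.0 <= self.tremor[0] <= 6.0):
            raise ValidationError("tremor centre must lie in 4-6 Hz")
        if self.gain_sd < 0 or self.gain_timescale_s <= 0:
            raise ValidationError("gain parameters must be positive")


@dataclass(frozen=True)
class Block:
    day: str
    condition: str  # 'sham' | 'active'
    task: str  # 'rest' | 'rdm'
    start: float  # s
    duration: float  # s

    def __post_init__(self) -> None:
        if self.day not in DAYS:
            raise ValidationError(f"unknown day {self.day!r}")
        if self.condition not in ("sham", "active"):
            raise ValidationError(f"unknown condition {self.condition!r}")
        if self.duration <= 0:
            raise ValidationError("block duration must be > 0")

    @property
    def end(self) -> float:
        return self.start + self.duration


def default_schedule(block_duration: float = 300.0, gap: float = 30.0) -> List[Block]:
    """Two-day rest schedule: on each day a sham block precedes the active
    block (the day's within-session baseline)."""
    blocks = []
    t = 0.0
    for day in DAYS:
        blocks.append(Block(day, "sham", "rest", t, block_duration))
        t += block_duration + gap
        blocks.append(Block(day, "active", "rest", t, block_duration))
        t += block_duration + gap
    return blocks


def validate_schedule(blocks: Sequence[Block]) -> None:
    if not blocks:
        raise ValidationError("empty block schedule")
    for day in {b.day for b in blocks}:
        day_blocks = sorted(
            (b for b in blocks if b.day == day), key=lambda b: b.start
        )
        for a, b in zip(day_blocks, day_blocks[1:]):
            if b.start < a.end:
                raise ValidationError(
                    f"overlapping blocks on {day}: {a} / {b}"
                )
        for b in day_blocks:
            if b.condition != "active":
                continue
            shams = [
                s
                for s in day_blocks
                if s.condition == "sham" and s.task == b.task and s.start < b.start
            ]
            if not shams:
                raise ValidationError(
                    f"active block on {day} ({b.task}) lacks a preceding sham"
                )


@dataclass
class RecordingSession:
    """Multi-rate recording: channel arrays, rates, sync events, schedule."""

    channels: Dict[str, np.ndarray]
    rates: Dict[str, float]
    sync_events: Dict[str, np.ndarray]  # stream -> pulse times, local clock, s
    blocks: List[Block]

    def __post_init__(self) -> None:
        missing = (set(LFP_CHANNELS) | set(EEG_CHANNELS)) - set(self.channels)
        if missing:
            raise ValidationError(f"session missing channels: {sorted(missing)}")
        validate_schedule(self.blocks)

    def block_samples(self, channel: str, block: Block) -> np.ndarray:
        rate = self.rates[channel]
        i0 = int(round(block.start * rate))
        i1 = int(round(block.end * rate))
        return self.channels[channel][i0:i1]

    def rest_block(self, day: str, condition: str) -> Block:
        for b in self.blocks:
            if b.day == day and b.condition == condition and b.task == "rest":
                return b
        raise ValidationError(f"no rest block for ({day}, {condition})")


@dataclass
class GroundTruth:
    """Planted effects, computed from realised component variances.

    ``band_table`` rows: channel, band, day, condition, band power and the
    per-(channel, band, day) true relative reduction in normalised band
    power (percent). ``gain_table``: per block realised mean-square gain
    of each group's beta components (for coupling-structure checks).
    ``rt_reduction_pct``: planted normalised-median RT reduction per day
    (filled by the behaviour generator when used together).
    """

    band_table: pd.DataFrame
    gain_table: pd.DataFrame
    rt_reduction_pct: Dict[str, float] = dfield(default_factory=dict)

    def true_relative_reduction(self, channel: str, band: str, day: str) -> float:
        t = self.band_table
        row = t[(t.channel == channel) & (t.band == band) & (t.day == day)]
        return float(row.true_rel_reduction_pct.iloc[0])


def _shaped_background(rng, n, fs, offset, slope, noise_sd):
    """Random-phase 1/f + white background; returns (x, psd_value_fn).

    The synthesis fixes each rfft magnitude to the model spectrum and
    randomises only phases, so the realised PSD equals the model exactly
    and band powers are analytic.
    """
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    df = fs / n
    psd = np.zeros_like(freqs)
    psd[1:] = offset**2 / freqs[1:] ** slope
    psd += noise_sd**2 / (fs / 2.0)
    mags = np.sqrt(psd * df / 2.0) * n
    mags[0] = 0.0
    phases = rng.uniform(0, 2 * np.pi, size=freqs.size)
    spec = mags * np.exp(1j * phases)
    spec[0] = 0.0
    if n % 2 == 0:
        spec[-1] = mags[-1] * np.cos(phases[-1]) * np.sqrt(2.0)
    x = np.fft.irfft(spec, n=n)

    # band powers are booked through the standard zero-phase analysis
    # filter's power response, matching what the pipeline can observe
    weight = two_pass_power_response(freqs)

    def band_power(low, high, bin_width=1.0):
        # the analysis sums 1 Hz Welch bins whose centres lie in the band;
        # each bin collects ~+-bin_width/2 beyond its centre, so book the
        # continuum over the bin-extent range
        half = bin_width / 2.0
        sel = (freqs >= low - half) & (freqs < high + half)
        return float(np.sum(psd[sel] * weight[sel]) * df)

    return x, band_power


def _slow_log_gain(rng, n, fs, timescale_s, internal_rate=25.0):
    """Unit-sd slow Gaussian process (Gaussian-smoothed white noise).

    Synthesised at a coarse internal rate and linearly interpolated, since
    the process only carries sub-Hz power."""
    from scipy.ndimage import gaussian_filter1d

    n_coarse = max(int(np.ceil(n / fs * internal_rate)) + 2, 16)
    raw = rng.standard_normal(n_coarse)
    smooth = gaussian_filter1d(raw, timescale_s * internal_rate, mode="wrap")
    sd = smooth.std()
    if sd > 0:
        smooth /= sd
    t_coarse = np.arange(n_coarse) / internal_rate
    return np.interp(np.arange(n) / fs, t_coarse, smooth)


from functools import lru_cache


@lru_cache(maxsize=256)
def _carrier_band_fractions(fs: float, centre: float, bw: float):
    """Fraction of a carrier's power per band on the analysis Welch grid.

    Measured once per (rate, centre, bandwidth) on a long deterministic
    probe realisation, through the standard zero-phase filter response
    and with inclusive 1 Hz band-edge binning — the same conventions the
    pipeline bins power with.
    """
    low = max(centre - bw / 2.0, 0.1)
    high = min(centre + bw / 2.0, 0.49 * fs)
    sos = sps.butter(4, [low, high], btype="bandpass", fs=fs, output="sos")
    probe_rng = np.random.default_rng(123456789)
    n = int(128 * fs)
    y = sps.sosfilt(sos, probe_rng.standard_normal(n))
    nperseg = int(round(fs))
    freqs, pxx = sps.welch(
        y, fs=fs, window="hann", nperseg=nperseg, noverlap=int(0.6 * nperseg)
    )
    total = pxx.sum()
    weight = two_pass_power_response(freqs)
    return {
        name: float(
            (pxx * weight)[(freqs >= b.low) & (freqs <= b.high)].sum() / total
        )
        for name, b in BANDS.items()
    }


def _narrowband_carrier(rng, n, fs, centre, bw):
    low = max(centre - bw / 2.0, 0.1)
    high = min(centre + bw / 2.0, 0.49 * fs)
    sos = sps.butter(4, [low, high], btype="bandpass", fs=fs, output="sos")
    y = sps.sosfilt(sos, rng.standard_normal(n))
    sd = y.std()
    y = y / sd if sd > 0 else y
    return y, _carrier_band_fractions(float(fs), float(centre), float(bw))


def _condition_factor(spec: ParticipantSpec, group: str, band: str,
                      block: Block) -> float:
    if block.condition != "active":
        return 1.0
    return spec.suppression.get((group, band, block.day), 1.0)


def generate_session(
    spec: ParticipantSpec,
    schedule: Optional[Sequence[Block]] = None,
    clock_offset_s: float = 0.5,
    n_sync_pulses: int = 10,
) -> Tuple[RecordingSession, GroundTruth]:
    """Generate one participant session plus its planted ground truth.

    Deterministic given ``spec`` (including ``spec.seed``). The EEG stream
    runs on a clock shifted by ``clock_offset_s`` relative to the LFP
    stream, with shared TENS-style sync pulses recorded in both local
    clocks for alignment testing.
    """
    blocks = list(schedule) if schedule is not None else default_schedule()
    validate_schedule(blocks)
    for day in DAYS:
        conds = {b.condition for b in blocks if b.day == day}
        if not {"sham", "active"} <= conds:
            raise ValidationError(f"schedule lacks sham+active blocks on {day}")

    duration = max(b.end for b in blocks) + 5.0
    day_factor = {DAYS[0]: 1.0, DAYS[1]: spec.day_drift}

    rates = {ch: LFP_RATE for ch in LFP_CHANNELS}
    rates.update({ch: spec.eeg_rate for ch in EEG_CHANNELS})

    # shared log-gain processes per group (at LFP rate; resampled for EEG)
    gain_logs: Dict[str, np.ndarray] = {}
    n_lfp = int(round(duration * LFP_RATE))
    for grp in CHANNEL_GROUPS:
        gain_logs[grp] = _slow_log_gain(
            child_rng(spec.seed, "gain", grp), n_lfp, LFP_RATE,
            spec.gain_timescale_s,
        )
    c = spec.ipsilateral_coupling
    gain_logs["m1_left"] = (
        c * gain_logs["stn_left"]
        + np.sqrt(max(0.0, 1.0 - c**2)) * gain_logs["m1_left"]
    )

    channels: Dict[str, np.ndarray] = {}
    band_rows = []
    gain_rows = []
    lfp_t = np.arange(n_lfp) / LFP_RATE

    for ch in LFP_CHANNELS + EEG_CHANNELS:
        fs = rates[ch]
        n = int(round(duration * fs))
        grp = GROUP_OF_CHANNEL[ch]
        bg, bg_band_power = _shaped_background(
            child_rng(spec.seed, "background", ch), n, fs,
            spec.aperiodic_offset, spec.aperiodic_slope, spec.noise_sd,
        )
        x = bg

        log_gain = gain_logs[grp]
        if fs != LFP_RATE:
            t_fs = np.arange(n) / fs
            log_gain = np.interp(t_fs, lfp_t, log_gain)
        gain = np.exp(spec.gain_sd * log_gain - 0.5 * spec.gain_sd**2)

        peaks = list(spec.peaks.get(grp, ()))
        if spec.tremor is not None:
            peaks.append(Peak(spec.tremor[0], spec.tremor[1], 1.0))
        comp_block_power: Dict[int, Dict[int, float]] = {}
        comp_fractions = []
        for ip, peak in enumerate(peaks):
            carrier, fractions = _narrowband_carrier(
                child_rng(spec.seed, "carrier", ch, ip), n, fs,
                peak.centre_hz, peak.bandwidth_hz,
            )
            comp = peak.amplitude * gain * carrier
            # apply per-block condition and day factors
            factor = np.ones(n)
            for ib, b in enumerate(blocks):
                i0, i1 = int(round(b.start * fs)), int(round(b.end * fs))
                f = day_factor[b.day] * _condition_factor(
                    spec, grp, peak.band, b
                )
                factor[i0:i1] = f
            comp = comp * factor
            x = x + comp
            powers = {}
            for ib, b in enumerate(blocks):
                i0, i1 = int(round(b.start * fs)), int(round(b.end * fs))
                powers[ib] = float(np.var(comp[i0:i1]))
            comp_block_power[ip] = powers
            comp_fractions.append(fractions)

        channels[ch] = x

        # realised per-block band powers -> true relative reductions
        for ib, b in enumerate(blocks):
            if b.task != "rest":
                continue
            i0, i1 = int(round(b.start * fs)), int(round(b.end * fs))
            g2 = float(np.mean(gain[i0:i1] ** 2))
            gain_rows.append(
                {"channel": ch, "group": grp, "block": ib, "day": b.day,
                 "condition": b.condition, "mean_sq_gain": g2}
            )
            for band_name in ("beta", "low_beta", "high_beta", "tremor"):
                band = BANDS[band_name]
                p_band = bg_band_power(band.low, band.high)
                p_total = bg_band_power(ANALYSIS.low, ANALYSIS.high)
                for ip in comp_block_power:
                    p = comp_block_power[ip][ib]
                    p_band += p * comp_fractions[ip][band_name]
                    p_total += p * comp_fractions[ip]["analysis"]
                band_rows.append(
                    {"channel": ch, "band": band_name, "day": b.day,
                     "condition": b.condition, "block": ib,
                     "band_power": p_band, "total_power": p_total,
                     "norm_band_power": p_band / p_total}
                )

    band_df = pd.DataFrame(band_rows)
    # per (channel, band, day): 100 * (sham - active) / sham on normalised power
    recs = []
    for (ch, band, day), g in band_df.groupby(["channel", "band", "day"]):
        sham = g[g.condition == "sham"].norm_band_power.mean()
        active = g[g.condition == "active"].norm_band_power.mean()
        recs.append(
            {"channel": ch, "band": band, "day": day,
             "true_rel_reduction_pct": 100.0 * (sham - active) / sham}
        )
    truth = band_df.merge(pd.DataFrame(recs), on=["channel", "band", "day"])

    # sync pulses shared by both streams; EEG clock shifted
    rng_sync = child_rng(spec.seed, "sync")
    pulse_times = np.sort(rng_sync.uniform(0.5, 4.5, size=n_sync_pulses))
    sync = {
        "lfp": pulse_times,
        "eeg": pulse_times + clock_offset_s,
    }

    session = RecordingSession(
        channels=channels, rates=rates, sync_events=sync, blocks=blocks
    )
    gt = GroundTruth(band_table=truth, gain_table=pd.DataFrame(gain_rows))
    return session, gt
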