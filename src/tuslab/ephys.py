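"""Spectral analysis of sham/active recording sessions.

The chain mirrors a standard deep-brain-recording workflow: EEG is
down-sampled to the 250 Hz LFP rate, all channels are zero-phase
band-pass filtered 4-45 Hz, detrended and DC-removed; resting spectra
are Welch estimates (Hann 1 s window, 600 ms overlap, 1 Hz bins)
normalised by total 4-45 Hz power; per-day active-minus-sham band-power
contrasts are then differenced across stimulation sites (GPi day minus
Ventricle day), which cancels day-level baseline drift.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Optional, Tuple

import numpy as np
import pandas as pd
from scipy import signal as sps

from .bands import BANDS, Band
from .errors import ValidationError
from .signals import (
    DAYS,
    EEG_CHANNELS,
    GROUP_OF_CHANNEL,
    LFP_CHANNELS,
    LFP_RATE,
    RecordingSession,
)


@dataclass(frozen=True)
class PreprocessConfig:
    bandpass: Tuple[float, float] = (4.0, 45.0)
    filter_order: int = 10  # Butterworth; zero-phase (applied twice)
    target_rate: float = 250.0

    def __post_init__(self) -> None:
        low, high = self.bandpass
        if not (0 < low < high < self.target_rate / 2):
            raise ValidationError(
                "bandpass must satisfy 0 < low < high < target_rate/2"
            )


@dataclass(frozen=True)
class WelchConfig:
    window_s: float = 1.0
    overlap_s: float = 0.6
    range_hz: Tuple[float, float] = (4.0, 45.0)
    normalise: bool = True

    def __post_init__(self) -> None:
        if not (0 <= self.overlap_s < self.window_s):
            raise ValidationError("overlap must satisfy 0 <= overlap < window")


@dataclass(frozen=True)
class PSD:
    frequencies: np.ndarray
    power: np.ndarray
    normalised: bool
    channel: Optional[str] = None
    block: Optional[str] = None

    def __post_init__(self) -> None:
        if np.any(self.power < 0):
            raise ValidationError("PSD must be non-negative")


@dataclass
class ContrastResult:
    """Sham-normalised band-power contrasts.

    ``per_day``: one row per (channel, band, day) with sham/active
    normalised band powers, their delta, and the relative percent change.
    ``site``: per (channel, band), the GPi-day minus Ventricle-day delta
    and relative percent difference.
    """

    per_day: pd.DataFrame
    site: pd.DataFrame


def preprocess(
    raw: np.ndarray, rate: float, config: PreprocessConfig = PreprocessConfig()
) -> np.ndarray:
    """Resample to the target rate, band-pass (zero-phase), detrend, de-mean."""
    x = np.asarray(raw, float)
    if rate < 2 * config.bandpass[1]:
        raise ValidationError("sampling rate below twice the band-pass edge")
    if rate != config.target_rate:
        frac = Fraction(config.target_rate / rate).limit_denominator(10000)
        x = sps.resample_poly(x, frac.numerator, frac.denominator)
    from .filters import analysis_bandpass_sos

    sos = analysis_bandpass_sos(
        config.target_rate, config.bandpass, config.filter_order
    )
    padlen = 3 * (2 * sos.shape[0] + 1)
    if x.size <= 3 * padlen:
        raise ValidationError(
            f"signal too short for filter transients (need > {3 * padlen} samples)"
        )
    x = sps.detrend(x, type="linear")
    x = x - x.mean()
    return sps.sosfiltfilt(sos, x)


def align_streams(
    lfp_events: np.ndarray,
    eeg_events: np.ndarray,
    rate: float = LFP_RATE,
    max_lag_s: float = 10.0,
) -> int:
    """Integer-sample offset (at the LFP rate) between two sync-pulse trains.

    The pulse times are binarised into sample trains and cross-correlated;
    the returned offset is the shift of the EEG train relative to the LFP
    train that maximises overlap. Raises on empty trains and on ambiguous
    (tied) maxima, reporting both candidates.
    """
    lfp_events = np.asarray(lfp_events, float)
    eeg_events = np.asarray(eeg_events, float)
    if lfp_events.size < 3 or eeg_events.size < 3:
        raise ValidationError("need at least 3 sync pulses in each stream")
    max_lag = int(round(max_lag_s * rate))
    t_max = max(lfp_events.max(), eeg_events.max()) + max_lag_s + 1.0
    n = int(round(t_max * rate)) + 1
    a = np.zeros(n)
    b = np.zeros(n)
    a[np.round(lfp_events * rate).astype(int)] = 1.0
    b[np.round(eeg_events * rate).astype(int)] = 1.0
    lags = np.arange(-max_lag, max_lag + 1)
    xc = np.array([np.dot(a, np.roll(b, -lag)) for lag in lags])
    best = xc.max()
    if best == 0:
        raise ValidationError("sync trains do not overlap within the lag window")
    winners = lags[xc == best]
    if winners.size > 1:
        raise ValidationError(
            f"ambiguous alignment: candidate offsets {winners.tolist()}"
        )
    return int(winners[0])


def welch_psd(
    x: np.ndarray,
    rate: float = LFP_RATE,
    config: WelchConfig = WelchConfig(),
    channel: Optional[str] = None,
    block: Optional[str] = None,
) -> PSD:
    """Hann-windowed overlapped Welch PSD, optionally broadband-normalised.

    A 1 s window yields 1 Hz bins; normalisation divides by the summed
    power over the 4-45 Hz analysis range so normalised values sum to 1
    there (making the spectrum invariant to global amplitude rescaling).
    """
    nperseg = int(round(config.window_s * rate))
    noverlap = int(round(config.overlap_s * rate))
    if x.size < 2 * nperseg:
        raise ValidationError("signal shorter than two Welch windows")
    freqs, pxx = sps.welch(
        x, fs=rate, window="hann", nperseg=nperseg, noverlap=noverlap
    )
    lo, hi = config.range_hz
    sel = (freqs >= lo) & (freqs <= hi)
    freqs, pxx = freqs[sel], pxx[sel]
    if config.normalise:
        total = pxx.sum()
        if total <= 0:
            raise ValidationError("zero total power; cannot normalise")
        pxx = pxx / total
    return PSD(
        frequencies=freqs, power=pxx, normalised=config.normalise,
        channel=channel, block=block,
    )


def band_power(psd: PSD, band: Band | str) -> float:
    """Sum of PSD bins whose centre frequency lies in the band (inclusive)."""
    if isinstance(band, str):
        band = BANDS[band]
    sel = (psd.frequencies >= band.low) & (psd.frequencies <= band.high)
    if not sel.any():
        raise ValidationError(f"band {band.name} empty on this frequency grid")
    return float(psd.power[sel].sum())


_CONTRAST_BANDS = ("beta", "low_beta", "high_beta")


def block_contrast(
    session: RecordingSession,
    preprocess_config: PreprocessConfig = PreprocessConfig(),
    welch_config: WelchConfig = WelchConfig(),
    bands: Tuple[str, ...] = _CONTRAST_BANDS,
) -> ContrastResult:
    """Sham-normalised, site-contrasted band-power changes for a session.

    Per day and channel: ``delta = bp(active) - bp(sham)`` on normalised
    PSDs and ``rel_pct = 100 * (sham - active) / sham``; the site contrast
    is the GPi-day value minus the Ventricle-day value.
    """
    rows = []
    for day in DAYS:
        try:
            sham = session.rest_block(day, "sham")
            active = session.rest_block(day, "active")
        except ValidationError as e:
            raise ValidationError(f"missing rest block: {e}") from e
        for ch in LFP_CHANNELS + EEG_CHANNELS:
            rate = session.rates[ch]
            bps = {}
            for cond, block in (("sham", sham), ("active", active)):
                x = preprocess(session.block_samples(ch, block), rate,
                               preprocess_config)
                psd = welch_psd(x, preprocess_config.target_rate, welch_config,
                                channel=ch, block=f"{day}:{cond}")
                bps[cond] = {b: band_power(psd, b) for b in bands}
            for b in bands:
                s, a = bps["sham"][b], bps["active"][b]
                if s <= 0:
                    raise ValidationError(
                        f"zero sham band power for {ch}/{b} on {day}"
                    )
                rows.append(
                    {"channel": ch, "group": GROUP_OF_CHANNEL[ch], "band": b,
                     "day": day, "sham_bp": s, "active_bp": a,
                     "delta": a - s, "rel_pct": 100.0 * (s - a) / s}
                )
    per_day = pd.DataFrame(rows)
    site_rows = []
    for (ch, b), g in per_day.groupby(["channel", "band"]):
        gpi = g[g.day == "GPi_day"].iloc[0]
        vent = g[g.day == "Ventricle_day"].iloc[0]
        site_rows.append(
            {"channel": ch, "group": GROUP_OF_CHANNEL[ch], "band": b,
             "delta_site": gpi.delta - vent.delta,
             "rel_pct_site": gpi.rel_pct - vent.rel_pct}
        )
    return ContrastResult(per_day=per_day, site=pd.DataFrame(site_rows))


def msc_coherence(
    x: np.ndarray,
    y: np.ndarray,
    rate: float = LFP_RATE,
    config: WelchConfig = WelchConfig(),
) -> PSD:
    """Magnitude-squared coherence on the analysis frequency grid."""
    if x.size != y.size:
        raise ValidationError("coherence inputs must have equal length")
    nperseg = int(round(config.window_s * rate))
    noverlap = int(round(config.overlap_s * rate))
    freqs, coh = sps.coherence(
        x, y, fs=rate, window="hann", nperseg=nperseg, noverlap=noverlap
    )
    lo, hi = config.range_hz
    sel = (freqs >= lo) & (freqs <= hi)
    coh = np.clip(coh[sel], 0.0, 1.0)
    return PSD(frequencies=freqs[sel], power=coh, normalised=False)


def segment_beta_power(
    session: RecordingSession,
    channel: str,
    segment_s: float = 15.0,
    band: str = "beta",
    preprocess_config: PreprocessConfig = PreprocessConfig(),
) -> np.ndarray:
    """Normalised beta power per consecutive segment of the rest blocks.

    Used to probe shared gain modulation between subcortical and cortical
    channels: segment-wise power co-fluctuates when the generator couples
    their gain processes.
    """
    rate = session.rates[channel]
    powers = []
    # raw (unnormalised) power: broadband normalisation would divide out
    # part of the very gain co-fluctuation this probe measures
    wc = WelchConfig(normalise=False)
    for day in DAYS:
        for cond in ("sham", "active"):
            block = session.rest_block(day, cond)
            x = preprocess(session.block_samples(channel, block), rate,
                           preprocess_config)
            seg = int(round(segment_s * preprocess_config.target_rate))
            for i0 in range(0, x.size - seg + 1, seg):
                psd = welch_psd(x[i0 : i0 + seg], preprocess_config.target_rate, wc)
                powers.append(band_power(psd, band))
    return np.asarray(powers)


def coupling_r2(
    session: RecordingSession,
    side: str = "left",
    segment_s: float = 15.0,
) -> float:
    """R^2 between segment-wise STN and M1 beta power on one side."""
    stn_ch = "Left_0-2" if side == "left" else "Right_0-2"
    m1_ch = "C3Cz" if side == "left" else "C4Cz"
    p_stn = segment_beta_power(session, stn_ch, segment_s)
    p_m1 = segment_beta_power(session, m1_ch, segment_s)
    n = min(p_stn.size, p_m1.size)
    r = np.corrcoef(p_stn[:n], p_m1[:n])[0, 1]
    return float(r**2)
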