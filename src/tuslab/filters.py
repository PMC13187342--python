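"""The standard zero-phase analysis band-pass, shared by the pipeline and
the generator's ground-truth bookkeeping.

A Butterworth band-pass at 4-45 Hz applied forward-backward (zero phase)
is the package-wide preprocessing convention. Because the two-pass
response is exactly 1/4 power at the band edges, any quantity summed over
the 4-45 Hz analysis grid (total-power normalisers in particular) depends
on this response; the generator therefore books its planted band powers
through the same magnitude weighting.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy import signal as sps

DEFAULT_BAND = (4.0, 45.0)
DEFAULT_ORDER = 10
DEFAULT_RATE = 250.0


@lru_cache(maxsize=64)
def _cached_sos(fs: float, low: float, high: float, order: int) -> np.ndarray:
    return sps.butter(order, (low, high), btype="bandpass", fs=fs, output="sos")


def analysis_bandpass_sos(
    fs: float = DEFAULT_RATE,
    band: tuple[float, float] = DEFAULT_BAND,
    order: int = DEFAULT_ORDER,
) -> np.ndarray:
    return _cached_sos(float(fs), float(band[0]), float(band[1]), int(order))


def two_pass_power_response(
    freqs: np.ndarray,
    fs: float = DEFAULT_RATE,
    band: tuple[float, float] = DEFAULT_BAND,
    order: int = DEFAULT_ORDER,
) -> np.ndarray:
    """|H(f)|^4: power response of the forward-backward band-pass."""
    sos = analysis_bandpass_sos(fs, band, order)
    freqs = np.asarray(freqs, float)
    # evaluate only below Nyquist of the filter design rate
    w = np.clip(freqs, 0.0, 0.499 * fs)
    _, h = sps.sosfreqz(sos, worN=w, fs=fs)
    resp = np.abs(h) ** 4
    resp[freqs >= 0.5 * fs] = 0.0
    return resp
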