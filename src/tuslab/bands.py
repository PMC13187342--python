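"""Canonical frequency bands of the analysis.

Beta (13-30 Hz) is the Parkinsonian biomarker band, split into low
(13-20 Hz) and high (21-30 Hz) sub-bands; all spectral analysis is
restricted to the 4-45 Hz filtered range; 4-6 Hz is the optional tremor
band. Band edges are inclusive on both sides, with the 20 Hz bin assigned
to low beta and the 21 Hz bin to high beta.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Tuple

from .errors import ValidationError


@dataclass(frozen=True)
class Band:
    name: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise ValidationError("band low must be < high")

    def contains(self, frequency: float) -> bool:
        return self.low <= frequency <= self.high


ANALYSIS = Band("analysis", 4.0, 45.0)
BETA = Band("beta", 13.0, 30.0)
LOW_BETA = Band("low_beta", 13.0, 20.0)
HIGH_BETA = Band("high_beta", 21.0, 30.0)
TREMOR = Band("tremor", 4.0, 6.0)

BANDS: Dict[str, Band] = {
    b.name: b for b in (ANALYSIS, BETA, LOW_BETA, HIGH_BETA, TREMOR)
}


def classify_peak(centre_hz: float) -> str:
    """Band name of an oscillatory peak by its centre frequency."""
    for band in (LOW_BETA, HIGH_BETA, TREMOR):
        if band.contains(centre_hz):
            return band.name
    return "other"
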