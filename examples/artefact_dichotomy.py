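"""Why a 130 Hz pulse repetition frequency cannot pollute the beta band.

Simulates direct sonication of an electrode through the recording chain
(100 Hz hardware low-pass, 250 Hz sampling) for the clinical 130 Hz PRF
and for a 5 Hz positive-control PRF, and compares in-band beta power.
"""

import numpy as np

from tuslab import (
    CouplingModel,
    PulseProtocol,
    THETA_CONTROL_PROTOCOL,
    artefact_beta_change,
    artefact_timeseries,
    harmonic_series,
)
from tuslab.artefact import inband_artefact_power

print("Rectangular-train harmonics (relative amplitude):")
for tau, prf, label in ((20e-3, 5.0, "5 Hz PRF, 20 ms pulses"),
                        (90e-6, 130.0, "130 Hz PRF, 90 us pulses")):
    hs = harmonic_series(tau, prf, 4)
    rows = ", ".join(f"{f:.0f} Hz: {m:.4f}" for f, m in hs)
    print(f"  {label:<26} {rows}")
print()

p5 = inband_artefact_power(THETA_CONTROL_PROTOCOL, 600e3)
p130 = inband_artefact_power(PulseProtocol(), 600e3)
print(f"noiseless in-band (13-30 Hz) artefact power, 5 Hz PRF  : {p5:.3e}")
print(f"noiseless in-band (13-30 Hz) artefact power, 130 Hz PRF: {p130:.3e}")
print(f"dichotomy ratio: {p5 / p130:.0f}x")
print()

for label, proto in (("130 Hz", PulseProtocol()), ("5 Hz", THETA_CONTROL_PROTOCOL)):
    ratios = []
    for pressure in (200e3, 400e3, 600e3):
        res = artefact_timeseries(proto, pressure, noise_sd=0.1, seed=1)
        ratios.append(artefact_beta_change(res.recording, res.baseline))
    print(f"beta power vs baseline, {label:>6} PRF at 200/400/600 kPa: "
          + " / ".join(f"{r:.2f}" for r in ratios))
print()
print("The 5 Hz train places harmonics at 15-30 Hz inside beta and its")
print("artefact grows with pressure; the 130 Hz fundamental sits above")
print("the 100 Hz hardware cutoff, so beta power stays at baseline.")
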