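"""Round-trip a session to disk, align its streams, and compute coherence.

Writes a generated session to the documented JSON-header + binary-payload
format, reads it back losslessly, recovers the LFP/EEG clock offset from
the shared TENS-style sync pulses, and computes magnitude-squared
coherence between a subthalamic and a motor-cortex channel.
"""

import tempfile
from pathlib import Path

import numpy as np

from tuslab import (
    ParticipantSpec,
    align_streams,
    default_schedule,
    generate_session,
    msc_coherence,
    preprocess,
    read_session,
    write_session,
)

spec = ParticipantSpec(seed=2, eeg_rate=512.0)
session, _ = generate_session(
    spec, default_schedule(block_duration=60.0), clock_offset_s=0.5
)

with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "session"
    write_session(session, path)
    back = read_session(path)
size_check = all(
    np.array_equal(back.channels[ch], session.channels[ch])
    for ch in session.channels
)
print(f"lossless round trip      : {size_check}")

offset = align_streams(back.sync_events["lfp"], back.sync_events["eeg"])
print(f"recovered clock offset   : {offset} samples at 250 Hz "
      f"({offset / 250.0:.3f} s; 0.500 s was planted)")

block = back.rest_block("GPi_day", "sham")
stn = preprocess(back.block_samples("Left_0-2", block), 250.0)
m1 = preprocess(back.block_samples("C3Cz", block), 512.0)
coh = msc_coherence(stn, m1)
beta = (coh.frequencies >= 13) & (coh.frequencies <= 30)
print(f"mean STN-M1 coherence    : beta {coh.power[beta].mean():.3f}, "
      f"full band {coh.power.mean():.3f}")
print()
print("The generator couples STN and M1 through a shared slow power")
print("modulation, not through phase, so coherence stays modest even in")
print("the beta band; the sync pulses carry the cross-device clock.")
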