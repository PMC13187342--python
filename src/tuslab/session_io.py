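"""Versioned on-disk session format: JSON header + raw binary payload.

``<stem>.json`` documents rates, channel order, sample counts, sync
events and the block schedule; ``<stem>.bin`` holds the channel samples
as little-endian float64, concatenated in header order. The format is a
deliberately simple, documented stand-in: faithful parsing of any
proprietary device export is explicitly not attempted.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Tuple

import numpy as np

from .errors import ValidationError
from .signals import Block, EEG_CHANNELS, LFP_CHANNELS, RecordingSession

FORMAT_VERSION = 1
REQUIRED_CHANNELS = tuple(LFP_CHANNELS) + tuple(EEG_CHANNELS)


def _paths(path: str | Path) -> Tuple[Path, Path]:
    stem = Path(path)
    if stem.suffix == ".json":
        stem = stem.with_suffix("")
    return stem.with_suffix(".json"), stem.with_suffix(".bin")


def write_session(session: RecordingSession, path: str | Path) -> None:
    """Write a session losslessly as header + payload file pair."""
    header_path, payload_path = _paths(path)
    order = list(session.channels)
    header = {
        "version": FORMAT_VERSION,
        "dtype": "<f8",
        "channels": [
            {
                "name": ch,
                "rate_hz": session.rates[ch],
                "n_samples": int(session.channels[ch].size),
            }
            for ch in order
        ],
        "sync_events": {k: list(map(float, v)) for k, v in session.sync_events.items()},
        "blocks": [asdict(b) for b in session.blocks],
    }
    with open(header_path, "w") as fh:
        json.dump(header, fh, indent=1)
    payload = np.concatenate([np.asarray(session.channels[ch], "<f8") for ch in order])
    payload.tofile(payload_path)


def read_session(path: str | Path) -> RecordingSession:
    """Read a session pair back; validates schema, channels and payload length."""
    header_path, payload_path = _paths(path)
    try:
        with open(header_path) as fh:
            header = json.load(fh)
    except json.JSONDecodeError as e:
        raise ValidationError(f"malformed session header: {e}") from e
    for key in ("version", "dtype", "channels", "sync_events", "blocks"):
        if key not in header:
            raise ValidationError(f"session header missing field '{key}'")
    if header["version"] != FORMAT_VERSION:
        raise ValidationError(
            f"unsupported session format version {header['version']}"
        )
    names = [c["name"] for c in header["channels"]]
    missing = set(REQUIRED_CHANNELS) - set(names)
    if missing:
        raise ValidationError(f"session file missing channels: {sorted(missing)}")

    payload = np.fromfile(payload_path, dtype=header["dtype"])
    expected = sum(int(c["n_samples"]) for c in header["channels"])
    if payload.size != expected:
        raise ValidationError(
            f"payload length mismatch: header declares {expected} samples, "
            f"file holds {payload.size}"
        )
    channels = {}
    rates = {}
    offset = 0
    for c in header["channels"]:
        n = int(c["n_samples"])
        channels[c["name"]] = payload[offset : offset + n].copy()
        rates[c["name"]] = float(c["rate_hz"])
        offset += n
    sync = {k: np.asarray(v, float) for k, v in header["sync_events"].items()}
    blocks = [Block(**b) for b in header["blocks"]]
    return RecordingSession(
        channels=channels, rates=rates, sync_events=sync, blocks=blocks
    )
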