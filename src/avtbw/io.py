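"""Writers for the package's external formats: envelope CSVs, mono WAV
renderings of the auditory stream, and JSON run manifests."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .envelopes import Envelope

__all__ = ["write_envelope_csv", "write_wav", "write_manifest"]


def write_envelope_csv(env: Envelope, path: str | Path) -> Path:
    """Envelope samples as a two-column CSV (time_s, amplitude)."""
    path = Path(path)
    pd.DataFrame({"time_s": env.times, "amplitude": env.samples}).to_csv(path, index=False)
    return path


def write_wav(
    env: Envelope,
    path: str | Path,
    carrier_hz: float = 500.0,
    audio_rate: int = 44100,
) -> Path:
    """Render the envelope onto a pure-tone carrier as 16-bit PCM mono WAV."""
    path = Path(path)
    n = int(round(env.duration * audio_rate))
    t = np.arange(n) / audio_rate
    # resample the envelope onto the audio clock by linear interpolation
    amp = np.interp(t, env.times, env.samples)
    wave = amp * np.sin(2.0 * np.pi * carrier_hz * t)
    pcm = np.int16(np.clip(wave, -1.0, 1.0) * 32767)
    wavfile.write(path, audio_rate, pcm)
    return path


def write_manifest(path: str | Path, payload: dict[str, Any]) -> Path:
    """JSON sidecar with generator parameters, seeds, and versions."""
    path = Path(path)
    path.write_text(json.dumps(payload, indent=2, sort_keys=True, default=str) + "\n")
    return path
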