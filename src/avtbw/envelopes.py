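"""Amplitude-modulation envelopes for pulsing audio-visual streams.

A stream is a slow modulation profile in [0, 1]: for the auditory channel it
scales the amplitude of a pure-tone carrier, for the visual channel the size
of a blob. Rhythmic streams follow a raised cosine at 1-3 Hz; speech-like
streams follow a quasi-rhythmic pulse train whose dominant frequency sits
near 3 Hz, mimicking the syllabic amplitude envelope of natural speech.

SOA (stimulus onset asynchrony) conventions: negative SOAs mean the auditory
stream leads, positive SOAs mean the visual stream leads.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import signal as sps

from .errors import DegenerateInputError, InvalidArgumentError, InvalidDesignError

__all__ = [
    "Envelope",
    "SpectralProfile",
    "AVPair",
    "make_sinusoidal_envelope",
    "make_stream_spec",
    "extract_envelope",
    "fft_dominant_frequency",
    "make_quasi_rhythmic_envelope",
    "select_speech_like",
    "render_av_pair",
    "count_pulses",
]

DEFAULT_SAMPLE_RATE = 1000.0
DEFAULT_FFT_BAND = (0.5, 10.0)
DEFAULT_MAX_SOA_MS = 500.0


@dataclass(frozen=True)
class Envelope:
    """A sampled amplitude-modulation profile in [0, 1]."""

    samples: np.ndarray
    sample_rate: float
    label: str = ""

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if self.sample_rate <= 0:
            raise InvalidArgumentError("sample_rate must be positive")
        if samples.ndim != 1 or samples.size == 0:
            raise InvalidArgumentError("samples must be a non-empty 1-D array")

    @property
    def duration(self) -> float:
        """Duration in seconds (sample count / sample rate)."""
        return self.samples.size / self.sample_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.sample_rate


@dataclass(frozen=True)
class SpectralProfile:
    """Power spectrum of a mean-removed envelope plus its in-band peak.

    ``dominant_frequency`` is NaN when the spectrum is degenerate (no power
    above numerical zero inside the search band, e.g. a constant envelope).
    """

    frequencies: np.ndarray
    power: np.ndarray
    dominant_frequency: float
    band: tuple[float, float]
    degenerate: bool = False


@dataclass(frozen=True)
class AVPair:
    """An SOA-shifted audio/visual envelope pair.

    Negative ``soa_ms``: auditory leads (visual onset delayed by |soa|);
    positive: visual leads. The leading track is zero-padded at its tail and
    the lagging track at its head so both have equal length.
    """

    audio_env: Envelope
    visual_env: Envelope
    soa_ms: float

    def __post_init__(self) -> None:
        if self.audio_env.sample_rate != self.visual_env.sample_rate:
            raise InvalidArgumentError("audio and visual envelopes must share sample_rate")
        if self.audio_env.samples.size != self.visual_env.samples.size:
            raise InvalidArgumentError("audio and visual tracks must have equal length")


def make_sinusoidal_envelope(
    freq_hz: float,
    duration_s: float,
    sample_rate: float = DEFAULT_SAMPLE_RATE,
    label: str | None = None,
) -> Envelope:
    """Raised-cosine modulation e(t) = (1 - cos(2*pi*f*t)) / 2.

    The stream starts and ends at amplitude 0 and contains ``freq_hz *
    duration_s`` pulses (local maxima), e.g. 3/6/9 pulses for 1/2/3 Hz
    streams of 3 s.
    """
    if freq_hz <= 0 or duration_s <= 0 or sample_rate <= 0:
        raise InvalidArgumentError("freq_hz, duration_s and sample_rate must be positive")
    if sample_rate < 20 * freq_hz:
        raise InvalidArgumentError(
            f"sample_rate {sample_rate} Hz too low for {freq_hz} Hz modulation "
            f"(need >= {20 * freq_hz})"
        )
    n = int(round(duration_s * sample_rate))
    t = np.arange(n) / sample_rate
    samples = (1.0 - np.cos(2.0 * np.pi * freq_hz * t)) / 2.0
    return Envelope(samples, sample_rate, label or f"rhythmic-{freq_hz:g}Hz")


def make_stream_spec(
    mode: str, freq_hz: float, value: float
) -> tuple[float, int]:
    """Resolve a stream design to (duration_s, n_pulses).

    ``fixed_duration`` keeps the stream length constant so the pulse count
    scales with frequency; ``fixed_pulses`` keeps the pulse count constant so
    the duration scales as value / freq_hz (3 pulses -> 3 / 1.5 / 1 s at
    1 / 2 / 3 Hz).
    """
    if freq_hz <= 0 or value <= 0:
        raise InvalidArgumentError("freq_hz and value must be positive")
    if mode == "fixed_duration":
        duration = float(value)
        pulses = freq_hz * duration
        if abs(pulses - round(pulses)) > 1e-9:
            raise InvalidDesignError(
                f"duration {duration} s at {freq_hz} Hz implies a non-integer "
                f"pulse count ({pulses})"
            )
        return duration, int(round(pulses))
    if mode == "fixed_pulses":
        if abs(value - round(value)) > 1e-9 or round(value) < 1:
            raise InvalidDesignError(f"pulse count must be a positive integer, got {value}")
        n_pulses = int(round(value))
        return n_pulses / freq_hz, n_pulses
    raise InvalidArgumentError(f"unknown stream mode {mode!r}")


def extract_envelope(
    waveform: Sequence[float] | np.ndarray,
    sample_rate: float,
    smoothing_cutoff: float = 10.0,
    label: str = "extracted",
) -> Envelope:
    """Low-frequency amplitude envelope of a mono waveform, rescaled to [0, 1].

    Full-wave rectification followed by a zero-phase 4th-order Butterworth
    low-pass at ``smoothing_cutoff`` (default 10 Hz, comfortably above the
    2-7 Hz syllabic band).
    """
    x = np.asarray(waveform, dtype=float)
    if x.ndim != 1 or x.size == 0:
        raise InvalidArgumentError("waveform must be a non-empty 1-D array")
    if not 0 < smoothing_cutoff < sample_rate / 2:
        raise InvalidArgumentError("smoothing_cutoff must lie in (0, sample_rate/2)")
    peak = np.max(np.abs(x))
    if peak == 0:
        raise DegenerateInputError("waveform is silent (all zeros)")
    rectified = np.abs(x)
    sos = sps.butter(4, smoothing_cutoff, btype="low", fs=sample_rate, output="sos")
    env = sps.sosfiltfilt(sos, rectified)
    env = np.clip(env, 0.0, None)
    top = env.max()
    if top <= 0:
        raise DegenerateInputError("envelope vanished after smoothing")
    return Envelope(env / top, sample_rate, label)


def fft_dominant_frequency(
    env: Envelope,
    band: tuple[float, float] = DEFAULT_FFT_BAND,
) -> SpectralProfile:
    """Power spectrum of the mean-removed envelope and its in-band peak.

    The frequency resolution is 1/duration (no zero padding). The argmax is
    taken inside ``band``; near-exact power ties break toward the lower
    frequency. A spectrum with no in-band power above numerical zero is
    flagged degenerate and gets a NaN dominant frequency.
    """
    lo, hi = band
    nyquist = env.sample_rate / 2
    if not (0 < lo < hi):
        raise InvalidArgumentError("band must satisfy 0 < low < high")
    # clip to what this envelope can resolve: at least two cycles per
    # component and below Nyquist
    lo = max(lo, 2.0 / env.duration)
    hi = min(hi, nyquist)
    if lo > hi:
        raise InvalidArgumentError(
            f"band {band} is empty after intersection with the resolvable range "
            f"[{2.0 / env.duration:.3f}, {nyquist:.1f}] Hz"
        )
    x = env.samples - env.samples.mean()
    spectrum = np.fft.rfft(x)
    power = np.abs(spectrum) ** 2
    freqs = np.fft.rfftfreq(x.size, d=1.0 / env.sample_rate)
    mask = (freqs >= lo) & (freqs <= hi)
    if not mask.any():
        raise InvalidArgumentError("band is empty after intersection with the resolvable range")

    in_band = power[mask]
    in_freqs = freqs[mask]
    peak = in_band.max()
    # numerical-zero gate relative to the signal's own scale
    scale = max(float(np.sum(power)), 1.0)
    if peak <= scale * 1e-18:
        return SpectralProfile(freqs, power, float("nan"), (lo, hi), degenerate=True)
    ties = in_band >= peak * (1.0 - 1e-9)
    dominant = float(in_freqs[ties][0])  # freqs ascending -> lowest tied bin
    return SpectralProfile(freqs, power, dominant, (lo, hi))


def _raised_cosine_kernel(width_s: float, sample_rate: float) -> np.ndarray:
    """Unit-peak raised-cosine pulse of total width ``width_s``."""
    half = int(round(width_s * sample_rate / 2))
    t = np.arange(-half, half + 1) / sample_rate
    return (1.0 + np.cos(2.0 * np.pi * t / width_s)) / 2.0


def make_quasi_rhythmic_envelope(
    mean_freq: float,
    jitter_cv: float,
    amp_cv: float,
    duration_s: float,
    sample_rate: float = DEFAULT_SAMPLE_RATE,
    seed: int = 0,
    label: str | None = None,
) -> Envelope:
    """Jittered pulse train emulating a speech-like amplitude envelope.

    Pulse centres are spaced around 1/mean_freq with Gaussian jitter of
    coefficient of variation ``jitter_cv``; pulse amplitudes vary with
    ``amp_cv``. Pulses are raised-cosine kernels of width 1/(2*mean_freq).
    With both CVs at zero this collapses bit-exactly to the regular train
    under the same kernel. Deterministic for a fixed seed.
    """
    if mean_freq <= 0 or duration_s <= 0 or sample_rate <= 0:
        raise InvalidArgumentError("mean_freq, duration_s and sample_rate must be positive")
    if not (0 <= jitter_cv <= 0.5) or not (0 <= amp_cv <= 0.5):
        raise InvalidArgumentError("jitter_cv and amp_cv must lie in [0, 0.5]")

    rng = np.random.default_rng(seed)
    period = 1.0 / mean_freq
    half_offset = period / 2.0

    centres: list[float] = []
    amps: list[float] = []
    c = half_offset
    while c <= duration_s - half_offset + 1e-12:
        centres.append(c)
        amps.append(max(0.1, 1.0 + amp_cv * rng.standard_normal()))
        # truncate intervals well away from zero so pulses never collide
        step = period * max(0.2, 1.0 + jitter_cv * rng.standard_normal())
        c += step

    n = int(round(duration_s * sample_rate))
    env = np.zeros(n)
    kernel = _raised_cosine_kernel(period / 2.0, sample_rate)
    half_k = kernel.size // 2
    for centre, amp in zip(centres, amps):
        idx = int(round(centre * sample_rate))
        lo = idx - half_k
        hi = idx + half_k + 1
        klo = max(0, -lo)
        khi = kernel.size - max(0, hi - n)
        env[max(0, lo):min(n, hi)] += amp * kernel[klo:khi]

    top = env.max()
    if top <= 0:
        raise InvalidArgumentError("parameters produced an empty pulse train")
    env = np.clip(env / top, 0.0, 1.0)
    return Envelope(env, sample_rate, label or f"quasi-{mean_freq:g}Hz-seed{seed}")


def select_speech_like(
    envelopes: Sequence[Envelope],
    target_freq: float = 3.0,
    tol: float = 0.5,
    band: tuple[float, float] = DEFAULT_FFT_BAND,
) -> list[Envelope]:
    """Keep envelopes whose dominant frequency is within ``tol`` of the target.

    Mirrors the stimulus-selection step in which only speech tokens with a
    clear spectral peak near 3 Hz qualify. Bounds are inclusive; input order
    is preserved; an empty input yields an empty output.
    """
    if tol < 0:
        raise InvalidArgumentError("tol must be non-negative")
    kept = []
    for env in envelopes:
        profile = fft_dominant_frequency(env, band)
        if profile.degenerate:
            continue
        if abs(profile.dominant_frequency - target_freq) <= tol:
            kept.append(env)
    return kept


def render_av_pair(
    env: Envelope,
    soa_ms: float,
    max_soa_ms: float = DEFAULT_MAX_SOA_MS,
) -> AVPair:
    """Assemble an SOA-shifted audio/visual pair from one modulation profile.

    Negative ``soa_ms`` delays the visual stream (auditory leads); positive
    delays the auditory stream. Padding is zero amplitude (silence / minimum
    size), so the pair lasts stream duration + |soa|/1000 seconds.
    """
    if abs(soa_ms) > max_soa_ms:
        raise InvalidArgumentError(f"|soa_ms| exceeds the configured maximum {max_soa_ms} ms")
    shift = int(round(abs(soa_ms) / 1000.0 * env.sample_rate))
    pad = np.zeros(shift)
    lead = np.concatenate([env.samples, pad])
    lag = np.concatenate([pad, env.samples])
    if soa_ms < 0:  # auditory leads
        audio, visual = lead, lag
    else:
        audio, visual = lag, lead
    return AVPair(
        Envelope(audio, env.sample_rate, f"{env.label}-audio"),
        Envelope(visual, env.sample_rate, f"{env.label}-visual"),
        float(soa_ms),
    )


def count_pulses(env: Envelope, min_height: float = 0.05) -> int:
    """Number of strict local maxima above ``min_height``.

    For a raised-cosine stream this equals freq_hz * duration_s exactly.
    """
    x = env.samples
    peaks, _ = sps.find_peaks(x, height=min_height)
    return int(peaks.size)
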