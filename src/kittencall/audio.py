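"""Waveform container, call segments, and 16-bit PCM WAV I/O.

All audio in this package is mono. Samples are stored as float64 in [-1, 1];
files on disk are RIFF WAV, 16-bit PCM, 44.1 kHz by default (the recording
format of the study design this package emulates).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.io import wavfile

DEFAULT_SAMPLE_RATE = 44_100


@dataclass(frozen=True)
class Waveform:
    """Mono audio: float samples in [-1, 1] plus a sample rate in Hz."""

    samples: np.ndarray
    sample_rate: int = DEFAULT_SAMPLE_RATE

    def __post_init__(self) -> None:
        if self.sample_rate <= 0:
            raise ValueError(f"sample_rate must be positive, got {self.sample_rate}")
        samples = np.asarray(self.samples, dtype=np.float64)
        if samples.ndim != 1 or samples.size == 0:
            raise ValueError("samples must be a non-empty 1-D array")
        object.__setattr__(self, "samples", samples)

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sample_rate

    @property
    def duration_ms(self) -> float:
        return 1000.0 * self.duration_s


@dataclass(frozen=True)
class CallSegment:
    """A located call: half-open sample range [onset, offset) of a source waveform."""

    source: Waveform
    onset: int
    offset: int

    def __post_init__(self) -> None:
        n = self.source.samples.size
        if not (0 <= self.onset < self.offset <= n):
            raise ValueError(
                f"invalid segment bounds [{self.onset}, {self.offset}) for length {n}"
            )

    @property
    def sample_rate(self) -> int:
        return self.source.sample_rate

    @property
    def samples(self) -> np.ndarray:
        return self.source.samples[self.onset : self.offset]

    @property
    def n_samples(self) -> int:
        return self.offset - self.onset

    @property
    def duration_ms(self) -> float:
        return 1000.0 * self.n_samples / self.sample_rate

    @property
    def onset_s(self) -> float:
        return self.onset / self.sample_rate

    @property
    def offset_s(self) -> float:
        return self.offset / self.sample_rate

    def as_waveform(self) -> Waveform:
        return Waveform(self.samples.copy(), self.sample_rate)


def write_wav(path: str | Path, w: Waveform) -> None:
    """Write a waveform as mono 16-bit PCM. Samples are clipped to [-1, 1]."""
    x = np.clip(w.samples, -1.0, 1.0)
    pcm = np.round(x * 32767.0).astype(np.int16)
    wavfile.write(str(path), w.sample_rate, pcm)


def read_wav(path: str | Path) -> Waveform:
    """Read a mono WAV file (16/24/32-bit PCM or float) into float64 [-1, 1]."""
    rate, data = wavfile.read(str(path))
    if data.ndim > 1:
        raise ValueError(f"{path}: expected mono audio, got {data.shape[1]} channels")
    if data.dtype == np.int16:
        x = data / 32768.0
    elif data.dtype == np.int32:
        x = data / 2147483648.0
    elif data.dtype == np.uint8:
        x = (data.astype(np.float64) - 128.0) / 128.0
    else:  # float32/float64 already in [-1, 1]
        x = data.astype(np.float64)
    return Waveform(x, rate)
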