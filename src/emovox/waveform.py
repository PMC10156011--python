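"""Mono waveform container and basic amplitude operations.

Every stage of the pipeline — synthesis, transformation, F0 analysis —
passes audio around as a :class:`Waveform`: a float64 sample array plus a
sample rate. Stimuli are root-mean-square normalized so that loudness is
never an available cue; :func:`rms_normalize` is the canonical way to do
that.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.io import wavfile

__all__ = [
    "Waveform",
    "DegenerateSignalError",
    "rms_normalize",
    "reverse_waveform",
    "read_wav",
    "write_wav",
]


class DegenerateSignalError(ValueError):
    """Raised when an operation requires a non-silent signal."""


@dataclass(frozen=True)
class Waveform:
    """Sampled mono audio.

    Parameters
    ----------
    samples
        Real-valued samples, nominally in [-1, 1] full scale.
    sample_rate
        Sampling rate in Hz (positive integer).
    """

    samples: np.ndarray = field(repr=False)
    sample_rate: int

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        object.__setattr__(self, "samples", samples)
        if samples.ndim != 1:
            raise ValueError("Waveform requires a 1-D (mono) sample array")
        if samples.size == 0:
            raise ValueError("Waveform requires at least one sample")
        if not np.all(np.isfinite(samples)):
            raise ValueError("Waveform samples must all be finite")
        if int(self.sample_rate) <= 0:
            raise ValueError("sample_rate must be a positive integer")
        object.__setattr__(self, "sample_rate", int(self.sample_rate))

    @property
    def duration_s(self) -> float:
        """Duration in seconds."""
        return self.samples.size / self.sample_rate

    @property
    def n_samples(self) -> int:
        return self.samples.size

    def rms(self) -> float:
        """Root-mean-square amplitude."""
        return float(np.sqrt(np.mean(np.square(self.samples))))

    def times(self) -> np.ndarray:
        """Per-sample time stamps in seconds."""
        return np.arange(self.samples.size) / self.sample_rate


def rms_normalize(w: Waveform, target_rms: float = 0.05) -> Waveform:
    """Scale a waveform to a target RMS amplitude.

    The shape is preserved up to a scalar gain. An all-zero (silent) input
    has no defined gain and raises :class:`DegenerateSignalError`.
    """
    if target_rms <= 0:
        raise ValueError("target_rms must be positive")
    rms = w.rms()
    if rms == 0.0:
        raise DegenerateSignalError("cannot RMS-normalize an all-zero signal")
    return Waveform(w.samples * (target_rms / rms), w.sample_rate)


def reverse_waveform(w: Waveform) -> Waveform:
    """Play a recording backwards (exact sample-order reversal).

    Time reversal preserves RMS and sample count exactly; it destroys
    temporal structure (syllable order, inflections) while leaving the
    long-term spectrum untouched.
    """
    return Waveform(w.samples[::-1].copy(), w.sample_rate)


def read_wav(path) -> Waveform:
    """Read a mono RIFF/WAVE file (PCM16/24/32 or float) as float64 in [-1, 1]."""
    rate, data = wavfile.read(path)
    if data.ndim > 1:
        raise ValueError(f"{path}: expected mono audio, got {data.shape[1]} channels")
    if np.issubdtype(data.dtype, np.integer):
        scale = float(np.iinfo(data.dtype).max) + 1.0
        data = data.astype(np.float64) / scale
    else:
        data = data.astype(np.float64)
    return Waveform(data, int(rate))


def write_wav(path, w: Waveform, subtype: str = "float32") -> None:
    """Write a waveform as a mono RIFF/WAVE file.

    Parameters
    ----------
    subtype
        ``"float32"`` (default) or ``"pcm16"``.
    """
    if subtype == "float32":
        wavfile.write(path, w.sample_rate, w.samples.astype(np.float32))
    elif subtype == "pcm16":
        clipped = np.clip(w.samples, -1.0, 1.0 - 1.0 / 32768.0)
        wavfile.write(path, w.sample_rate, np.round(clipped * 32768.0).astype(np.int16))
    else:
        raise ValueError(f"unknown WAV subtype: {subtype!r}")
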