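"""Audio container, WAV I/O and frame-level intensity helpers."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.io import wavfile

__all__ = ["AudioSignal", "read_wav", "write_wav", "frame_rms_db",
           "DB_REFERENCE"]

#: amplitude reference for dB conversion; a full-scale signal sits near
#: 94 dB, mimicking a calibrated SPL scale so contour means stay positive
DB_REFERENCE = 2e-5


@dataclass
class AudioSignal:
    samples: np.ndarray  # float, amplitude in [-1, 1]
    rate: int

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.rate <= 0:
            raise ValueError("sample rate must be positive")
        if self.samples.ndim != 1:
            raise ValueError("mono audio expected")

    @property
    def duration(self) -> float:
        return self.samples.size / self.rate

    def slice(self, start_s: float, end_s: float) -> "AudioSignal":
        i0 = max(0, int(round(start_s * self.rate)))
        i1 = min(self.samples.size, int(round(end_s * self.rate)))
        return AudioSignal(self.samples[i0:i1], self.rate)


def read_wav(path) -> AudioSignal:
    rate, data = wavfile.read(path)
    data = np.asarray(data)
    if data.ndim > 1:
        data = data.mean(axis=1)
    if np.issubdtype(data.dtype, np.integer):
        data = data / float(np.iinfo(data.dtype).max)
    return AudioSignal(data.astype(np.float64), int(rate))


def write_wav(path, audio: AudioSignal) -> None:
    peak = np.max(np.abs(audio.samples)) if audio.samples.size else 0.0
    samples = audio.samples / peak if peak > 1.0 else audio.samples
    wavfile.write(path, audio.rate, (samples * 32767).astype(np.int16))


def frame_rms_db(audio: AudioSignal, frame_ms: float = 30.0,
                 hop_ms: float = 10.0) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame RMS level in dB (re DB_REFERENCE) at frame centers.

    Returns ``(times, levels)``; levels of all-zero frames are -inf.
    """
    n = audio.samples.size
    frame = max(1, int(round(frame_ms * audio.rate / 1000.0)))
    hop = max(1, int(round(hop_ms * audio.rate / 1000.0)))
    if n < frame:
        frame = n
    starts = np.arange(0, n - frame + 1, hop)
    if starts.size == 0:
        raise ValueError("audio shorter than one frame")
    sq = np.concatenate([[0.0], np.cumsum(audio.samples ** 2)])
    energy = (sq[starts + frame] - sq[starts]) / frame
    rms = np.sqrt(np.maximum(energy, 0.0))
    with np.errstate(divide="ignore"):
        levels = 20.0 * np.log10(rms / DB_REFERENCE)
    times = (starts + frame / 2.0) / audio.rate
    return times, levels
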