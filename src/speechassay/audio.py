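"""Waveform container and PCM WAV input/output.

All in-memory audio is float64 in [-1, 1]. Files are written as 16-bit PCM
mono; wider integer formats are accepted on read and converted (with a
warning) so that archived recordings at other bit depths remain usable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.io import wavfile

TASKS = ("passage", "phonation", "ddk")


@dataclass
class AudioSample:
    """One recording of one speech task.

    Parameters
    ----------
    samples : ndarray
        Amplitude sequence, values in [-1, 1].
    fs_hz : int
        Sampling rate in Hz.
    bit_depth : int
        Nominal quantization depth of the source (16 for study recordings).
    task : str
        One of ``passage``, ``phonation``, ``ddk``.
    """

    samples: np.ndarray
    fs_hz: int
    bit_depth: int = 16
    task: str = "phonation"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.fs_hz <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs_hz}")
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise ValueError("samples must be a non-empty 1-D sequence")
        peak = np.max(np.abs(self.samples))
        if peak > 1.0 + 1e-9:
            raise ValueError(f"samples exceed full scale (peak {peak:.4g})")
        if self.task not in TASKS:
            raise ValueError(f"unknown task {self.task!r}; expected one of {TASKS}")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs_hz

    def time_axis(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.fs_hz


def read_wav(path, task: str = "phonation") -> AudioSample:
    """Read a mono PCM WAV file into an :class:`AudioSample`.

    16-bit input maps to [-1, 1] by division with 32768. 24/32-bit integer
    and float input are converted with a warning; stereo input is rejected.
    """
    fs, data = wavfile.read(path)
    if data.ndim != 1:
        raise ValueError(f"{path}: expected mono WAV, got shape {data.shape}")
    if data.dtype == np.int16:
        x = data / 32768.0
        depth = 16
    elif data.dtype == np.int32:
        warnings.warn(f"{path}: >16-bit integer WAV converted to float")
        x = data / 2147483648.0
        depth = 32
    elif data.dtype == np.uint8:
        warnings.warn(f"{path}: 8-bit WAV converted to float")
        x = (data.astype(np.float64) - 128.0) / 128.0
        depth = 8
    elif np.issubdtype(data.dtype, np.floating):
        warnings.warn(f"{path}: float WAV accepted as-is")
        x = np.clip(data.astype(np.float64), -1.0, 1.0)
        depth = 32
    else:
        raise ValueError(f"{path}: unsupported WAV sample format {data.dtype}")
    return AudioSample(samples=x, fs_hz=int(fs), bit_depth=depth, task=task)


def write_wav(path, audio: AudioSample) -> None:
    """Write an :class:`AudioSample` as 16-bit PCM mono WAV."""
    q = np.clip(np.round(audio.samples * 32767.0), -32768, 32767).astype(np.int16)
    wavfile.write(path, int(audio.fs_hz), q)
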