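"""Synthetic speech-task generators with per-cycle ground truth.

The study tasks — sustained /a/ phonation, rapid /ta/ repetition (DDK), and
passage reading — are emulated by a source–filter scheme: a glottal impulse
train with controlled cycle-to-cycle period (jitter) and amplitude (shimmer)
perturbation drives a fixed two-resonance vowel-like filter, and additive
broadband noise sets the harmonics-to-noise ratio. Every generator returns a
:class:`GroundTruthSidecar` holding the realized cycle series, event times and
the two additive signal components, so downstream estimators can be checked
against planted truth rather than against other estimators.

Pulse positions are quantized to integer samples and the sidecar stores the
*realized* (quantized) periods, keeping truth and waveform consistent
sample-for-sample.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import signal

from .audio import AudioSample

# Fixed vowel-like resonator: two formants (Hz, bandwidth Hz).
_FORMANTS = ((600.0, 90.0), (1100.0, 130.0))


def _resonator_sos(fs_hz: float) -> np.ndarray:
    """Cascade of two-pole resonators as second-order sections."""
    sos = []
    for f, bw in _FORMANTS:
        r = np.exp(-np.pi * bw / fs_hz)
        theta = 2.0 * np.pi * f / fs_hz
        # H(z) = g / (1 - 2 r cos(theta) z^-1 + r^2 z^-2), unit gain at f
        b0 = (1.0 - r) * np.sqrt(1.0 - 2.0 * r * np.cos(2 * theta) + r * r)
        sos.append([b0, 0.0, 0.0, 1.0, -2.0 * r * np.cos(theta), r * r])
    return np.asarray(sos)


def _truncated_normal(rng: np.random.Generator, sd: float, size: int) -> np.ndarray:
    """I.i.d. N(0, sd) draws truncated at +-3 sd (resampled, not clipped)."""
    if sd == 0.0:
        return np.zeros(size)
    out = rng.normal(0.0, sd, size)
    bad = np.abs(out) > 3.0 * sd
    while np.any(bad):
        out[bad] = rng.normal(0.0, sd, int(bad.sum()))
        bad = np.abs(out) > 3.0 * sd
    return out


@dataclass
class VoiceSpec:
    """Ground-truth parameters for a sustained-vowel synthesis."""

    f0_hz: float = 120.0
    duration_s: float = 3.0
    jitter_pct: float = 0.5
    shimmer_pct: float = 2.0
    hnr_db: float = 25.0
    fs_hz: int = 44100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.f0_hz <= 0 or self.duration_s <= 0:
            raise ValueError("f0_hz and duration_s must be positive")
        if self.jitter_pct < 0 or self.shimmer_pct < 0:
            raise ValueError("perturbation percentages must be non-negative")
        if self.fs_hz < 4 * self.f0_hz:
            raise ValueError(
                f"fs_hz={self.fs_hz} too low for f0={self.f0_hz} (need >= 4*f0)"
            )


@dataclass
class DDKSpec:
    """Ground-truth parameters for a /ta/-repetition synthesis."""

    rate_syll_per_s: float = 5.0
    ctv_s: float = 0.02
    n_syll: int = 20
    fs_hz: int = 44100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rate_syll_per_s <= 0:
            raise ValueError("rate must be positive")
        if self.ctv_s < 0:
            raise ValueError("ctv_s must be non-negative")
        if self.n_syll < 2:
            raise ValueError("need at least 2 syllables")


@dataclass
class PassageSpec:
    """Alternating speech/pause layout for a read-passage synthesis.

    ``speech_segment_durations_s`` and ``pause_durations_s`` interleave as
    segment, pause, segment, ...; there must be exactly one fewer pause than
    segments (or zero pauses with one segment).
    """

    speech_segment_durations_s: tuple = (4.0, 3.0, 4.0)
    pause_durations_s: tuple = (0.4, 0.8)
    n_words: int = 99
    fs_hz: int = 44100
    seed: int = 0

    def __post_init__(self) -> None:
        segs = tuple(self.speech_segment_durations_s)
        pauses = tuple(self.pause_durations_s)
        if len(segs) == 0:
            raise ValueError("need at least one speech segment")
        if len(pauses) != len(segs) - 1:
            raise ValueError("segments and pauses must alternate (n_pauses = n_segments - 1)")
        if any(d <= 0 for d in segs) or any(d <= 0 for d in pauses):
            raise ValueError("all durations must be positive")
        if self.n_words < 1:
            raise ValueError("n_words must be >= 1")


@dataclass
class GroundTruthSidecar:
    """Planted truth accompanying one synthetic recording."""

    fs_hz: int
    periods_s: np.ndarray = field(default_factory=lambda: np.empty(0))
    amplitudes: np.ndarray = field(default_factory=lambda: np.empty(0))
    pulse_times_s: np.ndarray = field(default_factory=lambda: np.empty(0))
    syllable_onsets_s: np.ndarray = field(default_factory=lambda: np.empty(0))
    pause_bounds_s: list = field(default_factory=list)
    harmonic: np.ndarray = field(default_factory=lambda: np.empty(0))
    noise: np.ndarray = field(default_factory=lambda: np.empty(0))

    def hnr_db_true(self) -> float:
        """10*log10 of harmonic/noise power ratio of the stored components."""
        p_h = float(np.mean(self.harmonic**2))
        p_n = float(np.mean(self.noise**2)) if self.noise.size else 0.0
        if p_n == 0.0:
            return float("inf")
        return 10.0 * np.log10(p_h / p_n)

    def to_json(self, path) -> None:
        obj = {
            "fs_hz": int(self.fs_hz),
            "periods_s": self.periods_s.tolist(),
            "amplitudes": self.amplitudes.tolist(),
            "pulse_times_s": self.pulse_times_s.tolist(),
            "syllable_onsets_s": self.syllable_onsets_s.tolist(),
            "pause_bounds_s": [list(map(float, b)) for b in self.pause_bounds_s],
            "harmonic": self.harmonic.tolist(),
            "noise": self.noise.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(obj, fh)

    @classmethod
    def from_json(cls, path) -> "GroundTruthSidecar":
        with open(path) as fh:
            obj = json.load(fh)
        return cls(
            fs_hz=obj["fs_hz"],
            periods_s=np.asarray(obj["periods_s"]),
            amplitudes=np.asarray(obj["amplitudes"]),
            pulse_times_s=np.asarray(obj["pulse_times_s"]),
            syllable_onsets_s=np.asarray(obj["syllable_onsets_s"]),
            pause_bounds_s=[tuple(b) for b in obj["pause_bounds_s"]],
            harmonic=np.asarray(obj["harmonic"]),
            noise=np.asarray(obj["noise"]),
        )


def _vowel_pulse(fs_hz: int, max_len: int) -> np.ndarray:
    """Truncated impulse response of the vowel resonator.

    Truncating just under the shortest admissible period keeps successive
    glottal cycles non-overlapping, so each cycle's waveform peak is an exact
    image of its planted amplitude; a raised-cosine taper removes the
    truncation edge.
    """
    imp = np.zeros(max_len)
    imp[0] = 1.0
    h = signal.sosfilt(_resonator_sos(fs_hz), imp)
    n_tap = max(8, int(0.15 * max_len))
    h[-n_tap:] *= 0.5 * (1.0 + np.cos(np.linspace(0.0, np.pi, n_tap)))
    return h


def _pulse_train(
    rng: np.random.Generator,
    f0_hz: float,
    duration_s: float,
    jitter_pct: float,
    shimmer_pct: float,
    fs_hz: int,
):
    """Quantized glottal impulse train; returns (train, periods_s, amps, times_s)."""
    t0 = 1.0 / f0_hz
    n_cycles = int(np.floor(duration_s * f0_hz)) + 1
    jitter_sd = jitter_pct / 100.0 * t0
    if 3.0 * jitter_sd >= t0:
        raise ValueError(
            f"jitter_pct={jitter_pct} allows non-positive periods at f0={f0_hz}"
        )
    periods = t0 + _truncated_normal(rng, jitter_sd, n_cycles)
    if np.any(periods <= 0):  # unreachable given the 3-sd guard, kept as a hard check
        raise ValueError("realized non-positive glottal period")
    amps = 1.0 + _truncated_normal(rng, shimmer_pct / 100.0, n_cycles)
    if np.any(amps <= 0):
        raise ValueError(f"shimmer_pct={shimmer_pct} allows non-positive amplitudes")

    times = np.concatenate([[0.0], np.cumsum(periods)])[:-1]
    idx = np.round(times * fs_hz).astype(int)
    n_samples = int(round(duration_s * fs_hz))
    keep = idx < n_samples
    idx, amps = idx[keep], amps[keep]
    train = np.zeros(n_samples)
    train[idx] = amps
    real_times = idx / fs_hz
    real_periods = np.diff(real_times)
    return train, real_periods, amps, real_times


def synth_vowel(spec: VoiceSpec) -> tuple[AudioSample, GroundTruthSidecar]:
    """Synthesize a sustained /a/-like vowel with planted perturbations.

    The harmonic component is the impulse train through the fixed resonator;
    the noise component is white Gaussian noise scaled so that
    ``10*log10(P_harmonic / P_noise)`` equals ``spec.hnr_db``.
    """
    rng = np.random.default_rng(spec.seed)
    train, periods, amps, times = _pulse_train(
        rng, spec.f0_hz, spec.duration_s, spec.jitter_pct, spec.shimmer_pct, spec.fs_hz
    )
    t0_samples = spec.fs_hz / spec.f0_hz
    min_period = t0_samples * (1.0 - 3.0 * spec.jitter_pct / 100.0)
    pulse = _vowel_pulse(spec.fs_hz, max(4, int(0.95 * min_period)))
    harmonic = np.zeros(train.size + pulse.size)
    for i in np.flatnonzero(train):
        harmonic[i : i + pulse.size] += train[i] * pulse
    harmonic = harmonic[: train.size]
    p_h = np.mean(harmonic**2)
    if np.isinf(spec.hnr_db):
        noise = np.zeros_like(harmonic)
    else:
        raw = rng.normal(0.0, 1.0, harmonic.size)
        target_pn = p_h / 10.0 ** (spec.hnr_db / 10.0)
        noise = raw * np.sqrt(target_pn / np.mean(raw**2))
    x = harmonic + noise
    scale = 0.9 / np.max(np.abs(x))
    audio = AudioSample(samples=x * scale, fs_hz=spec.fs_hz, task="phonation")
    sidecar = GroundTruthSidecar(
        fs_hz=spec.fs_hz,
        periods_s=periods,
        amplitudes=amps,
        pulse_times_s=times,
        harmonic=harmonic * scale,
        noise=noise * scale,
    )
    return audio, sidecar


def synth_ddk(spec: DDKSpec) -> tuple[AudioSample, GroundTruthSidecar]:
    """Synthesize a /ta/-repetition train with planted rate and timing jitter.

    Each syllable is a brief unvoiced noise burst (the /t/ release) followed by
    a decaying voiced nucleus. Inter-onset intervals are Normal(1/rate, ctv)
    truncated at +-3 sd and at zero.
    """
    rng = np.random.default_rng(spec.seed)
    mean_int = 1.0 / spec.rate_syll_per_s
    intervals = mean_int + _truncated_normal(rng, spec.ctv_s, spec.n_syll - 1)
    if np.any(intervals <= 0):
        raise ValueError("ctv_s too large: non-positive inter-onset interval")
    burst_s = 0.025
    nucleus_s = min(0.10, 0.55 * mean_int)
    if np.any(intervals <= burst_s + nucleus_s):
        raise ValueError("syllables overlap: interval shorter than burst length")

    onsets = np.concatenate([[0.05], 0.05 + np.cumsum(intervals)])
    onset_idx = np.round(onsets * spec.fs_hz).astype(int)
    onsets = onset_idx / spec.fs_hz
    n_samples = int(round((onsets[-1] + nucleus_s + 0.2) * spec.fs_hz))
    harmonic = np.zeros(n_samples)
    noise = np.zeros(n_samples)

    sos = _resonator_sos(spec.fs_hz)
    f0 = 150.0
    n_burst = int(burst_s * spec.fs_hz)
    n_nuc = int(nucleus_s * spec.fs_hz)
    t_nuc = np.arange(n_nuc) / spec.fs_hz
    envelope = np.sin(np.pi * np.arange(n_nuc) / n_nuc) ** 0.5
    for i0 in onset_idx:
        noise[i0 : i0 + n_burst] += 0.4 * rng.normal(0.0, 1.0, n_burst)
        train = np.zeros(n_nuc)
        pulse_at = np.round(np.arange(0.0, nucleus_s, 1.0 / f0) * spec.fs_hz).astype(int)
        train[pulse_at[pulse_at < n_nuc]] = 1.0
        nucleus = signal.sosfilt(sos, train) * envelope
        harmonic[i0 + n_burst : i0 + n_burst + n_nuc] += nucleus

    x = harmonic + noise
    scale = 0.9 / np.max(np.abs(x))
    audio = AudioSample(samples=x * scale, fs_hz=spec.fs_hz, task="ddk")
    sidecar = GroundTruthSidecar(
        fs_hz=spec.fs_hz,
        syllable_onsets_s=onsets,
        harmonic=harmonic * scale,
        noise=noise * scale,
    )
    return audio, sidecar


def synth_passage(
    spec: PassageSpec,
) -> tuple[AudioSample, GroundTruthSidecar, dict]:
    """Synthesize a passage-like alternation of voiced speech and silence.

    Speech segments are mildly jittered voiced signal through the resonator;
    pauses are near-silence (a -60 dB noise floor). ``transcript_meta``
    carries the nominal word count and total duration, mirroring the manual
    transcription metadata of a real reading task.
    """
    rng = np.random.default_rng(spec.seed)
    fs = spec.fs_hz
    pieces = []
    pause_bounds = []
    t_cursor = 0.0
    sos = _resonator_sos(fs)
    segs = list(spec.speech_segment_durations_s)
    pauses = list(spec.pause_durations_s)
    for i, seg_dur in enumerate(segs):
        train, _, _, _ = _pulse_train(rng, 120.0, seg_dur, 1.0, 3.0, fs)
        seg = signal.sosfilt(sos, train)
        seg = seg / np.max(np.abs(seg)) * 0.8
        pieces.append(seg)
        t_cursor += seg.size / fs
        if i < len(pauses):
            n_p = int(round(pauses[i] * fs))
            pieces.append(rng.normal(0.0, 1e-3, n_p))
            pause_bounds.append((t_cursor, t_cursor + n_p / fs))
            t_cursor += n_p / fs
    x = np.concatenate(pieces)
    audio = AudioSample(samples=np.clip(x, -1, 1), fs_hz=fs, task="passage")
    sidecar = GroundTruthSidecar(
        fs_hz=fs, pause_bounds_s=pause_bounds, harmonic=x, noise=np.zeros_like(x)
    )
    meta = {"n_words": int(spec.n_words), "total_duration_s": float(x.size / fs)}
    return audio, sidecar, meta
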