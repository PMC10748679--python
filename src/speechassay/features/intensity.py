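"""Frame-level intensity and zero-crossing-rate measures."""

from __future__ import annotations

import numpy as np
from scipy import stats

from ..audio import AudioSample
from .cycles import frame_signal

DB_FLOOR = -120.0
# Uncalibrated SPL mapping for loudness: digital full scale -> 90 dB SPL-equiv.
FULL_SCALE_DB_SPL = 90.0


def frame_rms_db(audio: AudioSample, win_s: float = 0.025, hop_s: float = 0.010):
    """Per-frame RMS and dB-full-scale, with silent frames floored at -120 dB."""
    frames, starts = frame_signal(audio.samples, audio.fs_hz, win_s, hop_s)
    rms = np.sqrt(np.mean(frames**2, axis=1))
    db = np.where(rms > 0, 20.0 * np.log10(np.maximum(rms, 1e-30)), DB_FLOOR)
    db = np.maximum(db, DB_FLOOR)
    return rms, db, starts


def intensity_measures(audio: AudioSample) -> dict:
    """Intensity summary: mean dB, mean energy, mean sones, and order
    statistics of the frame dB series.

    Sones use the fixed synthetic calibration full scale -> 90 dB
    SPL-equivalent (no physical SPL calibration exists), then the standard
    2**((L - 40)/10) loudness map.
    """
    rms, db, _ = frame_rms_db(audio)
    sones = 2.0 ** ((db + FULL_SCALE_DB_SPL - 40.0) / 10.0)
    return {
        "mean_db": float(db.mean()),
        "mean_energy": float(np.mean(rms**2)),
        "mean_sones": float(sones.mean()),
        "median": float(np.median(db)),
        "min": float(db.min()),
        "max": float(db.max()),
        "range": float(db.max() - db.min()),
        "var": float(db.var(ddof=1)) if db.size > 1 else 0.0,
    }


def zcr_measures(audio: AudioSample, win_s: float = 0.025, hop_s: float = 0.010) -> dict:
    """Zero-crossing rate (crossings per second) moments across frames.

    Kurtosis is the excess kurtosis. Constant frames contribute a rate of 0.
    """
    frames, _ = frame_signal(audio.samples, audio.fs_hz, win_s, hop_s)
    nonneg = frames >= 0.0
    crossings = np.sum(nonneg[:, 1:] != nonneg[:, :-1], axis=1)
    rate = crossings * audio.fs_hz / frames.shape[1]
    return {
        "mean": float(rate.mean()),
        "var": float(rate.var(ddof=1)) if rate.size > 1 else 0.0,
        "skewness": float(stats.skew(rate)) if rate.size > 2 else np.nan,
        "kurtosis": float(stats.kurtosis(rate)) if rate.size > 3 else np.nan,
    }
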