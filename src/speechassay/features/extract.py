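"""Composition of the per-family measures into full feature vectors.

``extract_features`` emits the fixed 53-name automated vector for any task;
``extract_reference_features`` emits the lab-style task-specific sets (80
passage / 43 phonation / 2 DDK) computed with independent algorithm choices
(cepstral pitch tracking, 40 ms frames, a different pause threshold), serving
as the second view for analytical validation. Undefined measures are NaN,
never 0, so downstream correlation code can use pairwise-complete data.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..audio import AudioSample
from .cycles import track_f0, track_f0_cepstral, frame_signal
from .intensity import frame_rms_db, intensity_measures, zcr_measures
from .names import FEATURE_NAMES, REFERENCE_NAMES
from .perturbation import hnr_measures, jitter_measures, shimmer_measures
from .segmentation import SegmentationResult, ddk_measures, segment_speech_pause, timing_measures

_STATS6 = ("mean", "median", "min", "max", "range", "var")


def _f0_stats(frame_f0: np.ndarray) -> dict:
    v = frame_f0[np.isfinite(frame_f0)]
    if v.size == 0:
        return {s: np.nan for s in _STATS6}
    return {
        "mean": float(v.mean()),
        "median": float(np.median(v)),
        "min": float(v.min()),
        "max": float(v.max()),
        "range": float(v.max() - v.min()),
        "var": float(v.var(ddof=1)) if v.size > 1 else 0.0,
    }


def _pause_features(seg: SegmentationResult, transcript_meta: dict | None) -> dict:
    total_min = seg.total_time_s / 60.0
    out = {}
    for cls, label in (("short", "short"), ("medium", "med"), ("long", "long")):
        durs = seg.pause_durations(cls)
        out[f"{label} pause ct norm"] = durs.size / total_min if total_min > 0 else np.nan
        out[f"{label} pause dur"] = float(durs.mean()) if durs.size else np.nan
    all_durs = seg.pause_durations()
    out["mean pause dur"] = float(all_durs.mean()) if all_durs.size else np.nan
    return out


def extract_features(
    audio: AudioSample, task: str | None = None, transcript_meta: dict | None = None
) -> pd.Series:
    """Extract the canonical 53-feature acoustic vector from one recording.

    The same names are emitted for every task; entries that a task cannot
    define (word-based timing without a transcript, pause durations with no
    pauses) are NaN. Per-measure failures never abort the vector.
    """
    task = task or audio.task
    cycles = track_f0(audio)
    out: dict = {}
    for s, v in _f0_stats(cycles.frame_f0_hz).items():
        out[f"F0 {s}"] = v
    for method in ("ac", "cc"):
        for s, v in hnr_measures(audio, cycles, method).items():
            out[f"HNR {method} {s}"] = v
    inten = intensity_measures(audio)
    out["int mean dB"] = inten["mean_db"]
    out["int mean energy"] = inten["mean_energy"]
    out["int mean sones"] = inten["mean_sones"]
    for s in ("median", "min", "max", "range", "var"):
        out[f"int {s}"] = inten[s]
    jit = jitter_measures(cycles)
    out["jitter local"] = jit["local"]
    out["jitter local abs"] = jit["local_abs"]
    out["jitter rap"] = jit["rap"]
    out["jitter PPQ5"] = jit["ppq5"]
    out["jitter DDP"] = jit["ddp"]
    shim = shimmer_measures(cycles)
    out["shimmer local"] = shim["local"]
    out["shimmer local dB"] = shim["local_db"]
    out["shimmer APQ3"] = shim["apq3"]
    out["shimmer APQ5"] = shim["apq5"]
    out["shimmer APQ11"] = shim["apq11"]
    out["shimmer DDA"] = shim["dda"]
    for s, v in zcr_measures(audio).items():
        out[f"ZCR {s}"] = v
    seg = segment_speech_pause(audio)
    out.update(_pause_features(seg, transcript_meta))
    timing = timing_measures(seg, transcript_meta)
    out["pause word ratio"] = timing["pause_word_ratio"]
    out["speech rate"] = timing["speech_rate"]
    out["articulation rate"] = timing["articulation_rate"]
    out["avg word dur"] = timing["avg_word_dur"]
    out["phonation rate"] = timing["phonation_rate"]
    vec = pd.Series(out, dtype=float).reindex(FEATURE_NAMES)
    assert len(vec) == 53
    return vec


def _spectral_moments(audio: AudioSample, win_s: float = 0.040, hop_s: float = 0.010):
    """Per-frame spectral centroid/spread/skewness/kurtosis and dB tilt."""
    frames, _ = frame_signal(audio.samples, audio.fs_hz, win_s, hop_s)
    win = np.hanning(frames.shape[1])
    spec = np.abs(np.fft.rfft(frames * win, axis=1))
    freqs = np.fft.rfftfreq(frames.shape[1], 1.0 / audio.fs_hz)
    power = spec**2
    tot = power.sum(axis=1)
    ok = tot > 0
    power = power[ok]
    tot = tot[ok]
    w = power / tot[:, None]
    centroid = w @ freqs
    spread = np.sqrt(np.maximum((w * (freqs[None, :] - centroid[:, None]) ** 2).sum(axis=1), 0))
    spread_safe = np.maximum(spread, 1e-9)
    zc = (freqs[None, :] - centroid[:, None]) / spread_safe[:, None]
    skewness = (w * zc**3).sum(axis=1)
    kurt = (w * zc**4).sum(axis=1) - 3.0
    # dB tilt over 0-8 kHz, slope per kHz averaged across frames
    band = freqs <= 8000.0
    db = 20.0 * np.log10(np.maximum(spec[:, band], 1e-12))
    slope = np.polyfit(freqs[band] / 1000.0, db.T, 1)[0]
    return centroid, spread, skewness, kurt, float(slope.mean())


def _reference_voice_measures(audio: AudioSample) -> dict:
    cyc = track_f0_cepstral(audio)
    out: dict = {}
    v = cyc.frame_f0_hz[np.isfinite(cyc.frame_f0_hz)]
    stats = {
        "mean": v.mean() if v.size else np.nan,
        "median": np.median(v) if v.size else np.nan,
        "sd": v.std(ddof=1) if v.size > 1 else np.nan,
        "min": v.min() if v.size else np.nan,
        "max": v.max() if v.size else np.nan,
        "range": v.max() - v.min() if v.size else np.nan,
    }
    for s, val in stats.items():
        out[f"ref F0 {s}"] = float(val) if np.isfinite(val) else np.nan
    jit = jitter_measures(cyc)
    out["ref jitter local"] = jit["local"]
    out["ref jitter local abs"] = jit["local_abs"]
    out["ref jitter rap"] = jit["rap"]
    out["ref jitter ppq5"] = jit["ppq5"]
    out["ref jitter ddp"] = jit["ddp"]
    shim = shimmer_measures(cyc)
    out["ref shimmer local"] = shim["local"]
    out["ref shimmer local dB"] = shim["local_db"]
    out["ref shimmer apq3"] = shim["apq3"]
    out["ref shimmer apq5"] = shim["apq5"]
    out["ref shimmer apq11"] = shim["apq11"]
    out["ref shimmer dda"] = shim["dda"]
    hnr = hnr_measures(audio, cyc, "ac")
    hnr_db = {
        "mean": hnr["mean"],
        "median": hnr["median"],
        "sd": np.sqrt(hnr["var"]) if np.isfinite(hnr["var"]) else np.nan,
        "min": hnr["min"],
        "max": hnr["max"],
        "range": hnr["range"],
    }
    for s, val in hnr_db.items():
        out[f"ref HNR {s}"] = val
    cpp = cyc.cpp_db[np.isfinite(cyc.cpp_db) & cyc.voiced_mask[: cyc.cpp_db.size]]
    out["ref CPP mean"] = float(cpp.mean()) if cpp.size else np.nan
    out["ref CPP sd"] = float(cpp.std(ddof=1)) if cpp.size > 1 else np.nan
    out["ref CPP min"] = float(cpp.min()) if cpp.size else np.nan
    out["ref CPP max"] = float(cpp.max()) if cpp.size else np.nan
    out["ref CPP median"] = float(np.median(cpp)) if cpp.size else np.nan
    centroid, spread, skewness, kurt, tilt = _spectral_moments(audio)
    out["ref spectral centroid mean"] = float(centroid.mean())
    out["ref spectral centroid sd"] = float(centroid.std(ddof=1))
    out["ref spectral centroid min"] = float(centroid.min())
    out["ref spectral centroid max"] = float(centroid.max())
    out["ref spectral spread mean"] = float(spread.mean())
    out["ref spectral skewness mean"] = float(skewness.mean())
    out["ref spectral kurtosis mean"] = float(kurt.mean())
    out["ref spectral tilt"] = tilt
    rms, db, _ = frame_rms_db(audio, 0.040, 0.010)
    out["ref rms mean"] = float(rms.mean())
    out["ref rms sd"] = float(rms.std(ddof=1))
    out["ref rms min"] = float(rms.min())
    out["ref rms max"] = float(rms.max())
    out["ref rms range"] = float(rms.max() - rms.min())
    out["ref peak amplitude"] = float(np.max(np.abs(audio.samples)))
    zcr = zcr_measures(audio, 0.040, 0.010)
    out["ref ZCR mean"] = zcr["mean"]
    out["ref ZCR sd"] = float(np.sqrt(zcr["var"])) if np.isfinite(zcr["var"]) else np.nan
    out["ref int dB p10"] = float(np.percentile(db, 10))
    out["ref int dB p90"] = float(np.percentile(db, 90))
    # noise-to-harmonics ratio per voiced frame, from the ac-method HNR series
    frames_hnr = _frame_nhr(audio, cyc)
    out["ref NHR mean"] = float(frames_hnr.mean()) if frames_hnr.size else np.nan
    out["ref NHR sd"] = float(frames_hnr.std(ddof=1)) if frames_hnr.size > 1 else np.nan
    out["ref NHR max"] = float(frames_hnr.max()) if frames_hnr.size else np.nan
    # frame-level ZCR extremes (for the passage set)
    fr, _ = frame_signal(audio.samples, audio.fs_hz, 0.040, 0.010)
    nonneg = fr >= 0
    rate = np.sum(nonneg[:, 1:] != nonneg[:, :-1], axis=1) * audio.fs_hz / fr.shape[1]
    out["ref ZCR min"] = float(rate.min())
    out["ref ZCR max"] = float(rate.max())
    voiced = cyc.voiced_mask
    out["ref voiced fraction"] = float(voiced.mean()) if voiced.size else np.nan
    d = np.diff(cyc.frame_f0_hz)
    d = d[np.isfinite(d)]
    out["ref F0 delta mean abs"] = float(np.mean(np.abs(d))) if d.size else np.nan
    return out


def _frame_nhr(audio: AudioSample, cyc) -> np.ndarray:
    frames, _ = frame_signal(audio.samples, audio.fs_hz, cyc.frame_win_s, 0.010)
    n_avail = min(frames.shape[0], cyc.voiced_mask.size)
    vals = []
    for i in range(n_avail):
        if not cyc.voiced_mask[i]:
            continue
        f0 = cyc.frame_f0_hz[i]
        lag = int(round(audio.fs_hz / f0))
        fr = frames[i] - frames[i].mean()
        n = fr.size
        if lag >= n - 1:
            continue
        num = np.dot(fr[:-lag], fr[lag:]) / (n - lag)
        den = np.dot(fr, fr) / n
        if den <= 0:
            continue
        r = np.clip(num / den, 1e-6, 1 - 1e-6)
        vals.append((1.0 - r) / r)
    return np.asarray(vals)


def _reference_segment_measures(audio: AudioSample, transcript_meta: dict | None) -> dict:
    seg = segment_speech_pause(audio, threshold_db=30.0, min_pause_s=0.20)
    out: dict = {}
    seg_durs = np.asarray([e - s for s, e in seg.speech_segments])
    pause_durs = seg.pause_durations()
    out["ref n speech segments"] = float(seg_durs.size)
    out["ref n pauses"] = float(pause_durs.size)
    out["ref speech time"] = seg.phonated_time_s
    out["ref pause time"] = seg.pause_time_s()
    out["ref total time"] = seg.total_time_s
    out["ref speech seg dur mean"] = float(seg_durs.mean()) if seg_durs.size else np.nan
    out["ref speech seg dur sd"] = float(seg_durs.std(ddof=1)) if seg_durs.size > 1 else np.nan
    out["ref speech seg dur min"] = float(seg_durs.min()) if seg_durs.size else np.nan
    out["ref speech seg dur max"] = float(seg_durs.max()) if seg_durs.size else np.nan
    out["ref pause dur mean"] = float(pause_durs.mean()) if pause_durs.size else np.nan
    out["ref pause dur sd"] = float(pause_durs.std(ddof=1)) if pause_durs.size > 1 else np.nan
    out["ref pause dur min"] = float(pause_durs.min()) if pause_durs.size else np.nan
    out["ref pause dur max"] = float(pause_durs.max()) if pause_durs.size else np.nan
    total = seg.total_time_s
    out["ref pause fraction"] = seg.pause_time_s() / total if total > 0 else np.nan
    out["ref speech fraction"] = seg.phonated_time_s / total if total > 0 else np.nan
    timing = timing_measures(seg, transcript_meta)
    out["ref speech rate wpm"] = timing["speech_rate"]
    out["ref articulation rate wpm"] = timing["articulation_rate"]
    out["ref avg word dur"] = timing["avg_word_dur"]
    out["ref pause word ratio"] = timing["pause_word_ratio"]
    for cls, label in (("short", "short"), ("medium", "med"), ("long", "long")):
        out[f"ref {label} pause ct"] = float(seg.pause_durations(cls).size)
    _, db, _ = frame_rms_db(audio, 0.040, 0.010)
    out["ref int dB mean"] = float(db.mean())
    out["ref int dB sd"] = float(db.std(ddof=1))
    out["ref int dB min"] = float(db.min())
    out["ref int dB max"] = float(db.max())
    out["ref int dB range"] = float(db.max() - db.min())
    return out


def extract_reference_features(
    audio: AudioSample, task: str | None = None, transcript_meta: dict | None = None
) -> pd.Series:
    """Extract the lab-style reference feature vector for one recording.

    Emits 43 voice measures for phonation, those plus 37 segment/timing
    measures (80 total) for passage reading, and exactly {rate, ctv} for DDK.
    """
    task = task or audio.task
    names = REFERENCE_NAMES[task]
    if task == "ddk":
        ddk = ddk_measures(audio)
        return pd.Series(
            {"ref ddk rate": ddk["rate"], "ref ddk ctv": ddk["ctv"]}, dtype=float
        ).reindex(names)
    out = _reference_voice_measures(audio)
    if task == "passage":
        out.update(_reference_segment_measures(audio, transcript_meta))
    return pd.Series(out, dtype=float).reindex(names)
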