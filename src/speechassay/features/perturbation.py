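"""Jitter, shimmer, and harmonics-to-noise ratio measures.

Jitter and shimmer follow the MDVP/Praat-standard formulas over a glottal
cycle series; HNR is computed per frame from the normalized autocorrelation
("ac") or from the cross-correlation of consecutive cycles ("cc") as
``10*log10(r / (1 - r))`` clamped to [-20, 60] dB.
"""

from __future__ import annotations

import warnings

import numpy as np

from ..audio import AudioSample
from .cycles import GlottalCycleSeries, frame_signal

HNR_CLAMP_DB = (-20.0, 60.0)
MIN_CYCLES = 6
MIN_CYCLES_APQ11 = 12

_STATS6 = ("mean", "median", "min", "max", "range", "var")


def _quotient(values: np.ndarray, width: int) -> float:
    """Mean absolute deviation of each value from its centered width-point
    moving average, as a fraction of the overall mean."""
    n = values.size
    half = width // 2
    if n < width:
        return np.nan
    devs = [
        abs(values[i] - values[i - half : i + half + 1].mean())
        for i in range(half, n - half)
    ]
    return float(np.mean(devs) / np.mean(values))


def jitter_measures(cycles: GlottalCycleSeries | np.ndarray) -> dict:
    """MDVP jitter family from per-cycle periods.

    Returns ``{"local", "local_abs", "rap", "ppq5", "ddp"}``; percentages
    except ``local_abs`` (seconds). Fewer than 6 cycles yields NaN.
    """
    periods = (
        cycles.periods_s if isinstance(cycles, GlottalCycleSeries) else np.asarray(cycles)
    )
    periods = periods[np.isfinite(periods)]
    if periods.size < MIN_CYCLES:
        warnings.warn(f"jitter undefined: {periods.size} < {MIN_CYCLES} cycles")
        return {k: np.nan for k in ("local", "local_abs", "rap", "ppq5", "ddp")}
    if np.any(periods <= 0):
        raise ValueError("non-positive period in cycle series")
    mean_t = periods.mean()
    local_abs = float(np.mean(np.abs(np.diff(periods))))
    rap = _quotient(periods, 3) * 100.0
    return {
        "local": local_abs / mean_t * 100.0,
        "local_abs": local_abs,
        "rap": rap,
        "ppq5": _quotient(periods, 5) * 100.0,
        "ddp": 3.0 * rap,
    }


def shimmer_measures(cycles: GlottalCycleSeries | np.ndarray) -> dict:
    """MDVP shimmer family from per-cycle peak amplitudes.

    Returns ``{"local", "local_db", "apq3", "apq5", "apq11", "dda"}``;
    percentages except ``local_db`` (dB). APQ11 needs 12 cycles, the rest 6;
    an insufficient series NaNs only the affected measure.
    """
    amps = (
        cycles.amplitudes if isinstance(cycles, GlottalCycleSeries) else np.asarray(cycles)
    )
    amps = amps[np.isfinite(amps)]
    out = {k: np.nan for k in ("local", "local_db", "apq3", "apq5", "apq11", "dda")}
    if amps.size < MIN_CYCLES:
        warnings.warn(f"shimmer undefined: {amps.size} < {MIN_CYCLES} cycles")
        return out
    if np.any(amps <= 0):
        raise ValueError("non-positive amplitude in cycle series")
    mean_a = amps.mean()
    apq3 = _quotient(amps, 3) * 100.0
    out["local"] = float(np.mean(np.abs(np.diff(amps))) / mean_a * 100.0)
    out["local_db"] = float(np.mean(np.abs(20.0 * np.log10(amps[1:] / amps[:-1]))))
    out["apq3"] = apq3
    out["apq5"] = _quotient(amps, 5) * 100.0
    if amps.size >= MIN_CYCLES_APQ11:
        out["apq11"] = _quotient(amps, 11) * 100.0
    out["dda"] = 3.0 * apq3
    return out


def _r_to_db(r: np.ndarray) -> np.ndarray:
    r = np.clip(r, 1e-6, 1.0 - 1e-6)
    return np.clip(10.0 * np.log10(r / (1.0 - r)), *HNR_CLAMP_DB)


def _summary6(values: np.ndarray) -> dict:
    values = values[np.isfinite(values)]
    if values.size == 0:
        return {s: np.nan for s in _STATS6}
    return {
        "mean": float(values.mean()),
        "median": float(np.median(values)),
        "min": float(values.min()),
        "max": float(values.max()),
        "range": float(values.max() - values.min()),
        "var": float(values.var(ddof=1)) if values.size > 1 else 0.0,
    }


def hnr_measures(
    audio: AudioSample, cycles: GlottalCycleSeries, method: str = "ac"
) -> dict:
    """Summary statistics of frame-level HNR in dB.

    ``ac``: per voiced frame, r is the unbiased normalized autocorrelation at
    the frame's pitch period. ``cc``: r is the Pearson correlation of each
    pair of consecutive cycle-length waveform chunks within a voiced run.
    """
    if method not in ("ac", "cc"):
        raise ValueError(f"unknown HNR method {method!r}")
    x = audio.samples
    fs = audio.fs_hz
    if method == "ac":
        frames, starts = frame_signal(x, fs, cycles.frame_win_s, 0.010)
        n_avail = min(frames.shape[0], cycles.voiced_mask.size)
        rs = []
        for i in range(n_avail):
            if not cycles.voiced_mask[i]:
                continue
            f0 = cycles.frame_f0_hz[i]
            lag = int(round(fs / f0))
            fr = frames[i] - frames[i].mean()
            n = fr.size
            if lag >= n - 1:
                continue
            num = float(np.dot(fr[:-lag], fr[lag:])) / (n - lag)
            den = float(np.dot(fr, fr)) / n
            if den <= 0:
                continue
            rs.append(num / den)
        return _summary6(_r_to_db(np.asarray(rs)))
    # cc: consecutive cycles within runs
    times = cycles.peak_times_s
    bset = set(cycles.run_breaks.tolist())
    rs = []
    for k in range(1, times.size):
        if k in bset:
            continue
        t0 = int(round(times[k - 1] * fs))
        t1 = int(round(times[k] * fs))
        length = t1 - t0
        if length < 4 or t1 + length > x.size:
            continue
        a = x[t0:t1]
        b = x[t1 : t1 + length]
        sa, sb = a.std(), b.std()
        if sa == 0 or sb == 0:
            continue
        rs.append(float(np.corrcoef(a, b)[0, 1]))
    return _summary6(_r_to_db(np.asarray(rs)))
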