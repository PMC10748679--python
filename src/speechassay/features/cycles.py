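"""Pitch tracking and glottal-cycle marking.

Two independent trackers are provided. The primary tracker is
autocorrelation-based (25 ms frames, 10 ms hop, unbiased lag normalization);
the reference tracker is cepstral (40 ms frames) and also yields cepstral
peak prominence. Both feed the same cycle-marking walker, which refines
pitch-synchronous waveform peaks with parabolic interpolation so that period
estimates are sub-sample accurate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..audio import AudioSample

F0_FLOOR_HZ = 60.0
F0_CEILING_HZ = 500.0
VOICING_R_THRESHOLD = 0.45
CPP_VOICING_Z = 4.0  # robust z of the cepstral peak within the search range


def frame_signal(x: np.ndarray, fs: float, win_s: float, hop_s: float):
    """Slice ``x`` into overlapping frames; returns (frames, start_times_s)."""
    n = int(round(win_s * fs))
    hop = int(round(hop_s * fs))
    if x.size < n:
        x = np.pad(x, (0, n - x.size))
    n_frames = 1 + (x.size - n) // hop
    idx = np.arange(n)[None, :] + hop * np.arange(n_frames)[:, None]
    return x[idx], hop * np.arange(n_frames) / fs


@dataclass
class GlottalCycleSeries:
    """Per-cycle periods/amplitudes plus the frame-level track behind them.

    ``run_breaks`` marks, in cycle-peak index space, where a new voiced run
    starts; period/amplitude differences are never taken across runs.
    """

    periods_s: np.ndarray
    amplitudes: np.ndarray
    peak_times_s: np.ndarray
    run_breaks: np.ndarray
    frame_times_s: np.ndarray
    frame_f0_hz: np.ndarray  # NaN where unvoiced
    voiced_mask: np.ndarray
    frame_win_s: float
    fs_hz: float
    cpp_db: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def n_cycles(self) -> int:
        return int(self.periods_s.size)


def _parabolic(y: np.ndarray, i: int) -> tuple[float, float]:
    """Sub-sample vertex (offset, value) of a parabola through y[i-1:i+2]."""
    if i <= 0 or i >= y.size - 1:
        return 0.0, float(y[i])
    a, b, c = y[i - 1], y[i], y[i + 1]
    denom = a - 2.0 * b + c
    if denom == 0.0:
        return 0.0, float(b)
    # a true local maximum keeps |dt| <= 0.5; flat curvature can blow the
    # estimate up, so clamp to the sample cell
    dt = float(np.clip(0.5 * (a - c) / denom, -0.5, 0.5))
    return dt, float(b - 0.25 * (a - c) * dt)


def _frame_autocorr_f0(frames, fs, floor_hz, ceiling_hz):
    """Per-frame best normalized-autocorrelation lag; returns (f0, r_peak)."""
    n = frames.shape[1]
    frames = frames - frames.mean(axis=1, keepdims=True)
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    spec = np.fft.rfft(frames, nfft, axis=1)
    r = np.fft.irfft(spec * np.conj(spec), nfft, axis=1)[:, :n]
    lag_min = max(2, int(np.floor(fs / ceiling_hz)))
    lag_max = min(n - 1, int(np.ceil(fs / floor_hz)))
    f0 = np.full(frames.shape[0], np.nan)
    rpk = np.zeros(frames.shape[0])
    if lag_max <= lag_min:
        return f0, rpk
    lags = np.arange(lag_min, lag_max + 1)
    # unbiased normalization: r[T]/(N-T) against r[0]/N
    r0 = r[:, 0] / n
    valid = r0 > 0
    rn = np.zeros((frames.shape[0], lags.size))
    rn[valid] = (r[valid][:, lags] / (n - lags)[None, :]) / r0[valid, None]
    for i in np.flatnonzero(valid):
        row = rn[i]
        peaks = np.flatnonzero((row[1:-1] >= row[:-2]) & (row[1:-1] >= row[2:])) + 1
        if peaks.size == 0:
            continue
        best = float(row[peaks].max())
        # favor the shortest lag among near-best peaks (octave-error guard);
        # a non-positive best peak is unvoiced anyway, keep its argmax
        cand = peaks[row[peaks] >= 0.85 * best] if best > 0 else peaks
        j = int(cand[0])
        dt, val = _parabolic(row, j)
        lag = lags[0] + j + dt
        f0[i] = fs / lag
        rpk[i] = min(val, 1.0)
    return f0, rpk


def _mark_cycles(x, fs, frame_starts, frame_f0, voiced, win_s):
    """Walk voiced runs marking one waveform peak per pitch period."""
    hop_s = frame_starts[1] - frame_starts[0] if frame_starts.size > 1 else win_s
    y = np.abs(x)
    times, amps, breaks = [], [], []
    runs = []
    i = 0
    while i < voiced.size:
        if voiced[i]:
            j = i
            while j + 1 < voiced.size and voiced[j + 1]:
                j += 1
            runs.append((i, j))
            i = j + 1
        else:
            i += 1
    for a, b in runs:
        s0 = int(round(frame_starts[a] * fs))
        s1 = min(int(round((frame_starts[b] + win_s) * fs)), x.size)
        run_f0 = frame_f0[a : b + 1]
        t_frames = frame_starts[a : b + 1]
        # run-median period: robust to occasional octave errors in the
        # frame-level track (the walker re-centers every cycle anyway)
        med_f0 = np.nanmedian(run_f0)

        def period_at(sample_pos):
            if not np.isfinite(med_f0) or med_f0 <= 0:
                return np.nan
            return fs / med_f0  # samples

        t0 = period_at(s0)
        if not np.isfinite(t0) or s1 - s0 < 2 * t0:
            continue
        p = s0 + int(np.argmax(y[s0 : s0 + int(2 * t0)]))
        run_times, run_amps = [], []
        dt, amp = _parabolic(y, p)
        run_times.append((p + dt) / fs)
        run_amps.append(amp)
        while True:
            period = period_at(p)
            lo = p + int(np.floor(0.70 * period))
            hi = p + int(np.ceil(1.30 * period))
            if hi >= s1:
                break
            # proximity-weighted peak choice: suppresses secondary resonance
            # lobes that noise can push above the true cycle peak
            offs = np.arange(lo, hi) - (p + period)
            w = np.exp(-0.5 * (offs / (0.12 * period)) ** 2)
            q = lo + int(np.argmax(y[lo:hi] * w))
            dt, amp = _parabolic(y, q)
            run_times.append((q + dt) / fs)
            run_amps.append(amp)
            p = q
        if len(run_times) >= 2:
            breaks.append(len(times))
            times.extend(run_times)
            amps.extend(run_amps)
    times = np.asarray(times)
    amps = np.asarray(amps)
    breaks = np.asarray(breaks, dtype=int)
    # periods within runs only
    periods, per_amps = [], []
    bset = set(breaks.tolist())
    for k in range(1, times.size):
        if k in bset:
            continue
        periods.append(times[k] - times[k - 1])
        per_amps.append(amps[k])
    return (
        np.asarray(periods),
        np.asarray(per_amps),
        times,
        breaks,
    )


def track_f0(
    audio: AudioSample,
    floor_hz: float = F0_FLOOR_HZ,
    ceiling_hz: float = F0_CEILING_HZ,
    win_s: float = 0.025,
    hop_s: float = 0.010,
) -> GlottalCycleSeries:
    """Autocorrelation pitch track plus refined glottal-cycle marks.

    Fully unvoiced input yields an empty cycle series (not an error).
    """
    if floor_hz >= ceiling_hz:
        raise ValueError("F0 floor must be below ceiling")
    x = audio.samples
    fs = audio.fs_hz
    frames, starts = frame_signal(x, fs, win_s, hop_s)
    f0, rpk = _frame_autocorr_f0(frames, fs, floor_hz, ceiling_hz)
    rms = np.sqrt(np.mean(frames**2, axis=1))
    energy_gate = rms > max(0.02 * rms.max(), 1e-5)
    voiced = (rpk > VOICING_R_THRESHOLD) & energy_gate & np.isfinite(f0)
    f0 = np.where(voiced, f0, np.nan)
    periods, amps, times, breaks = _mark_cycles(x, fs, starts, f0, voiced, win_s)
    return GlottalCycleSeries(
        periods_s=periods,
        amplitudes=amps,
        peak_times_s=times,
        run_breaks=breaks,
        frame_times_s=starts + win_s / 2,
        frame_f0_hz=f0,
        voiced_mask=voiced,
        frame_win_s=win_s,
        fs_hz=fs,
    )


def track_f0_cepstral(
    audio: AudioSample,
    floor_hz: float = F0_FLOOR_HZ,
    ceiling_hz: float = F0_CEILING_HZ,
    win_s: float = 0.040,
    hop_s: float = 0.010,
) -> GlottalCycleSeries:
    """Cepstral pitch track (reference pipeline) with CPP per frame.

    CPP is the height of the cepstral peak above a linear regression trend
    fitted across the search quefrency range, in dB; frames are voiced when
    CPP exceeds 5 dB and clear the energy gate.
    """
    if floor_hz >= ceiling_hz:
        raise ValueError("F0 floor must be below ceiling")
    x = audio.samples
    fs = audio.fs_hz
    frames, starts = frame_signal(x, fs, win_s, hop_s)
    n = frames.shape[1]
    win = np.hanning(n)
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    spec = np.abs(np.fft.rfft(frames * win, nfft, axis=1))
    logspec = 20.0 * np.log10(np.maximum(spec, 1e-12))
    cep = np.fft.irfft(logspec, axis=1)[:, : nfft // 2]
    q_min = max(2, int(np.floor(fs / ceiling_hz)))
    q_max = min(cep.shape[1] - 2, int(np.ceil(fs / floor_hz)))
    quef = np.arange(q_min, q_max + 1)
    f0 = np.full(frames.shape[0], np.nan)
    cpp = np.full(frames.shape[0], np.nan)
    zscore = np.full(frames.shape[0], 0.0)
    for i in range(frames.shape[0]):
        seg = cep[i, q_min : q_max + 1]
        j = int(np.argmax(seg))
        dq, peak = _parabolic(seg, j)
        slope, intercept = np.polyfit(quef, seg, 1)
        trend = slope * (q_min + j + dq) + intercept
        cpp[i] = (peak - trend) * (nfft / n)  # compensate zero-padding dilution
        med = np.median(seg)
        mad = np.median(np.abs(seg - med))
        zscore[i] = (peak - med) / (1.4826 * mad + 1e-12)
        f0[i] = fs / (q_min + j + dq)
    rms = np.sqrt(np.mean(frames**2, axis=1))
    energy_gate = rms > max(0.02 * rms.max(), 1e-5)
    # candidate frames by cepstral-peak prominence, then an f0-consistency
    # pass: isolated off-pitch detections (typical of aperiodic frames) drop
    candidates = (zscore > CPP_VOICING_Z) & energy_gate & np.isfinite(f0)
    voiced = np.zeros_like(candidates)
    if np.any(candidates):
        strong = candidates & (zscore > CPP_VOICING_Z + 1.0)
        ref_f0 = np.median(f0[strong]) if np.any(strong) else np.median(f0[candidates])
        voiced = candidates & (np.abs(f0 / ref_f0 - 1.0) < 0.25)
    f0 = np.where(voiced, f0, np.nan)
    periods, amps, times, breaks = _mark_cycles(x, fs, starts, f0, voiced, win_s)
    return GlottalCycleSeries(
        periods_s=periods,
        amplitudes=amps,
        peak_times_s=times,
        run_breaks=breaks,
        frame_times_s=starts + win_s / 2,
        frame_f0_hz=f0,
        voiced_mask=voiced,
        frame_win_s=win_s,
        fs_hz=fs,
        cpp_db=cpp,
    )
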