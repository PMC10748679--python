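"""Speech/pause segmentation, transcript-based timing, and DDK measures."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from ..audio import AudioSample
from .intensity import frame_rms_db

SPEECH_THRESHOLD_DB = 25.0  # below the max frame level
MIN_PAUSE_S = 0.15
PAUSE_CLASS_BOUNDS = (0.15, 0.5, 1.0)  # short [0.15,0.5), medium [0.5,1), long >= 1


@dataclass
class SegmentationResult:
    """Disjoint, ordered speech segments and classed pauses for a recording."""

    speech_segments: list  # of (start_s, end_s)
    pauses: list  # of (start_s, end_s, class) with class in {short, medium, long}
    phonated_time_s: float
    total_time_s: float

    def pause_time_s(self) -> float:
        return float(sum(e - s for s, e, _ in self.pauses))

    def pause_durations(self, cls: str | None = None) -> np.ndarray:
        return np.asarray(
            [e - s for s, e, c in self.pauses if cls is None or c == cls]
        )


def _classify_pause(duration: float) -> str:
    if duration >= PAUSE_CLASS_BOUNDS[2]:
        return "long"
    if duration >= PAUSE_CLASS_BOUNDS[1]:
        return "medium"
    return "short"


def segment_speech_pause(
    audio: AudioSample,
    threshold_db: float = SPEECH_THRESHOLD_DB,
    min_pause_s: float = MIN_PAUSE_S,
    win_s: float = 0.025,
    hop_s: float = 0.010,
) -> SegmentationResult:
    """Energy-based speech/pause segmentation.

    A frame is speech when its level exceeds (max frame dB - ``threshold_db``);
    the activity track is median-smoothed, and inter-speech gaps of at least
    ``min_pause_s`` become pauses (shorter gaps are merged into speech).
    Leading and trailing silence belongs to neither class.
    """
    _, db, starts = frame_rms_db(audio, win_s, hop_s)
    total = audio.duration_s
    # -60 dBFS absolute floor keeps a silent recording from being "speech"
    active = (db > db.max() - threshold_db) & (db > -60.0)
    if active.size >= 5:
        active = sps.medfilt(active.astype(float), 5) > 0.5
    if not np.any(active):
        return SegmentationResult([], [], 0.0, total)

    hop = starts[1] - starts[0] if starts.size > 1 else win_s
    # raw active runs -> candidate segments (frame start .. frame start + win)
    # boundaries from frame centers (a frame passes the threshold with any
    # speech overlap, so span-based boundaries would overextend segments)
    segs = []
    i = 0
    while i < active.size:
        if active[i]:
            j = i
            while j + 1 < active.size and active[j + 1]:
                j += 1
            lo = max(starts[i] + win_s / 2 - hop / 2, 0.0)
            hi = min(starts[j] + win_s / 2 + hop / 2, total)
            segs.append([lo, hi])
            i = j + 1
        else:
            i += 1
    # merge gaps shorter than min_pause_s
    merged = [segs[0]]
    for s, e in segs[1:]:
        if s - merged[-1][1] < min_pause_s:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    pauses = []
    for (s0, e0), (s1, _) in zip(merged[:-1], merged[1:]):
        gap = s1 - e0
        pauses.append((e0, s1, _classify_pause(gap)))
    phonated = float(sum(e - s for s, e in merged))
    return SegmentationResult(
        speech_segments=[tuple(se) for se in merged],
        pauses=pauses,
        phonated_time_s=phonated,
        total_time_s=total,
    )


def timing_measures(seg: SegmentationResult, transcript_meta: dict | None) -> dict:
    """Word/syllable timing from segmentation plus transcript metadata.

    ``n_words`` counts words for passage reading and syllables for DDK.
    Rates are per minute; without a usable transcript all word-based entries
    are NaN while ``phonation_rate`` (phonated / total time) remains defined.
    """
    total = seg.total_time_s
    phonated = seg.phonated_time_s
    out = {
        "speech_rate": np.nan,
        "articulation_rate": np.nan,
        "avg_word_dur": np.nan,
        "phonation_rate": phonated / total if total > 0 else np.nan,
        "pause_word_ratio": seg.pause_time_s() / phonated if phonated > 0 else np.nan,
    }
    n_words = (transcript_meta or {}).get("n_words", 0)
    if n_words and n_words > 0:
        out["speech_rate"] = n_words / total * 60.0 if total > 0 else np.nan
        out["articulation_rate"] = n_words / phonated * 60.0 if phonated > 0 else np.nan
        out["avg_word_dur"] = phonated / n_words
    return out


def ddk_measures(audio: AudioSample, envelope_cutoff_hz: float = 20.0) -> dict:
    """Syllable rate and cycle-to-cycle variability of a DDK recording.

    Syllable onsets are peaks of the low-passed amplitude envelope above an
    adaptive threshold. Rate is (n_onsets - 1) / span; CTV is the sample
    standard deviation of inter-onset intervals. Fewer than 3 detected
    onsets yields NaN for both.
    """
    x = np.abs(audio.samples)
    nyq = audio.fs_hz / 2.0
    b, a = sps.butter(4, envelope_cutoff_hz / nyq, btype="low")
    env = sps.filtfilt(b, a, x)
    env = np.maximum(env, 0.0)
    distance = max(1, int(0.08 * audio.fs_hz))
    peaks, _ = sps.find_peaks(env, height=0.25 * env.max(), distance=distance)
    if peaks.size < 3:
        return {"rate": np.nan, "ctv": np.nan}
    onsets = peaks / audio.fs_hz
    intervals = np.diff(onsets)
    rate = (onsets.size - 1) / (onsets[-1] - onsets[0])
    return {"rate": float(rate), "ctv": float(np.std(intervals, ddof=1))}
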