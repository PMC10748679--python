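"""Canonical feature-name registries for the two extraction pipelines.

The automated pipeline emits a fixed 53-name acoustic vector for every task.
The reference pipeline emits task-specific sets (80 for passage reading, 43
for sustained phonation, 2 for DDK), computed with independent algorithm
choices so the two pipelines can be compared feature-against-feature.
"""

_STATS6 = ("mean", "median", "min", "max", "range", "var")

FEATURE_NAMES: tuple = (
    # fundamental frequency summary statistics (Hz / Hz^2)
    *(f"F0 {s}" for s in _STATS6),
    # harmonics-to-noise ratio, frame autocorrelation method (dB)
    *(f"HNR ac {s}" for s in _STATS6),
    # harmonics-to-noise ratio, consecutive-cycle cross-correlation method (dB)
    *(f"HNR cc {s}" for s in _STATS6),
    # intensity (frame dB full scale unless noted)
    "int mean dB",
    "int mean energy",
    "int mean sones",
    "int median",
    "int min",
    "int max",
    "int range",
    "int var",
    # cycle-to-cycle period perturbation (% except local abs, in seconds)
    "jitter local",
    "jitter local abs",
    "jitter rap",
    "jitter PPQ5",
    "jitter DDP",
    # cycle-to-cycle amplitude perturbation (% except local dB)
    "shimmer local",
    "shimmer local dB",
    "shimmer APQ3",
    "shimmer APQ5",
    "shimmer APQ11",
    "shimmer DDA",
    # zero-crossing rate moments (crossings/s)
    "ZCR mean",
    "ZCR var",
    "ZCR skewness",
    "ZCR kurtosis",
    # pause counts (per minute) and durations (s)
    "short pause ct norm",
    "med pause ct norm",
    "long pause ct norm",
    "short pause dur",
    "med pause dur",
    "long pause dur",
    "mean pause dur",
    "pause word ratio",
    # transcript-based timing
    "speech rate",
    "articulation rate",
    "avg word dur",
    "phonation rate",
)
assert len(FEATURE_NAMES) == 53

# Reference (lab-style) sets. Voice measures use a cepstral F0 tracker with
# 40 ms frames; segment measures use a different pause threshold. Names are
# prefixed "ref" to keep the two pipelines' columns distinct in joined tables.
_REF_VOICE: tuple = (
    *(f"ref F0 {s}" for s in ("mean", "median", "sd", "min", "max", "range")),
    "ref jitter local",
    "ref jitter local abs",
    "ref jitter rap",
    "ref jitter ppq5",
    "ref jitter ddp",
    "ref shimmer local",
    "ref shimmer local dB",
    "ref shimmer apq3",
    "ref shimmer apq5",
    "ref shimmer apq11",
    "ref shimmer dda",
    *(f"ref HNR {s}" for s in ("mean", "median", "sd", "min", "max", "range")),
    "ref CPP mean",
    "ref CPP sd",
    "ref CPP min",
    "ref CPP max",
    "ref spectral centroid mean",
    "ref spectral centroid sd",
    "ref spectral spread mean",
    "ref spectral skewness mean",
    "ref spectral kurtosis mean",
    "ref spectral tilt",
    "ref rms mean",
    "ref rms sd",
    "ref rms min",
    "ref rms max",
    "ref rms range",
    "ref peak amplitude",
    "ref ZCR mean",
    "ref ZCR sd",
    "ref NHR mean",
    "ref NHR sd",
)
assert len(_REF_VOICE) == 43

_REF_SEGMENT: tuple = (
    "ref n speech segments",
    "ref n pauses",
    "ref speech time",
    "ref pause time",
    "ref total time",
    "ref speech seg dur mean",
    "ref speech seg dur sd",
    "ref speech seg dur min",
    "ref speech seg dur max",
    "ref pause dur mean",
    "ref pause dur sd",
    "ref pause dur min",
    "ref pause dur max",
    "ref pause fraction",
    "ref speech fraction",
    "ref speech rate wpm",
    "ref articulation rate wpm",
    "ref avg word dur",
    "ref pause word ratio",
    "ref short pause ct",
    "ref med pause ct",
    "ref long pause ct",
    "ref int dB mean",
    "ref int dB sd",
    "ref int dB min",
    "ref int dB max",
    "ref int dB range",
    "ref voiced fraction",
    "ref F0 delta mean abs",
    "ref int dB p10",
    "ref int dB p90",
    "ref ZCR min",
    "ref ZCR max",
    "ref spectral centroid min",
    "ref spectral centroid max",
    "ref CPP median",
    "ref NHR max",
)

REFERENCE_NAMES = {
    "phonation": _REF_VOICE,
    "passage": _REF_VOICE + _REF_SEGMENT,
    "ddk": ("ref ddk rate", "ref ddk ctv"),
}
assert len(REFERENCE_NAMES["passage"]) == 80
assert len(REFERENCE_NAMES["ddk"]) == 2
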