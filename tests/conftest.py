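import numpy as np
import pytest

from speechassay.synth import (
    DDKSpec,
    PassageSpec,
    VoiceSpec,
    synth_ddk,
    synth_passage,
    synth_vowel,
)


@pytest.fixture(scope="session")
def vowel_clean():
    """Perfectly periodic noiseless vowel (f0 = 100 Hz)."""
    return synth_vowel(
        VoiceSpec(f0_hz=100.0, duration_s=2.0, jitter_pct=0.0, shimmer_pct=0.0,
                  hnr_db=np.inf, seed=11)
    )


@pytest.fixture(scope="session")
def vowel_perturbed():
    """Vowel with planted jitter 2%, shimmer 5%, HNR 25 dB (f0 = 220 Hz)."""
    return synth_vowel(
        VoiceSpec(f0_hz=220.0, duration_s=2.0, jitter_pct=2.0, shimmer_pct=5.0,
                  hnr_db=25.0, seed=1)
    )


@pytest.fixture(scope="session")
def vowel_hnr10():
    """Periodic vowel at a 10 dB harmonics-to-noise ratio."""
    return synth_vowel(
        VoiceSpec(f0_hz=120.0, duration_s=2.0, jitter_pct=0.0, shimmer_pct=0.0,
                  hnr_db=10.0, seed=2)
    )


@pytest.fixture(scope="session")
def ddk_regular():
    """DDK train at 5 syll/s with zero planted timing variability."""
    return synth_ddk(DDKSpec(rate_syll_per_s=5.0, ctv_s=0.0, n_syll=20, seed=1))


@pytest.fixture(scope="session")
def passage_three_pauses():
    """Passage with planted pauses of 0.2, 0.7 and 1.5 s."""
    return synth_passage(
        PassageSpec(
            speech_segment_durations_s=(3.0, 2.0, 2.5, 3.0),
            pause_durations_s=(0.2, 0.7, 1.5),
            n_words=99,
            seed=3,
        )
    )
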