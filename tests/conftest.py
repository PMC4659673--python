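import numpy as np
import pytest

import tonestress as ts

FS = 44_100


@pytest.fixture(scope="session")
def design():
    return ts.build_design(seed=11)


@pytest.fixture(scope="session")
def rendered_templates():
    """Zero-jitter template vowels rendered at 63 dB, one per tone."""
    out = {}
    for tone in ts.TONES:
        trk = ts.template_track(ts.TONE_TEMPLATES[tone], hop_s=0.005)
        out[tone] = (trk, ts.render_wav(trk, intensity_db=63.0, vowel="a"))
    return out


def sine(freq, dur_s=1.0, amp=0.5, fs=FS):
    t = np.arange(int(dur_s * fs)) / fs
    return amp * np.sin(2 * np.pi * freq * t)
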