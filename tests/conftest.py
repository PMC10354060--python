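import numpy as np
import pytest

import phonovox as pv


@pytest.fixture(scope="session")
def phonotactics():
    return pv.default_phonotactics(seed=7)


@pytest.fixture(scope="session")
def annotation(phonotactics):
    """A medium-length synthetic stream shared across tests."""
    return pv.gen_stream(phonotactics, 400, seed=3)


@pytest.fixture(scope="session")
def short_annotation(phonotactics):
    return pv.gen_stream(phonotactics, 60, seed=4)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def make_annotation(words, tr=2.0045, gap=0.0, dur_per_phoneme=0.08,
                    start=0.0):
    """Hand-built annotation from (word, phoneme tuple) pairs."""
    events = []
    t = start
    for widx, (_, phonemes) in enumerate(words):
        for pos, ph in enumerate(phonemes):
            events.append(pv.PhonemeEvent(ph, t, t + dur_per_phoneme, widx,
                                          pos))
            t += dur_per_phoneme
        t += gap
    duration = max(t, tr)
    return pv.StimulusAnnotation(events=events, words=list(words),
                                 duration=duration, tr=tr)
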