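import numpy as np
import pytest

from storyenc.lm_adapter import ToyDecayLM
from storyenc.stimulus_windows import TimedToken, Transcript
from storyenc.synthetic_data import profile_config


@pytest.fixture
def toy_lm():
    return ToyDecayLM.random(V=20, d=5, gamma=0.7, seed=11)


@pytest.fixture
def small_transcript():
    """Five tokens at onsets 0, 5, 10, 20, 25 s."""
    onsets = [0.0, 5.0, 10.0, 20.0, 25.0]
    tokens = tuple(
        TimedToken(
            text=f"tok{i}", token_id=i, onset=o, duration=0.4,
            is_word=(i % 2 == 0), lex_freq=100.0 if i % 2 == 0 else float("nan"),
        )
        for i, o in enumerate(onsets)
    )
    return Transcript(tokens=tokens, total_duration=30.0)


@pytest.fixture
def tiny_config():
    return profile_config("tiny", seed=5)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
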