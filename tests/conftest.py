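import numpy as np
import pytest
from hypothesis import strategies as st

from hypnometrics.hypnogram import CANONICAL_STAGES, Hypnogram

#: Epoch-wise stage sequences over the canonical alphabet.
stage_sequences = st.lists(
    st.sampled_from(CANONICAL_STAGES), min_size=1, max_size=300
)

#: Sequences guaranteed to contain sleep (at least one non-W epoch).
sleep_sequences = stage_sequences.filter(lambda s: any(x != "W" for x in s))


def make_hypnogram(stages, record_id="test", epoch_seconds=30.0) -> Hypnogram:
    return Hypnogram(record_id, tuple(stages), epoch_seconds)


@pytest.fixture
def toy_night() -> Hypnogram:
    """20-epoch night with latency, two awakenings and terminal wake.

    Manual counts at 30-s epochs: SOL 90 s, onset epoch 3, sleep period
    epochs 3-18, WASO 1.5 min (epochs 10, 11, 16), TST 6.5 min, TIB 10 min,
    SE 0.65, 2 awakenings, REM latency 2.5 min.
    """
    stages = "W W W N1 N2 N2 N3 N3 R R W W N2 N2 R R W N2 N2 W".split()
    return make_hypnogram(stages, record_id="toy")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)
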