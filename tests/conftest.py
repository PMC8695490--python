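import numpy as np
import pytest

import spiketongue as st
from spiketongue.dataio import CHANNELS, RawRecording


@pytest.fixture
def tiny_recording():
    """Handcrafted 2-session recording with all nine channels."""
    rng = np.random.default_rng(7)
    rows = []
    for sid in (1, 2):
        for t in range(10):
            rows.append((t, sid, 0, t % 5))
    ts = np.array([r[0] for r in rows])
    return RawRecording(
        timestamps=ts,
        values=rng.normal(size=(len(rows), 9)),
        labels=np.array([r[3] for r in rows]),
        session=np.array([r[1] for r in rows]),
        cycle=np.array([r[2] for r in rows]),
        channels=CHANNELS,
    )


@pytest.fixture(scope="session")
def fast_config():
    """Small single-session generator config for quick pipeline tests."""
    return st.SyntheticConfig(
        n_sessions=1, segment_length=60, wash_length=10, transition_tau=5.0,
        seed=123,
    )


@pytest.fixture(scope="session")
def fast_processed(fast_config):
    rec = st.generate_dataset(fast_config)
    processed, model = st.preprocess(rec, segment_length=fast_config.segment_length)
    return processed, model


@pytest.fixture(scope="session")
def fast_split(fast_processed):
    processed, _ = fast_processed
    ws = st.make_windows(processed, T=8)
    return st.split_train_test(ws, processed)


@pytest.fixture(scope="session")
def fast_model(fast_split):
    """Small CNN trained on the quick fixture (T=8, all nine channels)."""
    train, _ = fast_split
    model = st.build_cnn(st.CNNSpec(), T=8, N=9, seed=0)
    st.train_cnn(model, train, st.TrainConfig(epochs=40, seed=0))
    return model
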