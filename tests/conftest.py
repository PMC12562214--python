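import numpy as np
import pytest

from afdetr.profiles import reduced_model_config
from afdetr.synthetic import RhythmSpec, generate_beat_train, render_segment


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def sinus_segment():
    """Clean 10 s sinus-rhythm segment with ground truth."""
    spec = RhythmSpec.sinus(seed=101)
    train = generate_beat_train(spec, 10.0)
    return render_segment(train, spec, duration_s=10.0)


@pytest.fixture(scope="session")
def af_segment():
    """Clean 10 s AF segment with ground truth."""
    spec = RhythmSpec.af(seed=202)
    train = generate_beat_train(spec, 10.0)
    return render_segment(train, spec, duration_s=10.0)


@pytest.fixture(scope="session")
def tiny_model_cfg():
    return reduced_model_config()
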