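import numpy as np
import pytest

from satsn.synthetic import SceneConfig, make_clip_set


@pytest.fixture(scope="session")
def small_clipset():
    """Eight rendered single-agent clips, two per behavior (session-cached)."""
    return make_clip_set(8, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
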