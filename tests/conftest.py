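import numpy as np
import pytest

from spermtrack import SynthConfig, generate_video


@pytest.fixture(scope="session")
def small_scene():
    """A compact seeded scene shared by read-only tests: 3 motile heads,
    2 immotile cells and 5 debris specks in a 320x240, 80-frame clip."""
    config = SynthConfig(
        width=320,
        height=240,
        n_frames=80,
        n_motile=3,
        n_immotile=2,
        n_debris=5,
        min_start_separation_px=60.0,
        seed=11,
    )
    seq, gt = generate_video(config)
    return config, seq, gt


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
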