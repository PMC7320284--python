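import numpy as np
import pytest

from tgamopt import BigPacket, SimConfig, simulate


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_big_packet(rng) -> BigPacket:
    return BigPacket(
        poor_signal=int(rng.integers(0, 201)),
        bands=tuple(int(b) for b in rng.integers(0, 1 << 24, 8)),
        attention=int(rng.integers(0, 101)),
        meditation=int(rng.integers(0, 101)),
    )


@pytest.fixture(scope="session")
def clean_stream():
    """A short clean simulated session: no blinks, no corruption."""
    data, gt = simulate(SimConfig(duration_s=8.0, seed=11))
    return data, gt


@pytest.fixture(scope="session")
def blinky_stream():
    """A session with scheduled blinks (spacing > one big-packet period)."""
    cfg = SimConfig(duration_s=12.0, seed=5, blink_schedule=[1.5, 3.6, 5.2, 7.9, 10.1])
    data, gt = simulate(cfg)
    return cfg, data, gt
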