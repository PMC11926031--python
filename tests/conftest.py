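import numpy as np
import pytest

from obcacount.containers import ChannelImage


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_channel(arr, bit_depth=8, **kw) -> ChannelImage:
    return ChannelImage(np.asarray(arr), bit_depth=bit_depth, **kw)


@pytest.fixture
def channel_factory():
    return make_channel
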