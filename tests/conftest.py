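import numpy as np
import pytest

from gliaquant.io_formats import ChannelStack
from gliaquant.synthetic.presets import default_schedule


@pytest.fixture(scope="session")
def schedule():
    return default_schedule()


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_stack(planes: dict[str, np.ndarray], pixels_per_um: float = 11.1,
               n_z: int = 1) -> ChannelStack:
    """Build a ChannelStack from named 2-D planes (replicated over z)."""
    names = list(planes)
    arr = np.stack([np.repeat(planes[n][None], n_z, axis=0) for n in names])
    return ChannelStack(arr, names, pixels_per_um=pixels_per_um)
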