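import numpy as np
import pytest

from gclnet.anatomy import AnatomyParams, build_local_network


@pytest.fixture(scope="session")
def standard_network():
    """One fixed instantiation of the anatomical local network (d = 4)."""
    return build_local_network(AnatomyParams(seed=42))


@pytest.fixture(scope="session")
def pinned_network():
    """Local network pinned to the 176-rosette / 509-GC instantiation."""
    return build_local_network(
        AnatomyParams(
            margin=0.0,
            dendrites_per_gc=4,
            seed=7,
            pinned_gc_count=509,
            pinned_rosette_count=176,
        )
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
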