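import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from satarray import GenomeLayout, GenomicInterval, IntervalSet

settings.register_profile(
    "suite",
    max_examples=25,
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def layout():
    return GenomeLayout([("chr1", 50_000), ("chr2", 30_000)])


@pytest.fixture
def rng():
    return np.random.default_rng(20_240_101)


def random_interval_set(rng, layout, n, max_len=2000, with_meta=False):
    """Uniformly placed intervals, possibly overlapping."""
    ivs = []
    names = layout.names
    sizes = np.array([layout.size_of(c) for c in names])
    for i in range(n):
        ci = int(rng.integers(0, len(names)))
        L = int(rng.integers(1, min(max_len, sizes[ci]) + 1))
        s = int(rng.integers(0, sizes[ci] - L + 1))
        if with_meta:
            ivs.append(GenomicInterval(names[ci], s, s + L,
                                       strand=("+", "-", ".")[int(rng.integers(3))],
                                       name=f"iv{i}",
                                       score=float(np.round(rng.uniform(0, 100), 3))))
        else:
            ivs.append(GenomicInterval(names[ci], s, s + L))
    return IntervalSet(ivs, layout)
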