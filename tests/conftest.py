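import numpy as np
import pytest

from ipodhr.tracks import GenomeTrack


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_track():
    """100 kb circular chromosome at 5-bp resolution, unit-normal values."""
    rng = np.random.default_rng(7)
    return GenomeTrack("chrom", 100_000, 5, rng.standard_normal(20_000))


def make_track(values, resolution=5, chrom="chrom", circular=True):
    values = np.asarray(values, dtype=float)
    return GenomeTrack(chrom, len(values) * resolution, resolution, values, circular)
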