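import numpy as np
import pandas as pd
import pytest

from cnaprofiler.synthetic import make_probe_map


@pytest.fixture
def probe_map_100():
    """Single chromosome, 100 probes of 1 kb."""
    return make_probe_map(1, 100, 1000)


@pytest.fixture
def probe_map_2x50():
    """Two chromosomes of 50 probes each."""
    return make_probe_map(2, 50, 1000)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def planted_profile(rng, n=100, sigma=0.1, segments=()):
    """Gaussian-noise profile with (first, last, amplitude) blocks added."""
    v = rng.normal(0.0, sigma, n)
    for first, last, amp in segments:
        v[first : last + 1] += amp
    return v


@pytest.fixture
def tiny_gene_annotation():
    return pd.DataFrame(
        {
            "gene": ["GA", "GB", "GC", "GD"],
            "chromosome": ["1", "1", "1", "2"],
            "start": [500, 10_000, 50_000, 2_000],
            "stop": [1_500, 12_000, 50_050, 3_000],
        }
    )
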