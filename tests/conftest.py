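import numpy as np
import pandas as pd
import pytest

from cnvclim import synthetic


def make_calls(rows):
    """Call table from (sample, chrom, start, end, cn, num_snps) tuples."""
    return pd.DataFrame(rows, columns=["sample", "chrom", "start", "end",
                                       "cn", "num_snps"])


def random_calls(rng, n, n_samples=5, n_chroms=2, span=5000, max_len=800):
    start = rng.integers(1, span, n)
    length = rng.integers(1, max_len, n)
    return make_calls([
        (f"s{rng.integers(n_samples)}", f"chr{rng.integers(1, n_chroms + 1)}",
         int(start[i]), int(start[i] + length[i] - 1),
         int(rng.choice([0, 1, 3, 4])), int(rng.integers(4, 30)))
        for i in range(n)
    ])


@pytest.fixture(scope="session")
def small_config():
    return synthetic.WorldConfig(
        n_sites=12, samples_per_site=10, n_clusters=4, n_cnv_loci=40,
        n_planted=4, effect_size=1.5, seed=3, n_chroms=2,
        chrom_len_bp=4_000_000)


@pytest.fixture(scope="session")
def small_world(small_config):
    return synthetic.generate_world(small_config)


@pytest.fixture(scope="session")
def null_world():
    cfg = synthetic.WorldConfig(
        n_sites=12, samples_per_site=10, n_clusters=4, n_cnv_loci=40,
        n_planted=4, effect_size=0.0, seed=11, n_chroms=2,
        chrom_len_bp=4_000_000)
    return synthetic.generate_world(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)
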