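import numpy as np
import pandas as pd
import pytest

from factorialseq.intervals import as_intervals
from factorialseq.simulate import SimConfig


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)


@pytest.fixture
def small_config():
    return SimConfig(seed=11, n_genes=40, n_peaks=40,
                     chrom_lengths={"chr1": 800_000, "chr2": 600_000})


def random_intervals(rng, n, chroms=("chr1", "chr2"), span=10_000, max_len=400):
    chrom = rng.choice(chroms, size=n)
    start = rng.integers(0, span, size=n)
    length = rng.integers(1, max_len, size=n)
    df = pd.DataFrame({"chrom": chrom, "start": start, "end": start + length})
    df["name"] = [f"iv_{i:05d}" for i in range(n)]
    return as_intervals(df)


@pytest.fixture
def interval_factory():
    return random_intervals
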