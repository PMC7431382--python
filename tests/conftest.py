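import numpy as np
import pandas as pd
import pytest

from miaglia import synthetic as syn
from miaglia import transcriptome as tx


@pytest.fixture(scope="session")
def default_counts():
    """Default synthetic microglia counts (10 groups x 3 replicates)."""
    return syn.generate_counts(seed=20)


@pytest.fixture(scope="session")
def filtered_zscores(default_counts):
    filtered, _ = tx.filter_expressed(default_counts.counts)
    return tx.zscore_rows(tx.log2_cpm(filtered))


@pytest.fixture()
def small_counts():
    """Tiny hand-checkable counts matrix: 4 genes x 4 samples."""
    counts = pd.DataFrame(
        {
            "s1": [10, 0, 5, 985],
            "s2": [20, 0, 10, 1970],
            "s3": [30, 0, 15, 2955],
            "s4": [40, 0, 20, 3940],
        },
        index=["g1", "g2", "g3", "g4"],
    )
    meta = pd.DataFrame(
        {"group": ["A", "A", "B", "B"]}, index=["s1", "s2", "s3", "s4"]
    )
    return tx.CountsMatrix(counts, meta)


@pytest.fixture(scope="session")
def planted_network():
    net, planted = syn.generate_network(50, 8, in_weight=0.9, out_weight=0.1, seed=3)
    return net, planted


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
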