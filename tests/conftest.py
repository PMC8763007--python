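import numpy as np
import pytest

import stromascope as ss


@pytest.fixture(scope="session")
def umi_dataset():
    """A mid-sized simulated UMI dataset shared across read-only tests."""
    cfg = ss.SimConfig(n_cells=1200, n_genes=1400, seed=11)
    return ss.simulate_tme_counts(cfg)


@pytest.fixture(scope="session")
def umi_lognorm(umi_dataset):
    counts, truth, sigs = umi_dataset
    return ss.lognormalize(counts), truth, sigs


@pytest.fixture()
def tiny_counts():
    """4 genes × 3 cells with one mito gene, hand-checkable."""
    vals = np.array(
        [
            [3, 0, 0],   # geneA
            [1, 0, 0],   # MT-1
            [0, 5, 0],   # geneB
            [0, 5, 0],   # geneC
        ]
    )
    return ss.CountMatrix(vals, ["geneA", "MT-1", "geneB", "geneC"],
                          ["c1", "c2", "c3"])
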