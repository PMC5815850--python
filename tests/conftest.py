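import numpy as np
import pytest

import cardiotomo as ct


@pytest.fixture(scope="session")
def toy():
    """Fixed 8-section, 12-gene instance with hand-checkable values."""
    return ct.worked_toy()


@pytest.fixture(scope="session")
def default_heart():
    """One draw of the reference synthetic heart (seed 1)."""
    cfg = ct.default_config(seed=1)
    return ct.generate_heart(cfg), cfg


@pytest.fixture(scope="session")
def default_normalized(default_heart):
    """Spike-in + total-count normalized default heart with its zlfc."""
    (matrix, truth), cfg = default_heart
    endo, spikes = ct.split_spikeins(matrix)
    normed = ct.total_count_normalize(ct.spikein_normalize(endo, spikes))
    zlfc = ct.zscore_rows(normed, log_space=True)
    return endo, spikes, normed, zlfc, truth


def random_count_matrix(rng, n_genes=20, n_sections=6, lam=15.0):
    counts = rng.poisson(lam, size=(n_genes, n_sections)).astype(float)
    # guarantee no all-zero section
    counts[0] += 1
    return ct.CountMatrix(
        gene_ids=[f"g{i:03d}" for i in range(n_genes)],
        section_ids=list(range(1, n_sections + 1)),
        counts=counts,
    )
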