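import numpy as np
import pandas as pd
import pytest

from orgsc import synthetic, qc


@pytest.fixture(scope="session")
def small_truth():
    cfg = synthetic.GeneratorConfig(
        markers_per_group=4, regulons_per_group=2, targets_per_regulon=6,
        mean_library_size=500.0, n_maturation_genes=10)
    return synthetic.generate_truth_model(n_cells=80, n_genes=150,
                                          n_groups=4, config=cfg, seed=11)


@pytest.fixture(scope="session")
def small_counts(small_truth):
    return synthetic.simulate_counts(small_truth, seed=12)


@pytest.fixture(scope="session")
def small_expr(small_counts):
    return qc.normalize(small_counts)


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
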