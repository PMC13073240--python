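import numpy as np
import pytest

import scposition as sp
from scposition.simulate import SimConfig


@pytest.fixture(scope="session")
def small_sim():
    """One small simulated dataset: counts, annotation, truth gene sets."""
    datasets, truth = sp.simulate(
        SimConfig(
            seed=11,
            n_datasets=1,
            cells_per_compartment=60,
            n_genes=300,
            n_signature_per_compartment=10,
        )
    )
    m, ann = datasets[0]
    return m, ann, truth


@pytest.fixture(scope="session")
def small_lognorm(small_sim):
    m, ann, truth = small_sim
    lognorm = sp.log_normalize(sp.qc_filter(m, min_genes=1)[0])
    return lognorm, ann.aligned_to(lognorm.cell_ids), truth


@pytest.fixture(scope="session")
def small_model(small_lognorm):
    """A quick-to-train position model over the small simulation."""
    lognorm, ann, truth = small_lognorm
    geneset, _ = sp.hvg_rank(lognorm, n_top=40)
    cfg = sp.TrainingConfig(seed=11, hidden_sizes=[32], max_epochs=60)
    model = sp.train_position_model(lognorm, ann, geneset, cfg)
    return model


@pytest.fixture
def tiny_counts():
    """2 cells × 3 genes toy counts matrix."""
    return sp.ExpressionMatrix(
        ["c1", "c2"], ["gA", "gB", "gC"], np.array([[4.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
    )
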