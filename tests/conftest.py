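import numpy as np
import pytest

import mutpanel as mp


@pytest.fixture(scope="session")
def small_cohort():
    """Small planted-signature cohort shared by read-only tests."""
    cfg = mp.SimulationConfig(n_samples=150, n_genes=40, planted_genes=6, seed=42)
    return mp.simulate_cohort(cfg)


@pytest.fixture()
def toy_matrix():
    """5-gene, 4-sample matrix with hand-picked entries."""
    import pandas as pd

    df = pd.DataFrame(
        [
            [1, 1, 0, 0, 0],
            [0, 0, 0, 0, 0],
            [1, 1, 1, 1, 1],
            [0, 1, 0, 1, 0],
        ],
        index=pd.Index(["S1", "S2", "S3", "S4"], name="sample_id"),
        columns=["GA", "GB", "GC", "GD", "GE"],
    )
    return mp.BinaryMutationMatrix(df)


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
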