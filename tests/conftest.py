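import numpy as np
import pandas as pd
import pytest

from convergex import SimulationConfig, generate_experiment


def gene_ids(n):
    return [f"G{i:05d}" for i in range(n)]


@pytest.fixture(scope="session")
def small_experiment():
    """A modest seeded experiment shared by read-only tests."""
    cfg = SimulationConfig(n_genes=400, seed=123)
    return generate_experiment(cfg)


@pytest.fixture()
def toy_matrix():
    """Tiny hand-sized matrix: 6 genes x 10 samples, one cell type."""
    rng = np.random.default_rng(0)
    samples = [f"s{i}" for i in range(10)]
    meta = pd.DataFrame(
        {
            "cell_type": ["daoy"] * 10,
            "treatment": ["H2O"] * 5 + ["propranolol"] * 5,
            "buffer": ["H2O"] * 10,
            "plate": ["P1", "P2"] * 5,
        },
        index=pd.Index(samples, name="sample_id"),
    )
    ab = pd.DataFrame(
        rng.integers(20, 200, size=(6, 10)).astype(float),
        index=gene_ids(6),
        columns=samples,
    )
    from convergex import ExperimentMatrix

    return ExperimentMatrix(abundance=ab, sample_meta=meta)
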