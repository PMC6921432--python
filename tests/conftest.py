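import numpy as np
import pandas as pd
import pytest

from sialonet.synthetic_data import SyntheticConfig, generate_all


@pytest.fixture(scope="session")
def small_config() -> SyntheticConfig:
    """Desk-scale study: small but with every planted structure present."""
    return SyntheticConfig(
        n_genes=1200,
        n_samples_per_group=(16, 12),
        n_batches=2,
        batch_shift_sd=0.4,
        n_de_genes=80,
        de_effect=2.0,
        n_pathways=14,
        pathway_size=(10, 20),
        n_active_pathways_per_cluster=4,
        cluster_shift=1.0,
        interactome_attachment=2,
        n_planted_drivers=3,
        driver_fanout=5,
        noise_sd=0.5,
        seed=101,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return generate_all(small_config)


@pytest.fixture()
def two_group_annotation():
    def _make(n_case: int, n_control: int, n_batches: int = 1) -> pd.DataFrame:
        samples = [f"case_{i}" for i in range(n_case)] + [
            f"ctrl_{i}" for i in range(n_control)
        ]
        return pd.DataFrame(
            {
                "sample_id": samples,
                "batch": [f"b{(i % n_batches) + 1}" for i in range(len(samples))],
                "group": ["case"] * n_case + ["control"] * n_control,
            }
        )

    return _make


@pytest.fixture()
def random_matrix():
    def _make(n_genes: int, samples, seed: int = 0, loc: float = 0.0) -> pd.DataFrame:
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            rng.normal(loc, 1.0, size=(n_genes, len(samples))),
            index=[f"g{i:04d}" for i in range(n_genes)],
            columns=samples,
        )

    return _make
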