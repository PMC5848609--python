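import warnings

import numpy as np
import pytest

from chromdyn.simulate import (
    SyntheticConfig,
    plant_truth,
    simulate_annotation,
    simulate_chip_counts,
)

warnings.filterwarnings("ignore", category=UserWarning)


def small_config(**overrides) -> SyntheticConfig:
    """A reduced genome for fast per-module tests (single 10-Mb chromosome)."""
    defaults = dict(
        n_chroms=1,
        chrom_length=10_000_000,
        n_tads=20,
        n_genes=200,
        n_enhancers=300,
        depth_per_sample=8e5,
        seed=0,
    )
    defaults.update(overrides)
    return SyntheticConfig(**defaults)


@pytest.fixture(scope="session")
def small_dataset():
    """One reduced synthetic dataset shared across tests (read-only)."""
    from chromdyn.simulate import simulate_all

    return simulate_all(small_config(seed=3))


@pytest.fixture(scope="session")
def small_chip():
    cfg = small_config(seed=4)
    ann = simulate_annotation(cfg)
    truth = plant_truth(ann, cfg)
    return cfg, ann, truth, simulate_chip_counts(ann, truth, cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
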