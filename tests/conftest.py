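import numpy as np
import pytest

from cernet.synthetic import SimulationConfig, generate_dataset

SMALL_FEATURES = {"lncRNA": 40, "circRNA": 40, "miRNA": 24, "mRNA": 80}


def small_config(seed: int = 0, **overrides) -> SimulationConfig:
    """A fast config that keeps every planted structure class present."""
    base = dict(
        n_features=dict(SMALL_FEATURES),
        n_planted_pairs=4,
        n_planted_triplets=4,
        n_planted_cis_pairs=5,
        n_planted_motifs=2,
        n_motif_lncrnas=2,
        seed=seed,
    )
    base.update(overrides)
    return SimulationConfig(**base)


def null_config(seed: int = 0) -> SimulationConfig:
    """Pure-noise config: no DE, no planted structure of any kind."""
    return SimulationConfig(
        n_features={"lncRNA": 30, "circRNA": 30, "miRNA": 20, "mRNA": 60},
        de_fraction=0.0,
        n_planted_pairs=0,
        n_planted_triplets=0,
        n_planted_cis_pairs=0,
        n_planted_motifs=0,
        n_motif_lncrnas=0,
        seed=seed,
    )


def species_of(feature_id: str) -> str:
    return {
        "LNC": "lncRNA", "CIR": "circRNA", "MIR": "miRNA", "MRN": "mRNA"
    }[feature_id[:3]]


@pytest.fixture(scope="session")
def default_bundle():
    """One default-scale study shared by read-only tests."""
    return generate_dataset(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def small_bundle():
    return generate_dataset(small_config(seed=3))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
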