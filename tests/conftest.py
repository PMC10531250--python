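import numpy as np
import pytest

from hybridgp.bayes import MCMCSettings
from hybridgp.markers import MarkerMatrix
from hybridgp.simulate import SimConfig, simulate_dataset


@pytest.fixture
def tiny_raw_markers() -> MarkerMatrix:
    """4 individuals x 5 SNPs with one missing call and one monomorphic SNP."""
    dos = np.array(
        [
            [0, 2, 0, 2, 1],
            [2, 2, 0, 0, 1],
            [0, 2, 2, 2, 1],
            [2, 2, 0, 0, 1],
        ],
        dtype=float,
    )
    mask = np.zeros_like(dos, dtype=bool)
    mask[2, 2] = True
    return MarkerMatrix(ids=["a", "b", "c", "d"], dosages=dos, missing_mask=mask)


@pytest.fixture(scope="session")
def small_sim():
    """Pocket-sized synthetic trial reused across tests (fixed seed)."""
    cfg = SimConfig(
        n_males=6,
        n_females=24,
        crosses_per_female=2,
        n_markers=120,
        n_years=2,
        seed=42,
    )
    return simulate_dataset(cfg)


@pytest.fixture
def short_mcmc() -> MCMCSettings:
    return MCMCSettings(iterations=400, burn_in=150, thin=2, seed=0)
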