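import numpy as np
import pandas as pd
import pytest

from seragut.synthetic import generate_cohort, generate_metabolome, simulate_scenario


@pytest.fixture(scope="session")
def scenario():
    """The default linked synthetic study (15 subjects, 8/6/1)."""
    return simulate_scenario(seed=1)


@pytest.fixture(scope="session")
def cohort():
    info, truth = generate_cohort(8, 6, 1, seed=1)
    return info, truth


@pytest.fixture(scope="session")
def metabolome(cohort):
    info, truth = cohort
    # fresh truth: do not mutate the shared cohort fixture
    info2, truth2 = generate_cohort(8, 6, 1, seed=1)
    return generate_metabolome(info2, truth2, seed=2)


def block_matrix(rng, n_blocks, block_size, n_noise, n_samples, within_r=0.9):
    """Gaussian planted-block matrix (features x samples) plus noise features."""
    feats = []
    ids = []
    for b in range(n_blocks):
        f = rng.normal(size=n_samples)
        for j in range(block_size):
            feats.append(np.sqrt(within_r) * f + np.sqrt(1 - within_r) * rng.normal(size=n_samples))
            ids.append(f"B{b}_{j}")
    for j in range(n_noise):
        feats.append(rng.normal(size=n_samples))
        ids.append(f"N_{j}")
    return pd.DataFrame(np.array(feats), index=ids)
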