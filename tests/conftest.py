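import numpy as np
import pytest

from spatiomux.synthetic import generate_experiment, generate_sample

UNIT_SQUARE = np.array([(0.0, 0.0), (1.0, 0.0), (1.0, 1.0), (0.0, 1.0)])


@pytest.fixture(scope="session")
def small_sample():
    """Small synthetic sample shared (read-only) across tests."""
    sample, truth = generate_sample(
        n_cells=80, n_genes=30, n_types=3, image_px=256, seed=42
    )
    return sample, truth


@pytest.fixture()
def fresh_sample():
    """Same parameters as small_sample but private to the test (mutable)."""
    return generate_sample(n_cells=80, n_genes=30, n_types=3, image_px=256, seed=42)


@pytest.fixture(scope="session")
def small_experiment():
    exp, truth = generate_experiment(
        n_samples=5, seed=7, n_cells=60, n_genes=30, image_px=256
    )
    return exp, truth
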