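import numpy as np
import pytest

from spectracell.synthetic_cells import SyntheticSpec, generate_arrays


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def tiny_arrays():
    """Small in-memory synthetic dataset: 8 classes × 6 images at 32 px."""
    return generate_arrays(SyntheticSpec(per_class_count=6, image_size=32, seed=3))


@pytest.fixture(scope="session")
def desk_results():
    """The desk-scale experiment pair (spectral model + max-pool ablation).

    Session-scoped because two full trainings are the dominant cost of the
    suite; every test that needs a trained model shares this result.
    """
    from spectracell.experiment import run_desk_experiment

    return {
        "lsbdu": run_desk_experiment(seed=7, per_class=100, image_size=64,
                                     epochs=15, downsampler="lsbdu"),
        "maxpool": run_desk_experiment(seed=7, per_class=100, image_size=64,
                                       epochs=15, downsampler="maxpool"),
    }
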