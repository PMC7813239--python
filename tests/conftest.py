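import numpy as np
import pytest

from refugia import (
    LandscapeConfig,
    PredictorConfig,
    TruthParams,
    generate_landscape,
    true_suitability,
)
from refugia.predictors import build_predictor_stack
from refugia.raster import Grid


@pytest.fixture(scope="session")
def small_landscape():
    """A 30x30-coarse-cell synthetic landscape shared across tests."""
    config = LandscapeConfig(shape=(30, 30), seed=11)
    fine = generate_landscape(config)
    return config, fine


@pytest.fixture(scope="session")
def small_stack(small_landscape):
    _, fine = small_landscape
    return build_predictor_stack(fine, fine.coarse, PredictorConfig())


@pytest.fixture(scope="session")
def small_truth(small_stack):
    return true_suitability(small_stack, TruthParams())


@pytest.fixture()
def flat_grid():
    def make(values, cell_size=1000.0, mask=None):
        values = np.asarray(values, dtype=float)
        return Grid(values, mask, cell_size, (0.0, 0.0))

    return make
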