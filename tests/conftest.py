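import numpy as np
import pytest

from sdmnet import (
    ActivationModel,
    BehaviorModel,
    CorrelationBlock,
    PlantedHub,
    generate_activation,
    generate_dyads,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_dyads():
    """Five dyads per sex from the default behavior model."""
    model = BehaviorModel(seed=11)
    return generate_dyads(model, 5)


@pytest.fixture(scope="session")
def blocked_activation():
    """Activation table with a planted positive block and a planted hub."""
    model = ActivationModel(
        blocks=[CorrelationBlock(("Vs", "Hv", "TPp"), 0.9)],
        hubs=[PlantedHub("PM", ("Dm", "Dl", "Vc", "PPp"), 0.85)],
        seed=7,
    )
    return generate_activation(model)
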