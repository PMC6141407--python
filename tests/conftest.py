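import dataclasses

import numpy as np
import pytest

from resusim.plant import PlantParams
from resusim.protocol import ProtocolConfig


@pytest.fixture
def noiseless_params() -> PlantParams:
    return PlantParams(noise_sd=0.0)


@pytest.fixture
def short_config() -> ProtocolConfig:
    """Abbreviated timeline for fast closed-loop tests (shallower shock)."""
    return ProtocolConfig(
        ramp_duration=180.0, clamp_duration=120.0, resus_duration=600.0
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def with_params(params: PlantParams, **kw) -> PlantParams:
    return dataclasses.replace(params, **kw)
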