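import numpy as np
import pytest
from hypothesis import settings

from costimod import ModelParameters, VariantSpec
from costimod.inference import rank_variants

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def params() -> ModelParameters:
    return ModelParameters()


@pytest.fixture(scope="session")
def spec() -> VariantSpec:
    return VariantSpec()


@pytest.fixture(scope="session")
def scorecard(params):
    """Full variant scorecard with per-variant strength refits (computed once;
    deterministic)."""
    return rank_variants(params)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
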