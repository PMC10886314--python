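import numpy as np
import pytest

from sonotriage import PhantomSpec, generate_dataset


def small_spec(image_size: int = 96, **overrides) -> PhantomSpec:
    """A phantom spec scaled down for fast tests (geometry ∝ image size)."""
    kwargs = dict(
        image_size=image_size,
        vessel_radius_range=(5.0, 9.0),
        bundle_spread=16.0,
        shrapnel_distance_range=(1.0, 25.0),
    )
    kwargs.update(overrides)
    return PhantomSpec(**kwargs)


@pytest.fixture(scope="session")
def spec96() -> PhantomSpec:
    return small_spec()


@pytest.fixture(scope="session")
def dataset96(spec96):
    """Twenty 96x96 phantom samples with annotations, shared across tests."""
    return generate_dataset(spec96, 20, seed=11)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
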