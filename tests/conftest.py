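import numpy as np
import pytest

from sadhm import OpticalConfig, SamplingRanges


@pytest.fixture(scope="session")
def tiny_config() -> OpticalConfig:
    """16x-reduced geometry (140 px grid, 14 px mask) for fast unit tests."""
    return OpticalConfig.scaled(factor=16)


@pytest.fixture(scope="session")
def small_config() -> OpticalConfig:
    """8x-reduced geometry (280 px grid, 28 px mask)."""
    return OpticalConfig.scaled(factor=8)


@pytest.fixture(scope="session")
def scaled_config() -> OpticalConfig:
    """The 4x-reduced preset (560 px grid, 56 px mask) used by the heavier
    pipeline tests; preserves all dimensionless ratios of the full layout."""
    return OpticalConfig.scaled(factor=4)


@pytest.fixture(scope="session")
def scaled_ranges() -> SamplingRanges:
    return SamplingRanges.scaled(factor=4)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
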