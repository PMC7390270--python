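import numpy as np
import pytest

from thrombosim.channel import ChannelGeometry
from thrombosim.generation import GenerationParams
from thrombosim.wave import WaveParams


@pytest.fixture(scope="session")
def gen_params() -> GenerationParams:
    """Packaged thrombin-generation constants (platelet count 350e9/L)."""
    return GenerationParams.from_parameters("table1")


@pytest.fixture(scope="session")
def wave_prp() -> WaveParams:
    """Reduced-wave constants for platelet-rich plasma (phi0 = 300e9/L)."""
    return WaveParams.from_parameters("table2-wave")


@pytest.fixture(scope="session")
def wave_npp(wave_prp) -> WaveParams:
    import dataclasses
    return dataclasses.replace(wave_prp, phi0=0.0)


@pytest.fixture(scope="session")
def bistable_wave(wave_prp) -> WaveParams:
    """A genuinely bistable configuration: no constant production source
    (phi0 = 0, B0 = 0) and a sink strong enough to stabilize T = 0."""
    import dataclasses
    return dataclasses.replace(wave_prp, phi0=0.0, B0=0.0, gamma=5.0)


@pytest.fixture(scope="session")
def small_geometry() -> ChannelGeometry:
    """Short desk-scale channel for transport tests."""
    return ChannelGeometry(L=2.0, H=1.0, patch_start=0.6, patch_width=0.2, h=0.04)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260923)
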