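import numpy as np
import pytest

from wormcars import render_worm, strain_preset
from wormcars.presets import StrainProfile


@pytest.fixture(scope="session")
def n2_profile() -> StrainProfile:
    return strain_preset("N2")


@pytest.fixture(scope="session")
def noiseless_n2(n2_profile) -> StrainProfile:
    from dataclasses import replace
    return replace(n2_profile, noise_cv=0.0)


@pytest.fixture(scope="session")
def n2_render(n2_profile):
    """One noisy wild-type render shared by read-only tests."""
    return render_worm(n2_profile, seed=42)


@pytest.fixture(scope="session")
def noiseless_render(noiseless_n2):
    """One noiseless wild-type render shared by exact-recovery tests."""
    return render_worm(noiseless_n2, seed=42)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
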