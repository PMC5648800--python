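import pytest

from starkit import DesignConfig, EnergyModel, design_library, toy_scaffold


@pytest.fixture(scope="session")
def model():
    return EnergyModel()


@pytest.fixture(scope="session")
def scaffold():
    """Toy terminator scaffold: 8-bp GC stem, 4-nt inert loop, U8 tract."""
    return toy_scaffold(stem_len=8, loop_len=4, u_len=8, seed=0)


@pytest.fixture(scope="session")
def small_cfg():
    """22-nt linear regions give a 30-nt recognition region on the toy stem."""
    return DesignConfig(linear_len=22, seed=1)


@pytest.fixture(scope="session")
def small_library(scaffold, model, small_cfg):
    return design_library(3, scaffold, model, small_cfg)
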