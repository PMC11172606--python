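import numpy as np
import pytest

from pacsab import (SimulationConfig, build_pacsab_model, make_polypeptide,
                    preset, replicate_with_offset)


@pytest.fixture(scope="session")
def default_params():
    return preset("default")


@pytest.fixture(scope="session")
def helix10():
    """10-residue ideal poly-Ala helix."""
    return make_polypeptide("A" * 10, "helix")


@pytest.fixture(scope="session")
def helix4_model():
    """The canonical 24-particle fixture: 4-residue poly-Ala helix."""
    return build_pacsab_model(make_polypeptide("AAAA", "helix"))


@pytest.fixture(scope="session")
def boxed_helix4(helix4_model):
    return helix4_model.with_box(60.0)


@pytest.fixture(scope="session")
def small_coil_model():
    """A 3-residue mixed coil, the smallest system exercising every term."""
    return build_pacsab_model(make_polypeptide("AKV", "coil", seed=3)).with_box(100.0)


@pytest.fixture(scope="session")
def two_copy_system(helix4_model):
    return replicate_with_offset(helix4_model, offset=(30.0, 0.0, 0.0), L=60.0)


def quick_config(**kw):
    kw.setdefault("tf_ps", 10.0)
    kw.setdefault("n_frames", 2)
    kw.setdefault("dt_ps", 0.01)
    kw.setdefault("seed", 1)
    return SimulationConfig(**kw)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
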