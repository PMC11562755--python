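import numpy as np
import pytest

from drgstereo import GanglionConfig, SubpopulationSpec, generate_ganglion


def default_subpops():
    return (
        SubpopulationSpec("mrgprd", 0.15, 361.0, 138.0, markers=frozenset({"mrgprd"})),
        SubpopulationSpec("cgrp", 0.481, 380.0, 150.0, markers=frozenset({"cgrp"})),
        SubpopulationSpec("trpm8", 0.083, 300.0, 110.0, markers=frozenset({"trpm8"})),
        SubpopulationSpec("thy1", 0.156, 700.0, 250.0, markers=frozenset({"thy1"})),
        SubpopulationSpec("other", 0.13, 450.0, 200.0),
    )


@pytest.fixture(scope="session")
def subpops():
    return default_subpops()


@pytest.fixture(scope="session")
def small_config(subpops):
    return GanglionConfig(n=500, subpopulations=subpops)


@pytest.fixture(scope="session")
def small_ganglion(small_config):
    return generate_ganglion(small_config, seed=7)


@pytest.fixture(scope="session")
def full_config(subpops):
    return GanglionConfig(n=8000, subpopulations=subpops)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
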