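import numpy as np
import pytest

from vocalid import (PopulationSpec, make_population, synth_call_batch,
                     sample_features_direct, gaussian_null_table)


@pytest.fixture(scope="session")
def hind_spec():
    return PopulationSpec("hind")


@pytest.fixture(scope="session")
def calf_spec():
    return PopulationSpec("calf")


@pytest.fixture(scope="session")
def hind_calls(hind_spec):
    """Small batch of synthesized hind oral calls (shared: synthesis is the
    slow part of the suite)."""
    profiles = make_population(hind_spec, 6, seed=101)
    return synth_call_batch(hind_spec, profiles, ("oral",), 3, seed=202)


@pytest.fixture(scope="session")
def calf_calls(calf_spec):
    profiles = make_population(calf_spec, 6, seed=103)
    return synth_call_batch(calf_spec, profiles, ("oral",), 3, seed=204)


@pytest.fixture(scope="session")
def signal_table(hind_spec):
    """Feature table with strong individuality: 22 hinds x 10 oral calls."""
    from dataclasses import replace
    spec = replace(hind_spec, icc=0.8)
    profiles = make_population(spec, 22, seed=7)
    return sample_features_direct(spec, profiles, 10, seed=8,
                                  call_types=("oral",))


@pytest.fixture(scope="session")
def null_table():
    """No-signal Gaussian table: 5 groups of 10, 6 variables."""
    return gaussian_null_table([10] * 5, 6, seed=42)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
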