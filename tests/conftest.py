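"""Shared fixtures: one small simulated experiment reused across tests."""

import pytest

from psiseq import simdata as sd


@pytest.fixture(scope="session")
def small_config():
    return sd.SimConfig(seed=42, depth=5000)


@pytest.fixture(scope="session")
def reference(small_config):
    return sd.build_reference(small_config)


@pytest.fixture(scope="session")
def pool(small_config, reference):
    ref, truth = reference
    return sd.simulate_pool(ref, truth, small_config)
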