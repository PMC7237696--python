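import numpy as np
import pytest

from mutload import TrioSimConfig, generate_reference, simulate_trio


@pytest.fixture(scope="session")
def ref100k():
    return generate_reference(100_000, 0.41, seed=1)


@pytest.fixture(scope="session")
def ref300k():
    return generate_reference(300_000, 0.41, seed=2)


def trio_config(**overrides):
    base = dict(
        n_germline=100,
        n_culture=50,
        n_subclonal=30,
        n_artifact_positions=5,
        n_pre_clonal=20,
        n_germline_indels=20,
        n_culture_indels=10,
        seed=7,
    )
    base.update(overrides)
    return TrioSimConfig(**base)


@pytest.fixture(scope="session")
def trio_exact(ref100k):
    """Noise-free trio: fixed depth, rounded alt counts (true VAFs exact)."""
    return simulate_trio(ref100k, trio_config(exact_vafs=True))


@pytest.fixture(scope="session")
def trio_noisy(ref100k):
    """Binomial sampling noise at 30x depth."""
    return simulate_trio(ref100k, trio_config(exact_vafs=False))
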