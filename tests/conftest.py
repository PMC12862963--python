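import numpy as np
import pytest

from titinkit import ScoringScheme
from titinkit.references import medtkb_annotation
from titinkit.synth import SimConfig, simulate_families


@pytest.fixture(scope="session")
def scheme():
    return ScoringScheme()


@pytest.fixture(scope="session")
def medtkb_ref():
    return medtkb_annotation()


@pytest.fixture(scope="session")
def small_family():
    """A small five-group family with truth labels (seed-fixed)."""
    cfg = SimConfig(seed=7, n_per_group=6)
    sset, truth = simulate_families(cfg)
    return sset, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
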