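import numpy as np
import pytest

import mosaicqtl as mq


@pytest.fixture(scope="session")
def small_map():
    """3 chromosomes x 60 cM x 60 markers — fast unit-test genome."""
    return mq.default_map(n_chrom=3, chrom_length_cm=60.0, n_markers_per_chrom=60)


@pytest.fixture(scope="session")
def small_probs(small_map):
    mosaics = mq.simulate_mosaics(small_map, 80, seed=11)
    return mq.mosaics_to_probs(mosaics, small_map)


@pytest.fixture(scope="session")
def small_kinship(small_probs):
    return mq.calc_kinship(small_probs, mode="loco")


@pytest.fixture(scope="session")
def desk_map():
    """Default desk-scale genome (5 x 100 cM x 200 markers)."""
    return mq.default_map()


@pytest.fixture(scope="session")
def desk_dataset(desk_map):
    """Full study-condition simulation (n=186, 127 shared donors)."""
    return mq.simulate_dataset(desk_map, seed=2024)


@pytest.fixture()
def rng():
    """Fresh deterministic generator per test: results never depend on test order."""
    return np.random.default_rng(1234)
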