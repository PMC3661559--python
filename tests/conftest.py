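import numpy as np
import pytest

from intromir.pipeline import run_discovery
from intromir.synthetic_data import SyntheticConfig, build_dataset

CLEAN_SEED = 11


@pytest.fixture(scope="session")
def clean_dataset():
    """The clean synthetic study: 20 genes, 10 planted precursors across
    UMP/MMP/cluster classes, 5 siRNA decoys, duplex read ratio 0.8."""
    return build_dataset(SyntheticConfig(seed=CLEAN_SEED))


@pytest.fixture(scope="session")
def discovery(clean_dataset):
    ds = clean_dataset
    return run_discovery(ds.genome, ds.models, ds.libraries)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def random_rna(rng, n):
    return "".join(np.array(list("ACGU"))[rng.integers(0, 4, size=n)])


def random_dna(rng, n):
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=n)])
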