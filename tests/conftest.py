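import numpy as np
import pytest

from miredit.align import MatureMiRNA
from miredit.simulate import DEFAULT_REFERENCE, default_truth, simulate_bundle


@pytest.fixture(scope="session")
def reference_panel():
    return [MatureMiRNA(mid, seq) for mid, seq in DEFAULT_REFERENCE]


@pytest.fixture(scope="session")
def truth():
    return default_truth(seed=7)


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory):
    """A small but complete synthetic cohort shared by integration tests."""
    outdir = tmp_path_factory.mktemp("bundle")
    return simulate_bundle(
        outdir,
        seed=11,
        n_tumour=10,
        n_control=8,
        reads_per_sample=600,
        n_genes=150,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
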