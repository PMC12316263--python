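import numpy as np
import pytest

from scanqc.bids_index import ScanIdentifier
from scanqc.synth_fixtures import PhantomSpec


@pytest.fixture
def small_spec():
    return PhantomSpec(shape=(24, 24, 24), n_shells=3, noise_sd=0.0, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(20260101)


def make_ident(i: int, dataset: str = "demo", pipeline: str = "tensor") -> ScanIdentifier:
    return ScanIdentifier(dataset=dataset, subject=f"sub-{i:03d}",
                          session="ses-01", pipeline=pipeline)


@pytest.fixture
def identifiers():
    return [make_ident(i) for i in range(10)]
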