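import numpy as np
import pytest
from hypothesis import settings

from mirqc import pipeline, simulate
from mirqc.trimming import get_preset

settings.register_profile("deterministic", derandomize=True, deadline=None, database=None)
settings.load_profile("deterministic")

REFERENCE_SEED = 101


@pytest.fixture(scope="session")
def references():
    return simulate.generate_references(REFERENCE_SEED)


@pytest.fixture(scope="session")
def indexes(references):
    return pipeline.build_indexes(references.as_reference_sets())


@pytest.fixture(scope="session")
def illumina_preset():
    return get_preset("Illumina")


@pytest.fixture()
def rng():
    return np.random.default_rng(20240915)


def random_seq(rng, length):
    return "".join(rng.choice(list("ACGT"), size=length))
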