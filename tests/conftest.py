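import numpy as np
import pytest

from chemobarcode.signatures import fixture_signatures


@pytest.fixture(scope="session")
def hsc_profile():
    return fixture_signatures("hsc_like", seed=0)


@pytest.fixture(scope="session")
def platinum_profile():
    return fixture_signatures("platinum_like", seed=0)


@pytest.fixture(scope="session")
def fivefu_profile():
    return fixture_signatures("fivefu_like", seed=0)


@pytest.fixture(scope="session")
def flat_profile():
    return fixture_signatures("flat")


@pytest.fixture(scope="session")
def toy_genome():
    """Synthetic single-chromosome reference as a plain mapping."""
    rng = np.random.default_rng(1234)
    seq = "".join(rng.choice(list("ACGT"), size=20_000))
    return {"chr1": seq}
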