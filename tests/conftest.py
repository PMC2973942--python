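import pytest

from mitokit import datasets
from mitokit.synthetic import generate, roscoffensis_like


@pytest.fixture(scope="session")
def table1():
    """The S. roscoffensis annotation fixture (coordinates only)."""
    return datasets.load_roscoffensis()


@pytest.fixture(scope="session")
def synthetic_genome():
    """The default study-condition genome plus its ground-truth record."""
    return generate(roscoffensis_like(seed=1))
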