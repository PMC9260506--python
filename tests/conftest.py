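import pytest

from mimoseq.datasets import load_public_clone_table, public_clonotypes
from mimoseq.repertoire import default_scheme
from mimoseq.synthetic import generate_germline_reference


@pytest.fixture(scope="session")
def reference():
    return generate_germline_reference(4, seed=1)


@pytest.fixture(scope="session")
def scheme():
    return default_scheme()


@pytest.fixture(scope="session")
def clone_table():
    return load_public_clone_table()


@pytest.fixture(scope="session")
def public_lineages():
    return public_clonotypes()
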