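import pytest

from rhdamp import make_synthetic_references


@pytest.fixture(scope="session")
def refs_and_model():
    return make_synthetic_references(seed=0)


@pytest.fixture(scope="session")
def refs(refs_and_model):
    return refs_and_model[0]


@pytest.fixture(scope="session")
def model(refs_and_model):
    return refs_and_model[1]


@pytest.fixture(scope="session")
def roles(refs):
    from rhdamp.reference_model import infer_roles

    return infer_roles(refs)
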