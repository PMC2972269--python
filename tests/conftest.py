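import pytest

from rootscn import build_meta_grn, build_scn_model
from rootscn.models import reference_profiles


@pytest.fixture(scope="session")
def model_a():
    return build_scn_model("A")


@pytest.fixture(scope="session")
def model_b_prime():
    return build_scn_model("B_prime")


@pytest.fixture(scope="session")
def profiles_a():
    return reference_profiles("A")


@pytest.fixture(scope="session")
def profiles_b():
    return reference_profiles("B_prime")


@pytest.fixture(scope="session")
def meta_grn():
    return build_meta_grn()
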