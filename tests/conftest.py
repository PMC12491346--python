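from pathlib import Path

import pytest

from fetcea import load_model_spec, packaged_model_path, study_fixture

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def model1_spec():
    return load_model_spec(packaged_model_path("model1"))


@pytest.fixture(scope="session")
def model2_spec():
    return load_model_spec(packaged_model_path("model2"))


@pytest.fixture(scope="session")
def model1_fixture():
    return study_fixture("model1")


@pytest.fixture(scope="session")
def model2_fixture():
    return study_fixture("model2")
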