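import pytest

from sparsepk.datasets import load_study


@pytest.fixture(scope="session")
def study_profiles():
    """The bundled six-rat study with doses attached."""
    return load_study()


@pytest.fixture(scope="session")
def profile_by_id(study_profiles):
    return {p.subject_id: p for p in study_profiles}
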