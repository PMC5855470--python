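import pytest

from odormix.synthetic import StudyConfig, build_compound_library, generate_study


@pytest.fixture(scope="session")
def library():
    return build_compound_library()


@pytest.fixture(scope="session")
def small_study(library):
    """A reduced two-phase study for fast unit tests."""
    cfg = StudyConfig(n_train=60, n_test=24)
    return generate_study(cfg, seed=11, library=library)
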