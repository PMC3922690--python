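import pytest

from epicode import make_planted_matrix, make_toy_alignments


@pytest.fixture(scope="session")
def planted():
    """Planted benchmark at the standard study size (n=200, m=8, c=3)."""
    return make_planted_matrix(200, 8, 3, noise_sd=0.05, seed=1)


@pytest.fixture(scope="session")
def planted_clean():
    return make_planted_matrix(200, 8, 3, noise_sd=0.0, seed=1)


@pytest.fixture(scope="session")
def toy_absolute(tmp_path_factory):
    return make_toy_alignments("absolute", tmp_path_factory.mktemp("abs"), seed=0)


@pytest.fixture(scope="session")
def toy_differential(tmp_path_factory):
    return make_toy_alignments("differential", tmp_path_factory.mktemp("diff"), seed=0)


@pytest.fixture(scope="session")
def toy_broadened(tmp_path_factory):
    return make_toy_alignments("broadened_peak", tmp_path_factory.mktemp("bp"), seed=0)
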