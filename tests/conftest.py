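import pytest

from ppisite.synthetic import SyntheticSpec, generate, worked_toy


@pytest.fixture(scope="session")
def toy(tmp_path_factory):
    """The fixed 3-chain fixture (lengths 12, 19, 40)."""
    return worked_toy(tmp_path_factory.mktemp("toy"))


@pytest.fixture(scope="session")
def small_manifest(tmp_path_factory):
    """A small planted-signal dataset for mid-weight tests."""
    spec = SyntheticSpec(n_proteins=12, length_range=(30, 60), seed=7)
    return generate(spec, tmp_path_factory.mktemp("small"))
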