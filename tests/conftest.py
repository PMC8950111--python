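import pytest

from phagetup.genome_model import m13ke_fixture
from phagetup.synthetic import generate_genomes


@pytest.fixture(scope="session")
def m13ke():
    return m13ke_fixture()


@pytest.fixture(scope="session")
def genome_pair():
    """Synthetic reference/mutant pair with the fixture deletion."""
    return generate_genomes(seed=11)
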