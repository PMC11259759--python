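import numpy as np
import pytest

from polyreact.embed import MockEmbedder
from polyreact.featurize import EncodingConfig
from polyreact.numbering import extract_variable_domains
from polyreact.synthetic import GeneratorSpec, generate_panel, simulate_assay


@pytest.fixture(scope="session")
def small_spec():
    return GeneratorSpec(n_antibodies=60, seed=42)


@pytest.fixture(scope="session")
def small_panel(small_spec):
    """A 60-antibody panel covering every supported format."""
    records, truths = generate_panel(small_spec)
    return records, truths


@pytest.fixture(scope="session")
def assay_points(small_panel, small_spec):
    records, truths = small_panel
    return simulate_assay(records, truths, small_spec)


@pytest.fixture(scope="session")
def domain_sets(small_panel):
    records, _ = small_panel
    return {r.id: extract_variable_domains(r) for r in records}


@pytest.fixture(scope="session")
def mock_embedder():
    return MockEmbedder(feature_dim=32, special_tokens_per_domain=2)


@pytest.fixture(scope="session")
def encoding():
    return EncodingConfig()


@pytest.fixture
def rng():
    return np.random.default_rng(0)
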