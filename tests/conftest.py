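import pytest

from mammokg.fusion import default_lexicon
from mammokg.schema import default_schema
from mammokg.synthetic import GeneratorConfig, generate_corpus


@pytest.fixture(scope="session")
def schema():
    return default_schema()


@pytest.fixture(scope="session")
def lexicon():
    return default_lexicon()


@pytest.fixture(scope="session")
def small_bundle():
    """Default-condition corpus for structural and round-trip checks."""
    return generate_corpus(GeneratorConfig(n_reports=120, seed=11))


@pytest.fixture(scope="session")
def clean_bundle():
    """Canonical-surface corpus (variant_rate 0): fusion's exact oracle."""
    return generate_corpus(GeneratorConfig(n_reports=200, seed=13, variant_rate=0.0))


@pytest.fixture(scope="session")
def bundle1000():
    """Association-scale corpus for the conditional-probability checks."""
    return generate_corpus(GeneratorConfig(n_reports=1000, seed=5))
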