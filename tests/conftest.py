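import numpy as np
import pytest

from bicodon_bias import (
    GeneratorConfig,
    enumerate_bicodons,
    generate_proteome,
)
from bicodon_bias.synthetic import uniform_profile


@pytest.fixture(scope="session")
def index():
    return enumerate_bicodons()


@pytest.fixture(scope="session")
def null_proteome():
    """Proteome with identical codon processes in both expression classes."""
    config = GeneratorConfig(
        n_genes=800,
        seed=20260930,
        codon_profile_low=uniform_profile(),
        codon_profile_high=uniform_profile(),
    )
    return generate_proteome(config)


@pytest.fixture(scope="session")
def default_proteome():
    """Proteome with the default (class-dependent) codon profiles."""
    return generate_proteome(GeneratorConfig(n_genes=1000, seed=42))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
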