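import numpy as np
import pytest

from waspfam.pipeline import build_profile_set
from waspfam.simulate import DomainLibrary, GeneratorConfig, generate_proteome

AA = "ACDEFGHIKLMNPQRSTVWY"


@pytest.fixture(scope="session")
def library():
    return DomainLibrary()


@pytest.fixture(scope="session")
def profiles():
    return build_profile_set()


@pytest.fixture(scope="session")
def small_proteome():
    """30 proteins, noise-free, spanning many architectures."""
    cfg = GeneratorConfig(seed=11, n_proteins=30, n_species=5)
    return generate_proteome(cfg)


def random_protein(rng, n):
    return "".join(rng.choice(list(AA), size=n))
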