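import numpy as np
import pytest

from orbopt import make_fixture, roothaan_reference
from orbopt.hf import scf_oracle


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def reference_cache():
    """Tightly converged Roothaan references, computed once per session."""
    cache = {}

    def get(name):
        if name not in cache:
            fix = make_fixture(name)
            energy, orbitals, eps = roothaan_reference(fix)
            cache[name] = (fix, energy, orbitals, eps)
        return cache[name]

    return get


@pytest.fixture(scope="session")
def converged_oracle(reference_cache):
    """Factory: SCF oracle anchored at the converged reference orbitals."""

    def make(name):
        fix, energy, orbitals, _ = reference_cache(name)
        return scf_oracle(fix, orbitals), energy

    return make
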