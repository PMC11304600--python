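import numpy as np
import pytest

from sweetsim import GenomeSpec, Population


def make_hwe_population(spec, n, rng, freq=None, pool=None):
    """Random Hardy-Weinberg population over a spec (test helper)."""
    if freq is None:
        freq = rng.uniform(0.1, 0.9, size=spec.n_sites)
    haplo = (rng.random((n, 2, spec.n_sites)) < freq).astype(np.uint8)
    return Population(spec, haplo, ids=np.arange(n), pool=pool)


@pytest.fixture(scope="session")
def small_spec():
    return GenomeSpec.create(np.random.default_rng(11), n_chromosomes=2,
                             qtn_per_chr=20, snp_per_chr=50)


@pytest.fixture(scope="session")
def small_founders(small_spec):
    rng = np.random.default_rng(42)
    return make_hwe_population(small_spec, 40, rng)


@pytest.fixture()
def rng():
    return np.random.default_rng(202406)
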