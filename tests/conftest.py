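import numpy as np
import pytest

from nullkit.fixtures import synth_annotation, synth_genome, synth_vcf


@pytest.fixture(scope="session")
def toy_genome():
    return synth_genome(20000, gc=0.45, n_runs=((0.4, 50),), seed=1)


@pytest.fixture(scope="session")
def toy_models(toy_genome):
    return synth_annotation(toy_genome, 3, seed=2)


@pytest.fixture(scope="session")
def toy_variants(toy_genome):
    return synth_vcf(toy_genome, 30, seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def _random_dna(rng, length, n_fraction=0.0):
    if n_fraction > 0:
        p = [(1 - n_fraction) / 4] * 4 + [n_fraction]
        return "".join(rng.choice(list("ACGTN"), p=p, size=length))
    return "".join(rng.choice(list("ACGT"), size=length))


@pytest.fixture()
def random_dna():
    """Factory fixture: random_dna(rng, length, n_fraction=0)."""
    return _random_dna
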