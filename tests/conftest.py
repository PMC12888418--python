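import numpy as np
import pytest

from asbkit.io import Motif
from asbkit.simulate import FixtureSpec, generate_fixture


@pytest.fixture(scope="session")
def default_bundle():
    """The default planted fixture used by end-to-end tests."""
    return generate_fixture(FixtureSpec(seed=11), make_reads=False)


@pytest.fixture(scope="session")
def discovery_bundle():
    """Dense-motif fixture tuned for k-mer discovery tests."""
    spec = FixtureSpec(
        genome_len=60_000, n_snps=20, n_planted_asb=10, n_extra_motif_sites=200, seed=1
    )
    return generate_fixture(spec, make_reads=True)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def random_motif(rng, length=8, concentration=0.5, name="m"):
    return Motif(name=name, matrix=rng.dirichlet(np.full(4, concentration), size=length))


def one_hot_motif(consensus, name="onehot", p_major=1.0, tf=None, source="JASPAR"):
    """Motif with probability ``p_major`` on the consensus base per column."""
    p_minor = (1.0 - p_major) / 3.0
    m = np.full((len(consensus), 4), p_minor)
    for i, b in enumerate(consensus):
        m[i, "ACGT".index(b)] = p_major
    return Motif(name=name, matrix=m, tf=tf, source=source)
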