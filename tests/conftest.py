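import numpy as np
import pytest

from endofootprint.genome import AnnotatedGenome, GeneFeature
from endofootprint.simulate import SimConfig, simulate_genomes

ZERO_TREE = "((Z1:0.0,Z3:0.0):0.0,(B:0.0,Q:0.0):0.0);"


@pytest.fixture(scope="session")
def quartet():
    """Default synthetic quartet: two sister pairs with planted elements."""
    return simulate_genomes(SimConfig(seed=7))


@pytest.fixture(scope="session")
def quartet_zero():
    """Zero-mutation quartet: all four genomes identical up to labels."""
    return simulate_genomes(SimConfig(seed=7, tree=ZERO_TREE))


def make_genome(seq, genes, gid="toy", topology="circular"):
    return AnnotatedGenome(id=gid, sequence=seq, genes=genes, topology=topology)


def make_gene(gid, start, end, strand="+", kind="CDS", **kw):
    return GeneFeature(id=gid, start=start, end=end, strand=strand, kind=kind, **kw)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
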