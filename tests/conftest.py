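import numpy as np
import pytest

from clustercoherence.genome import GeneFamily, GenomeAnnotation


def make_annotation(n: int, chromosomes: int = 1, pitch: int = 2000, length: int = 1500):
    """Evenly spaced genes g000..g(n-1) split across chromosomes."""
    per = n // chromosomes
    genes = []
    for i in range(n):
        c, pos = divmod(i, per)
        genes.append(
            (f"g{i:03d}", f"chr{c + 1}", pos * pitch, pos * pitch + length, "+")
        )
    return GenomeAnnotation(genes)


@pytest.fixture
def annotation10():
    """Ten genes on one chromosome, ranks 0..9."""
    return make_annotation(10)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def family(name, *members):
    return GeneFamily(name=name, members=frozenset(members))
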