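import numpy as np
import pytest

from regionks.pswm import PSWM, build_pswm, pswm_from_consensus
from regionks.regions import Gene


@pytest.fixture
def uniform_bg():
    return (0.25, 0.25, 0.25, 0.25)


@pytest.fixture
def toy_pswm():
    """Width-4 matrix built from a small alignment; consensus ACGT."""
    return build_pswm(["ACGT", "ACGT", "ACGA", "TCGT"], pseudocount=1.0)


@pytest.fixture
def consensus_pswm():
    return pswm_from_consensus("TTGACA", 0.9, name="m35")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_dna(rng, length):
    return "".join(rng.choice(list("ACGT"), size=length))


@pytest.fixture
def toy_genes():
    """5 genes on one chromosome, strands + + - + -, fixed coordinates.

    Gaps: [100,150) other (upstream of gene 2), [250,300) convergent
    (+ then -), [400,450) other (upstream of gene 4, downstream of
    gene 3 on -), [550,600) convergent.
    """
    coords = [(0, 100), (150, 250), (300, 400), (450, 550), (600, 700)]
    strands = "++-+-"
    return [
        Gene(gene_id=f"g{i}", chrom="chr", start=s, end=e, strand=st)
        for i, ((s, e), st) in enumerate(zip(coords, strands))
    ]
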