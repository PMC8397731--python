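import numpy as np
import pytest

from sedipan.formats import GenomeEntry, SequenceRecord

AA = "ACDEFGHIKLMNPQRSTVWY"


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def random_protein(rng, length, seq_id="p", genome_id="g"):
    residues = "".join(np.random.default_rng(rng.integers(2**31)).choice(list(AA), length))
    return SequenceRecord(seq_id, residues, genome_id=genome_id)


@pytest.fixture
def tiny_taxonomy():
    """Minimal taxonomy with all four AOA orders, three NP subclades and
    one outgroup genome."""
    return [
        GenomeEntry("nc1", "NC"),
        GenomeEntry("ns1", "NS"),
        GenomeEntry("nt1", "NT"),
        GenomeEntry("np_t1", "NP", subclade="theta"),
        GenomeEntry("np_d1", "NP", subclade="delta"),
        GenomeEntry("np_i1", "NP", subclade="iota"),
        GenomeEntry("out1", "OUTGROUP"),
    ]
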