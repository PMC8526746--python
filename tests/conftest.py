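import numpy as np
import pytest
from hypothesis import settings

from synspot.synthetic_data import ntrb_like_cds

settings.register_profile("repro", derandomize=True)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def ntrb_cds():
    """Synthetic 363-codon CDS carrying the worked-example codon features
    (Thr at residue 97 with A as nt 289, LVRGL at residues 136-140, A at
    nt 683, degenerate third positions in codons 92-102)."""
    return ntrb_like_cds()


@pytest.fixture
def rng():
    return np.random.default_rng(20211019)
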