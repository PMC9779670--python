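import pytest

from silkarch.core_io import Alphabet, Sequence


@pytest.fixture
def protein():
    def make(residues, seq_id="p"):
        return Sequence(seq_id, residues, Alphabet.PROTEIN)
    return make


@pytest.fixture
def dna():
    def make(residues, seq_id="d"):
        return Sequence(seq_id, residues, Alphabet.DNA)
    return make
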