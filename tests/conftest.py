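import pytest

from swfscreen.seq import NucSequence, ProteinSequence, write_fasta


@pytest.fixture
def fasta_writer(tmp_path):
    """Write sequences to a temp FASTA file and return its path."""

    def _write(records, name="seqs.fa"):
        path = tmp_path / name
        write_fasta(records, path)
        return path

    return _write


@pytest.fixture
def dna():
    def _make(residues, id="seq"):
        return NucSequence(id=id, residues=residues)

    return _make


@pytest.fixture
def protein():
    def _make(residues, id="prot"):
        return ProteinSequence(id=id, residues=residues)

    return _make
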