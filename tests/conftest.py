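import pytest

from sedaprof.simulate import (
    make_reference_panel,
    make_toy_taxonomy,
    parse_fasta,
)


@pytest.fixture(scope="session")
def tree():
    return make_toy_taxonomy()


@pytest.fixture(scope="session")
def panel_bundle(tree):
    """(fasta text, accession→taxid map, accession→sequence dict)."""
    fasta, acc_map = make_reference_panel(tree, seq_len=1000, seed=7)
    return fasta, acc_map, parse_fasta(fasta)


@pytest.fixture(scope="session")
def taxid_of(tree):
    def _lookup(name):
        return tree.find_name(name)

    return _lookup
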