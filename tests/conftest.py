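import pytest

from polyglu import load_tails, variant_cterm_peptidoform, worked_example_fixtures


@pytest.fixture(scope="session")
def tails():
    return load_tails()


@pytest.fixture(scope="session")
def alpha_peptide(tails):
    """The tryptic C-terminal peptide of the detyrosinated TUBA1B tail,
    with its full-length start residue number."""
    return variant_cterm_peptidoform("TUBA1B", "dTyr", tails)


@pytest.fixture(scope="session")
def worked_examples():
    return worked_example_fixtures()
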