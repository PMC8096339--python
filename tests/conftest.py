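from pathlib import Path

import pytest

from vario_rna import load_registry
from vario_rna.synthetic import generate_transcript

DATA = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def hierarchy():
    return load_registry()


@pytest.fixture(scope="session")
def transcript():
    """A 200-codon synthetic mRNA with UTRs, shared across tests."""
    return generate_transcript(7, cds_codons=200, utr5=25, utr3=40)


@pytest.fixture(scope="session")
def data_dir():
    return DATA
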