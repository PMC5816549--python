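import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from hypmine.seqio import ProteinRecord


@pytest.fixture
def rng():
    return np.random.default_rng(20180217)


@pytest.fixture
def toy_proteome():
    return [
        ProteinRecord("agp1", "PAST" * 20),
        ProteinRecord("ext1", "SPPP" + "G" * 60 + "SPPP" + "G" * 60),
        ProteinRecord("prp1", "G" * 40 + "PPVAK" + "G" * 40),
        ProteinRecord("neg1", "G" * 80),
    ]


@pytest.fixture
def proteome_fasta(tmp_path, toy_proteome):
    path = tmp_path / "toy.faa"
    path.write_text(
        "".join(f">{r.id}\n{r.sequence}\n" for r in toy_proteome)
    )
    return path
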