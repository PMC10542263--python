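import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # makes oracles importable

from hybrec.io import GenomeSequence


def random_dna(rng, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


@pytest.fixture(scope="session")
def parent_genomes():
    """Two unrelated 6 kb chromosomes standing in for the parental genomes."""
    rng = np.random.default_rng(42)
    return (
        GenomeSequence("speciesA", "chrA", random_dna(rng, 6000)),
        GenomeSequence("speciesB", "chrB", random_dna(rng, 6000)),
    )
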