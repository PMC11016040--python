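import numpy as np
import pytest

from codonbias.genetics import CODONS, FAMILIES
from codonbias.metrics import CodonCountTable


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


def random_count_table(rng, max_count: int = 50) -> CodonCountTable:
    """A random 64-codon count table (some codons zero)."""
    counts = {
        c: int(rng.integers(0, max_count)) if rng.random() > 0.2 else 0
        for c in CODONS
    }
    return CodonCountTable(counts)


def table_from_family_counts(**family_counts) -> CodonCountTable:
    """Build a count table from explicit codon counts (rest zero)."""
    return CodonCountTable(dict(family_counts))


@pytest.fixture
def uniform_families_table() -> CodonCountTable:
    """Every codon of every family (stops included) used 10 times."""
    return CodonCountTable({c: 10 for c in CODONS})


@pytest.fixture
def one_codon_per_family_table() -> CodonCountTable:
    """Exactly one codon used per family; the extreme-bias limit."""
    counts = {}
    for aa, codons in FAMILIES.items():
        counts[codons[0]] = 30
    return CodonCountTable(counts)
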