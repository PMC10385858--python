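import numpy as np
import pytest

from codontrend.genetic_code import STANDARD_CODE, SYNONYMOUS_CODONS, CodonCounts
from codontrend.synthetic_data import lentivirus_panel_spec
from codontrend import coding_counts, generate_panel


@pytest.fixture(scope="session")
def uniform_counts() -> CodonCounts:
    """1000 occurrences of each of the 59 synonymous codons."""
    return CodonCounts(counts={c: 1000 for c in SYNONYMOUS_CODONS})


@pytest.fixture(scope="session")
def one_codon_counts() -> CodonCounts:
    """Exactly one synonym used per degenerate family, 100 occurrences each."""
    counts = {
        fam[0]: 100
        for fam in STANDARD_CODE.synonym_families.values()
        if len(fam) > 1
    }
    return CodonCounts(counts=counts)


@pytest.fixture(scope="session")
def gradient_panel():
    """The 8-group study panel (54 taxa, AT3 gradient 65.4% -> 70.4%,
    8000 codons per taxon) with per-taxon codon counts precomputed."""
    spec = lentivirus_panel_spec(seed=1234)
    seqs, entries = generate_panel(spec)
    counts_list = [coding_counts(seqs[e.record_id], e) for e in entries]
    return spec, entries, counts_list


def random_counts(rng: np.random.Generator, scale: int = 200) -> CodonCounts:
    """Arbitrary mixed counts with every family observed at least twice."""
    counts = {}
    for fam in STANDARD_CODE.synonym_families.values():
        if len(fam) == 1:
            continue
        alloc = rng.multinomial(scale, np.ones(len(fam)) / len(fam))
        # guarantee n >= 2 per family so Nc is defined
        alloc[0] += 2
        for codon, n in zip(fam, alloc):
            if n:
                counts[codon] = int(n)
    return CodonCounts(counts=counts)
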