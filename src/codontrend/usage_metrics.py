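"""Per-taxon codon-usage statistics: RSCU, Wright's effective number of
codons, and amino-acid composition.

RSCU (relative synonymous codon usage) for a codon c of amino acid a is

    RSCU(c) = (N_c / N_a) * D_a

where N_c is the codon's count, N_a the count of the amino acid over all
its synonyms and D_a the degeneracy. Uniform synonym usage gives RSCU = 1
for every codon; exclusive use of one synonym gives RSCU = D for it and 0
for the rest.

The effective number of codons (Nc) summarises codon bias on a scale from
20 (one codon per amino acid) to 61 (all synonyms equally used), using
Wright's class-averaged homozygosity estimator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd

from .genetic_code import (
    STANDARD_CODE,
    SYNONYMOUS_CODONS,
    CodonCounts,
    CompositionUndefinedError,
)

__all__ = [
    "RSCUProfile",
    "NcValue",
    "AAProfile",
    "NcUndefinedError",
    "rscu",
    "effective_number_of_codons",
    "amino_acid_composition",
    "profiles_to_frame",
]

#: The 18 amino acids with two or more synonyms, alphabetical.
DEGENERATE_AMINO_ACIDS: tuple[str, ...] = tuple(
    sorted(STANDARD_CODE.degenerate_amino_acids)
)

#: Alphabetical order of the 59 synonymous codons, the documented column
#: order of every table writer in this package.
SYNONYMOUS_CODON_ORDER: tuple[str, ...] = tuple(sorted(SYNONYMOUS_CODONS))


class NcUndefinedError(ValueError):
    """A required degeneracy class has no computable homozygosity."""


@dataclass
class RSCUProfile:
    """RSCU values over the 59 synonymous codons for one taxon.

    Families with zero observations are listed in ``undefined_families``;
    their codons carry the sentinel value 0.0 and should be excluded
    pairwise from downstream correlations rather than treated as data.
    """

    values: dict[str, float]
    undefined_families: frozenset[str] = frozenset()
    source_id: str = ""

    def as_series(self) -> pd.Series:
        """RSCU in fixed alphabetical codon order, NaN for undefined families."""
        data = {}
        for aa in DEGENERATE_AMINO_ACIDS:
            undef = aa in self.undefined_families
            for codon in STANDARD_CODE.synonym_families[aa]:
                data[codon] = float("nan") if undef else self.values[codon]
        return pd.Series(data, name=self.source_id or None).reindex(
            list(SYNONYMOUS_CODON_ORDER)
        )


@dataclass
class NcValue:
    nc: float
    f_bars: dict[int, float] = field(default_factory=dict)
    families_used: int = 0
    raw_nc: float = 0.0


@dataclass
class AAProfile:
    """Percent content of the 18 degenerate-family amino acids.

    Met and Trp occurrences are excluded from numerator and denominator, so
    the profile is 18-dimensional by construction and not comparable to a
    20-amino-acid composition without conversion.
    """

    pct: dict[str, float]
    total_aa: int

    def as_series(self) -> pd.Series:
        return pd.Series(self.pct).reindex(list(DEGENERATE_AMINO_ACIDS))


def _family_counts(counts: CodonCounts) -> dict[str, dict[str, int]]:
    return {
        aa: {c: counts.get(c) for c in STANDARD_CODE.synonym_families[aa]}
        for aa in DEGENERATE_AMINO_ACIDS
    }


def rscu(counts: CodonCounts) -> RSCUProfile:
    """Relative synonymous codon usage of one taxon.

    Families with no observed codon are flagged undefined (sentinel 0.0)
    instead of raising, so sparse inputs degrade gracefully.
    """
    values: dict[str, float] = {}
    undefined: set[str] = set()
    for aa, fam in _family_counts(counts).items():
        n_aa = sum(fam.values())
        d = STANDARD_CODE.degeneracy[aa]
        if n_aa == 0:
            undefined.add(aa)
            for codon in fam:
                values[codon] = 0.0
            continue
        for codon, n_c in fam.items():
            values[codon] = (n_c / n_aa) * d
    return RSCUProfile(
        values=values,
        undefined_families=frozenset(undefined),
        source_id=counts.source_id,
    )


#: Number of amino-acid families per degeneracy class in the standard code
#: (2-fold: 9, 3-fold: 1 (Ile), 4-fold: 5, 6-fold: 3), giving Wright's
#: identity 2 + 9 + 1 + 5 + 3 = 20.
_CLASS_SIZES = {2: 9, 3: 1, 4: 5, 6: 3}


def effective_number_of_codons(counts: CodonCounts) -> NcValue:
    """Wright's effective number of codons, capped into [20, 61].

    Per family with n >= 2 observations the codon homozygosity is estimated
    as F = (n * sum(p_i^2) - 1) / (n - 1); class means average F over the
    families of each degeneracy class, and

        Nc = 2 + 9/F2 + 1/F3 + 5/F4 + 3/F6.

    Families with n < 2 or F = 0 are excluded from their class mean. If the
    single 3-fold family (Ile) is unusable, F3 is imputed as (F2 + F4) / 2.
    The finite-sample estimator can slightly exceed 61; the returned value
    is capped into the statistic's theoretical range (raw value kept in
    ``raw_nc``).
    """
    class_f: dict[int, list[float]] = {2: [], 3: [], 4: [], 6: []}
    families_used = 0
    for aa, fam in _family_counts(counts).items():
        n = sum(fam.values())
        if n < 2:
            continue
        sum_p2 = sum((c / n) ** 2 for c in fam.values())
        f_hat = (n * sum_p2 - 1.0) / (n - 1.0)
        if f_hat <= 0.0:
            continue
        class_f[STANDARD_CODE.degeneracy[aa]].append(f_hat)
        families_used += 1
    f_bars = {k: sum(v) / len(v) for k, v in class_f.items() if v}
    if 3 not in f_bars and 2 in f_bars and 4 in f_bars:
        f_bars[3] = (f_bars[2] + f_bars[4]) / 2.0
    missing = [k for k in _CLASS_SIZES if k not in f_bars]
    if missing:
        raise NcUndefinedError(
            f"no computable homozygosity for degeneracy class(es) {missing}"
        )
    raw = 2.0 + sum(_CLASS_SIZES[k] / f_bars[k] for k in _CLASS_SIZES)
    return NcValue(
        nc=min(61.0, max(20.0, raw)),
        f_bars=f_bars,
        families_used=families_used,
        raw_nc=raw,
    )


def amino_acid_composition(counts: CodonCounts) -> AAProfile:
    """Percent amino-acid content over the 18 degenerate families."""
    fam_totals = {
        aa: sum(fam.values()) for aa, fam in _family_counts(counts).items()
    }
    total = sum(fam_totals.values())
    if total == 0:
        raise CompositionUndefinedError(
            "no synonymous-codon occurrences; amino-acid composition undefined"
        )
    pct = {aa: 100.0 * n / total for aa, n in fam_totals.items()}
    return AAProfile(pct=pct, total_aa=total)


def profiles_to_frame(profiles: list[RSCUProfile] | list[AAProfile]) -> pd.DataFrame:
    """Stack per-taxon profiles into a taxa-by-feature DataFrame.

    Columns follow the documented fixed order (alphabetical codons for RSCU,
    alphabetical one-letter amino acids for composition).
    """
    rows = [p.as_series() for p in profiles]
    frame = pd.DataFrame(rows)
    if all(isinstance(p, RSCUProfile) for p in profiles):
        ids = [p.source_id or f"taxon_{i}" for i, p in enumerate(profiles)]
        frame.index = pd.Index(ids, name="taxon")
    return frame
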