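"""Standard genetic code tables, codon counting, and position-specific
nucleotide composition.

The analyses in this package are built on the 59 "synonymous codons": the 61
sense codons of the standard genetic code minus ATG (Met) and TGG (Trp),
whose amino acids are encoded by a single codon and therefore carry no
synonymous-choice information. Composition summaries are occurrence-weighted:
each codon occurrence contributes its base at the chosen position, so the
result is a property of the sequence, not of the codon inventory.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from Bio.Data import CodonTable

__all__ = [
    "GeneticCode",
    "CodonCounts",
    "CompositionProfile",
    "STANDARD_CODE",
    "SENSE_CODONS",
    "STOP_CODONS",
    "SYNONYMOUS_CODONS",
    "FIRST_POSITION_EXCLUSIONS",
    "FrameError",
    "InternalStopError",
    "CompositionUndefinedError",
    "count_codons",
    "positional_composition",
]


class FrameError(ValueError):
    """Sequence length is not a multiple of three."""


class InternalStopError(ValueError):
    """A stop codon occurs before the final triplet under strict policy."""


class CompositionUndefinedError(ValueError):
    """No included codon was observed, so percentages are undefined."""


@dataclass(frozen=True)
class GeneticCode:
    """The standard genetic code (translation table 1) over DNA triplets.

    Attributes
    ----------
    codon_to_aa
        Map of the 64 uppercase DNA triplets to one-letter amino acids;
        stop codons map to ``"*"``.
    synonym_families
        Amino acid -> alphabetically ordered tuple of its codons
        (sense codons only).
    degeneracy
        Amino acid -> number of synonyms (1, 2, 3, 4 or 6).
    """

    codon_to_aa: Mapping[str, str]
    synonym_families: Mapping[str, tuple[str, ...]]
    degeneracy: Mapping[str, int]

    @property
    def sense_codons(self) -> frozenset[str]:
        return frozenset(c for c, a in self.codon_to_aa.items() if a != "*")

    @property
    def stop_codons(self) -> frozenset[str]:
        return frozenset(c for c, a in self.codon_to_aa.items() if a == "*")

    @property
    def synonymous_codons(self) -> frozenset[str]:
        """The 59 sense codons excluding ATG (Met) and TGG (Trp)."""
        return frozenset(c for c in self.sense_codons if c not in ("ATG", "TGG"))

    @property
    def degenerate_amino_acids(self) -> frozenset[str]:
        """The 18 amino acids encoded by more than one codon."""
        return frozenset(a for a, d in self.degeneracy.items() if d >= 2)


def _build_standard_code() -> GeneticCode:
    table = CodonTable.unambiguous_dna_by_id[1]
    codon_to_aa = dict(table.forward_table)
    for stop in table.stop_codons:
        codon_to_aa[stop] = "*"
    families: dict[str, tuple[str, ...]] = {}
    for aa in sorted(set(table.forward_table.values())):
        families[aa] = tuple(
            sorted(c for c, a in table.forward_table.items() if a == aa)
        )
    degeneracy = {aa: len(cods) for aa, cods in families.items()}
    return GeneticCode(codon_to_aa, families, degeneracy)


STANDARD_CODE = _build_standard_code()
SENSE_CODONS = STANDARD_CODE.sense_codons
STOP_CODONS = STANDARD_CODE.stop_codons
SYNONYMOUS_CODONS = STANDARD_CODE.synonymous_codons

#: Codons excluded from first-position composition: the Arg and Leu synonyms
#: for which a first-position substitution can be silent (AGA<->CGA,
#: AGG<->CGG, TTA<->CTA, TTG<->CTG).
FIRST_POSITION_EXCLUSIONS = frozenset(
    {"AGA", "CGA", "AGG", "CGG", "TTA", "CTA", "TTG", "CTG"}
)


@dataclass
class CodonCounts:
    """Absolute occurrence counts of sense codons for one coding region.

    ``counts`` is keyed only by the 61 sense codons. Triplets containing a
    non-ACGT symbol are skipped whole and tallied in ``n_skipped_ambiguous``;
    stop triplets are tallied in ``n_stop_codons`` and never counted as sense
    codons.
    """

    counts: dict[str, int] = field(default_factory=dict)
    n_skipped_ambiguous: int = 0
    n_stop_codons: int = 0
    source_id: str = ""

    def __post_init__(self) -> None:
        bad = set(self.counts) - SENSE_CODONS
        if bad:
            raise ValueError(f"non-sense-codon keys in counts: {sorted(bad)}")
        neg = [c for c, n in self.counts.items() if n < 0]
        if neg:
            raise ValueError(f"negative counts for {sorted(neg)}")

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def get(self, codon: str) -> int:
        return self.counts.get(codon, 0)

    def __add__(self, other: "CodonCounts") -> "CodonCounts":
        merged = Counter(self.counts)
        merged.update(other.counts)
        return CodonCounts(
            counts=dict(merged),
            n_skipped_ambiguous=self.n_skipped_ambiguous + other.n_skipped_ambiguous,
            n_stop_codons=self.n_stop_codons + other.n_stop_codons,
            source_id=self.source_id or other.source_id,
        )


@dataclass(frozen=True)
class CompositionProfile:
    """Percent base frequency at one codon position.

    ``pct`` maps A, T, G, C, ``A+T`` and ``G+C`` to percentages that sum to
    100 over the four bases; ``included_codons`` is the codon set that
    defined the denominator.
    """

    position: int
    pct: Mapping[str, float]
    included_codons: frozenset[str]


_VALID_BASES = frozenset("ACGT")


def count_codons(coding_sequence: str, policy: str = "strict") -> CodonCounts:
    """Count in-frame sense codons of a coding sequence.

    Parameters
    ----------
    coding_sequence
        DNA text already in frame. Case-insensitive; U is normalised to T.
    policy
        ``"strict"`` (default) raises :class:`InternalStopError` on any stop
        triplet before the final one; ``"tolerant"`` tallies every stop in
        ``n_stop_codons`` and never raises.

    Returns
    -------
    CodonCounts
        Sense-codon counts plus tallies of skipped ambiguous triplets and
        stop codons. An empty sequence yields all-zero counts.
    """
    if policy not in ("strict", "tolerant"):
        raise ValueError(f"unknown policy {policy!r}")
    seq = coding_sequence.strip().upper().replace("U", "T")
    if len(seq) % 3 != 0:
        raise FrameError(
            f"sequence length {len(seq)} is not divisible by 3"
        )
    counts: Counter[str] = Counter()
    n_ambiguous = 0
    n_stop = 0
    n_triplets = len(seq) // 3
    for i in range(n_triplets):
        codon = seq[3 * i : 3 * i + 3]
        if not _VALID_BASES.issuperset(codon):
            n_ambiguous += 1
            continue
        if codon in STOP_CODONS:
            if policy == "strict" and i != n_triplets - 1:
                raise InternalStopError(
                    f"internal stop codon {codon} at triplet {i + 1}"
                )
            n_stop += 1
            continue
        counts[codon] += 1
    return CodonCounts(
        counts=dict(counts),
        n_skipped_ambiguous=n_ambiguous,
        n_stop_codons=n_stop,
    )


def included_codons_for_rule(rule: str | Iterable[str]) -> frozenset[str]:
    """Resolve an inclusion-rule name (or explicit codon set) to a codon set.

    Named rules: ``"third-synonymous"`` and ``"second-all-synonymous"`` use
    the 59 synonymous codons; ``"first-nonsynonymous"`` additionally drops
    the eight Arg/Leu synonyms whose first-position substitutions can be
    silent.
    """
    if isinstance(rule, str):
        if rule in ("third-synonymous", "second-all-synonymous"):
            return SYNONYMOUS_CODONS
        if rule == "first-nonsynonymous":
            return SYNONYMOUS_CODONS - FIRST_POSITION_EXCLUSIONS
        raise ValueError(f"unknown inclusion rule {rule!r}")
    custom = frozenset(c.upper() for c in rule)
    bad = custom - SENSE_CODONS
    if bad:
        raise ValueError(f"custom rule contains non-sense codons: {sorted(bad)}")
    return custom


def positional_composition(
    counts: CodonCounts, position: int, rule: str | Iterable[str]
) -> CompositionProfile:
    """Occurrence-weighted percent base composition at one codon position.

    For each base b, ``pct[b]`` is 100 times the number of included codon
    occurrences carrying b at ``position`` divided by the total included
    occurrences.

    Raises
    ------
    CompositionUndefinedError
        If no included codon was observed.
    """
    if position not in (1, 2, 3):
        raise ValueError("position must be 1, 2 or 3")
    included = included_codons_for_rule(rule)
    base_counts = {b: 0 for b in "ACGT"}
    total = 0
    for codon in included:
        n = counts.get(codon)
        if n:
            base_counts[codon[position - 1]] += n
            total += n
    if total == 0:
        raise CompositionUndefinedError(
            f"no included codon observed at position {position}"
        )
    pct = {b: 100.0 * base_counts[b] / total for b in "ACGT"}
    pct["A+T"] = pct["A"] + pct["T"]
    pct["G+C"] = pct["G"] + pct["C"]
    return CompositionProfile(position=position, pct=pct, included_codons=included)
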