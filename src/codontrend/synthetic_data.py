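"""Synthetic virus panels and host usage tables with controllable codon-usage
structure.

The generator emulates the statistical structure the trend analysis assumes:
groups of coding sequences whose third-position A+T content (AT3) follows a
monotone gradient, optionally with correlated shifts in amino-acid
composition (Ile/Ser up, Tyr/Leu down along the gradient), plus host-like
codon-usage tables with a controllable share of A/T-ending codons.

Codons are sampled i.i.d. within a taxon: within each amino-acid family,
probability mass ``target_at3`` sits uniformly on the A/T-ending synonyms
and the rest uniformly on the G/C-ending synonyms, which makes the expected
occurrence-weighted AT3 equal to the target exactly, independently of the
amino-acid frequencies. Amino-acid frequencies follow a base distribution
over the 18 degenerate families multiplied by per-group shift weights.
Everything is a pure function of the spec, seed included.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .genetic_code import STANDARD_CODE
from .sequence_ingest import HostUsageTable, RegionManifestEntry, write_manifest
from .usage_metrics import DEGENERATE_AMINO_ACIDS
from . import usage_metrics
from .genetic_code import CodonCounts

__all__ = [
    "GroupSpec",
    "PanelSpec",
    "codon_weights_for",
    "generate_panel",
    "generate_host_table",
    "lentivirus_panel_spec",
    "LENTIVIRUS_LIKE_AA",
    "UNIFORM_AA",
]

#: Uniform base distribution over the 18 degenerate amino-acid families.
UNIFORM_AA: dict[str, float] = {aa: 1.0 / 18 for aa in DEGENERATE_AMINO_ACIDS}

#: A lentivirus-like base composition (Ile/Ser-rich relative to uniform),
#: normalised at use. Values are rough proteome-scale percentages.
LENTIVIRUS_LIKE_AA: dict[str, float] = {
    "A": 5.5, "R": 5.5, "N": 4.0, "D": 4.5, "C": 2.0, "Q": 4.5,
    "E": 7.0, "G": 6.5, "H": 2.5, "I": 6.7, "L": 8.6, "K": 6.5,
    "F": 3.5, "P": 5.0, "S": 4.4, "T": 6.0, "Y": 3.7, "V": 6.0,
}


@dataclass(frozen=True)
class GroupSpec:
    label: str
    n_taxa: int
    target_at3: float
    aa_shift: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_taxa < 1:
            raise ValueError("n_taxa must be >= 1")
        if not 0.0 <= self.target_at3 <= 1.0:
            raise ValueError("target_at3 must be in [0, 1]")


@dataclass(frozen=True)
class PanelSpec:
    groups: tuple[GroupSpec, ...]
    codons_per_taxon: int = 8000
    seed: int = 0
    aa_base: Mapping[str, float] | None = None
    gene_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.codons_per_taxon < 500:
            raise ValueError("codons_per_taxon must be >= 500 for stable RSCU")


def _split_family(aa: str) -> tuple[list[str], list[str]]:
    fam = STANDARD_CODE.synonym_families[aa]
    at = [c for c in fam if c[2] in "AT"]
    gc = [c for c in fam if c[2] in "GC"]
    return at, gc


def codon_weights_for(
    target_at3: float,
    aa_shift: Mapping[str, float] | None = None,
    aa_base: Mapping[str, float] | None = None,
) -> dict[str, float]:
    """Per-codon sampling probabilities achieving an expected AT3 target.

    Within each family, probability mass ``target_at3`` is spread uniformly
    over the A/T-ending synonyms and ``1 - target_at3`` over the G/C-ending
    synonyms; amino-acid frequencies follow ``aa_base`` (default uniform
    over the 18 degenerate families) multiplied by ``aa_shift`` and
    renormalised. Returns a probability map over the 59 synonymous codons.
    """
    if not 0.0 <= target_at3 <= 1.0:
        raise ValueError("target_at3 must be in [0, 1]")
    base = dict(aa_base or UNIFORM_AA)
    shift = dict(aa_shift or {})
    unknown = set(shift) - set(DEGENERATE_AMINO_ACIDS)
    if unknown:
        raise ValueError(f"aa_shift for unknown amino acids: {sorted(unknown)}")
    aa_w = {aa: base.get(aa, 0.0) * shift.get(aa, 1.0) for aa in DEGENERATE_AMINO_ACIDS}
    total = sum(aa_w.values())
    if total <= 0:
        raise ValueError("amino-acid weights sum to zero")
    aa_w = {aa: w / total for aa, w in aa_w.items()}
    weights: dict[str, float] = {}
    for aa, f_aa in aa_w.items():
        at, gc = _split_family(aa)
        if target_at3 > 0 and not at:
            raise ValueError(f"family {aa} has no A/T-ending synonyms")
        if target_at3 < 1 and not gc:
            raise ValueError(f"family {aa} has no G/C-ending synonyms")
        for c in at:
            weights[c] = f_aa * target_at3 / len(at)
        for c in gc:
            weights[c] = f_aa * (1.0 - target_at3) / len(gc)
    return weights


def _sample_gene(
    rng: np.random.Generator, codon_list: list[str], probs: np.ndarray, n_codons: int
) -> str:
    idx = rng.choice(len(codon_list), size=n_codons, p=probs)
    return "".join(codon_list[i] for i in idx) + "TAA"


def generate_panel(
    spec: PanelSpec,
    fasta_path: str | Path | None = None,
    manifest_path: str | Path | None = None,
) -> tuple[dict[str, str], list[RegionManifestEntry]]:
    """Generate a reproducible panel of coding sequences.

    For each taxon, codons are drawn i.i.d. from its group's weights and a
    terminal stop appended per gene. Returns the sequences and manifest
    entries, and writes FASTA/manifest files when paths are given; outputs
    are byte-identical for identical specs.
    """
    rng = np.random.default_rng(spec.seed)
    gene_names = spec.gene_names or ("cds",)
    n_genes = len(gene_names)
    per_gene = [spec.codons_per_taxon // n_genes] * n_genes
    per_gene[-1] += spec.codons_per_taxon - sum(per_gene)
    seqs: dict[str, str] = {}
    entries: list[RegionManifestEntry] = []
    for group in spec.groups:
        weights = codon_weights_for(group.target_at3, group.aa_shift, spec.aa_base)
        codon_list = sorted(weights)
        probs = np.array([weights[c] for c in codon_list])
        probs = probs / probs.sum()
        for i in range(group.n_taxa):
            taxon = f"{group.label}_{i + 1:02d}"
            parts = [
                _sample_gene(rng, codon_list, probs, m) for m in per_gene
            ]
            seqs[taxon] = "".join(parts)
            intervals, genes, offset = [], [], 0
            for gene, part in zip(gene_names, parts):
                intervals.append((offset + 1, offset + len(part)))
                genes.append(gene)
                offset += len(part)
            entries.append(
                RegionManifestEntry(
                    record_id=taxon,
                    group=group.label,
                    intervals=intervals,
                    genes=genes,
                )
            )
    if fasta_path is not None:
        with open(fasta_path, "w") as fh:
            for taxon, seq in seqs.items():
                fh.write(f">{taxon}\n")
                for j in range(0, len(seq), 70):
                    fh.write(seq[j : j + 70] + "\n")
    if manifest_path is not None:
        write_manifest(entries, manifest_path)
    return seqs, entries


def generate_host_table(
    at_ending_fraction: float,
    seed: int,
    cell_type: str = "host",
    n_codons: int = 200_000,
    aa_base: Mapping[str, float] | None = None,
) -> HostUsageTable:
    """A 59-codon RSCU table whose A/T-ending usage share matches a target.

    Codon counts are drawn once from a multinomial at the target weights
    (finite sampling noise mimics a real transcriptome-derived table) and
    converted to RSCU; with the default depth the realised share is within
    half a percentage point of the target.
    """
    if not 0.0 < at_ending_fraction < 1.0:
        raise ValueError("at_ending_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    weights = codon_weights_for(at_ending_fraction, aa_base=aa_base)
    codon_list = sorted(weights)
    probs = np.array([weights[c] for c in codon_list])
    counts_vec = rng.multinomial(n_codons, probs / probs.sum())
    counts = CodonCounts(
        counts={c: int(n) for c, n in zip(codon_list, counts_vec)},
        source_id=cell_type,
    )
    profile = usage_metrics.rscu(counts)
    return HostUsageTable(cell_type=cell_type, codon_values=dict(profile.values))


#: Eight panel groups in trend order, scaled to 54 taxa, with an AT3
#: gradient from 65.4% to 70.4% and a correlated amino-acid drift
#: (Ile and Ser enriched, Tyr and Leu depleted along the gradient).
_LENTIVIRUS_GROUPS: tuple[tuple[str, int], ...] = (
    ("SIV-monkey", 21),
    ("HIV-2", 2),
    ("SIVgor", 4),
    ("SIVcpz", 7),
    ("HIV-1-O", 5),
    ("HIV-1-P", 1),
    ("HIV-1-N", 4),
    ("HIV-1-M", 10),
)


def lentivirus_panel_spec(
    seed: int = 0,
    codons_per_taxon: int = 8000,
    at3_range: tuple[float, float] = (0.654, 0.704),
    aa_drift: bool = True,
    gene_names: tuple[str, ...] = (),
) -> PanelSpec:
    """The default study panel: 8 primate-lentivirus-like groups, 54 taxa.

    AT3 targets are spaced linearly over ``at3_range`` in trend order from
    monkey-infecting SIV to pandemic HIV-1 group M. With ``aa_drift``, the
    amino-acid distribution shifts along the gradient with endpoint ratios
    matching an Ile 6.7->7.8%, Ser 4.4->5.2%, Tyr 3.7->3.1%, Leu 8.6->8.2%
    drift over a lentivirus-like base composition.
    """
    lo, hi = at3_range
    targets = np.linspace(lo, hi, len(_LENTIVIRUS_GROUPS))
    groups = []
    for k, ((label, n_taxa), target) in enumerate(zip(_LENTIVIRUS_GROUPS, targets)):
        g = k / (len(_LENTIVIRUS_GROUPS) - 1)
        shift = (
            {
                "I": 1.0 + (7.8 / 6.7 - 1.0) * g,
                "S": 1.0 + (5.2 / 4.4 - 1.0) * g,
                "Y": 1.0 + (3.1 / 3.7 - 1.0) * g,
                "L": 1.0 + (8.2 / 8.6 - 1.0) * g,
            }
            if aa_drift
            else {}
        )
        groups.append(GroupSpec(label, n_taxa, float(target), shift))
    return PanelSpec(
        groups=tuple(groups),
        codons_per_taxon=codons_per_taxon,
        seed=seed,
        aa_base=LENTIVIRUS_LIKE_AA,
        gene_names=gene_names,
    )
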