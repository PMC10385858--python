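"""Loading of genomes, coding-region manifests, and host codon-usage tables.

A *region manifest* lists, per FASTA record, the non-overlapping coding
intervals to analyse (1-based inclusive, forward strand) together with a
group label, optional per-interval gene names, and optional exclusion spans
(e.g., a structured RNA element such as the RRE inside *env* that would
confound coding-sequence statistics). Each interval is validated
independently so that the terminal stop codon of one gene is never misread
as an internal stop of the concatenated region.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping

import pandas as pd
from Bio import SeqIO

from . import usage_metrics
from .genetic_code import STANDARD_CODE, SYNONYMOUS_CODONS, CodonCounts, count_codons

logger = logging.getLogger(__name__)

__all__ = [
    "RegionManifestEntry",
    "HostUsageTable",
    "ManifestError",
    "extract_regions",
    "coding_counts",
    "read_fasta",
    "read_manifest",
    "write_manifest",
    "load_host_table",
    "write_host_table",
    "at_ending_fraction",
]

MANIFEST_COLUMNS = ("record_id", "group", "intervals", "exclusions", "genes")


class ManifestError(ValueError):
    """A manifest entry violates the interval contract."""


@dataclass
class RegionManifestEntry:
    """Coding intervals for one FASTA record.

    ``intervals`` are 1-based inclusive (start, end) pairs on the forward
    strand, strictly ascending and non-overlapping; ``exclusions`` are spans
    subtracted from them. After subtraction, the remaining length of every
    interval must be divisible by 3. ``genes`` optionally names each
    interval (parallel list) for gene-level analyses.
    """

    record_id: str
    group: str
    intervals: list[tuple[int, int]]
    exclusions: list[tuple[int, int]] = field(default_factory=list)
    genes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for start, end in self.intervals + self.exclusions:
            if start < 1 or end < start:
                raise ManifestError(
                    f"{self.record_id}: bad interval ({start}, {end})"
                )
        prev_end = 0
        for start, end in self.intervals:
            if start <= prev_end:
                raise ManifestError(
                    f"{self.record_id}: intervals overlap or are out of order "
                    f"at ({start}, {end})"
                )
            prev_end = end
        if self.genes and len(self.genes) != len(self.intervals):
            raise ManifestError(
                f"{self.record_id}: {len(self.genes)} gene names for "
                f"{len(self.intervals)} intervals"
            )
        for start, end in self.intervals:
            if self._remaining_length(start, end) % 3 != 0:
                raise ManifestError(
                    f"{self.record_id}: interval ({start}, {end}) has "
                    "post-exclusion length not divisible by 3"
                )

    def _pieces(self, start: int, end: int) -> list[tuple[int, int]]:
        """0-based half-open sub-pieces of one interval after exclusions."""
        pieces = [(start - 1, end)]
        for ex_start, ex_end in self.exclusions:
            nxt: list[tuple[int, int]] = []
            for p_start, p_end in pieces:
                cut_lo, cut_hi = max(p_start, ex_start - 1), min(p_end, ex_end)
                if cut_lo >= cut_hi:
                    nxt.append((p_start, p_end))
                    continue
                if p_start < cut_lo:
                    nxt.append((p_start, cut_lo))
                if cut_hi < p_end:
                    nxt.append((cut_hi, p_end))
            pieces = nxt
        return pieces

    def _remaining_length(self, start: int, end: int) -> int:
        return sum(e - s for s, e in self._pieces(start, end))


def extract_regions(genome: str, entry: RegionManifestEntry) -> str:
    """Concatenated in-frame coding sequence for one manifest entry.

    Intervals are cut from the genome, exclusion spans subtracted, and the
    remaining pieces joined in genomic order. Each interval's sequence is
    validated with strict stop handling before concatenation.
    """
    genome = genome.strip().upper().replace("U", "T")
    parts = []
    for start, end in entry.intervals:
        if end > len(genome):
            raise ManifestError(
                f"{entry.record_id}: interval end {end} beyond genome "
                f"length {len(genome)}"
            )
        piece = "".join(genome[s:e] for s, e in entry._pieces(start, end))
        count_codons(piece, policy="strict")  # frame + internal-stop check
        parts.append(piece)
    return "".join(parts)


def coding_counts(genome: str, entry: RegionManifestEntry) -> CodonCounts:
    """Summed codon counts over an entry's intervals, validated per interval."""
    genome = genome.strip().upper().replace("U", "T")
    total = CodonCounts(source_id=entry.record_id)
    for start, end in entry.intervals:
        if end > len(genome):
            raise ManifestError(
                f"{entry.record_id}: interval end {end} beyond genome "
                f"length {len(genome)}"
            )
        piece = "".join(genome[s:e] for s, e in entry._pieces(start, end))
        total = total + count_codons(piece, policy="strict")
    total.source_id = entry.record_id
    return total


def gene_counts(genome: str, entry: RegionManifestEntry) -> dict[str, CodonCounts]:
    """Codon counts per gene tag, summing intervals sharing a tag.

    Requires the entry to carry gene names; pooling several genes is done
    by summing their raw counts (equivalent to concatenating the sequences
    before counting).
    """
    if not entry.genes:
        raise ManifestError(f"{entry.record_id}: manifest has no gene tags")
    genome = genome.strip().upper().replace("U", "T")
    out: dict[str, CodonCounts] = {}
    for (start, end), gene in zip(entry.intervals, entry.genes):
        if end > len(genome):
            raise ManifestError(
                f"{entry.record_id}: interval end {end} beyond genome "
                f"length {len(genome)}"
            )
        piece = "".join(genome[s:e] for s, e in entry._pieces(start, end))
        counts = count_codons(piece, policy="strict")
        out[gene] = out[gene] + counts if gene in out else counts
        out[gene].source_id = f"{entry.record_id}:{gene}"
    return out


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file (plain or gzip) into an id -> sequence map."""
    path = Path(path)
    if path.suffix == ".gz":
        with gzip.open(path, "rt") as handle:
            records = list(SeqIO.parse(handle, "fasta"))
    else:
        records = list(SeqIO.parse(str(path), "fasta"))
    seqs: dict[str, str] = {}
    for rec in records:
        if rec.id in seqs:
            raise ValueError(f"duplicate FASTA record id {rec.id!r}")
        seqs[rec.id] = str(rec.seq)
    return seqs


def _parse_spans(text: str) -> list[tuple[int, int]]:
    if not text or pd.isna(text):
        return []
    spans = []
    for token in str(text).split(";"):
        token = token.strip()
        if not token:
            continue
        start_s, _, end_s = token.partition("-")
        spans.append((int(start_s), int(end_s)))
    return spans


def _format_spans(spans: list[tuple[int, int]]) -> str:
    return ";".join(f"{s}-{e}" for s, e in spans)


def read_manifest(path: str | Path) -> list[RegionManifestEntry]:
    """Read a manifest TSV (columns record_id, group, intervals, and
    optionally exclusions and genes) into validated entries."""
    frame = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    missing = {"record_id", "group", "intervals"} - set(frame.columns)
    if missing:
        raise ManifestError(f"manifest missing columns {sorted(missing)}")
    entries = []
    for row in frame.itertuples(index=False):
        genes_text = getattr(row, "genes", "") or ""
        if pd.isna(genes_text):
            genes_text = ""
        entries.append(
            RegionManifestEntry(
                record_id=row.record_id,
                group=row.group,
                intervals=_parse_spans(row.intervals),
                exclusions=_parse_spans(getattr(row, "exclusions", "")),
                genes=[g for g in str(genes_text).split(";") if g],
            )
        )
    return entries


def write_manifest(entries: list[RegionManifestEntry], path: str | Path) -> None:
    frame = pd.DataFrame(
        {
            "record_id": [e.record_id for e in entries],
            "group": [e.group for e in entries],
            "intervals": [_format_spans(e.intervals) for e in entries],
            "exclusions": [_format_spans(e.exclusions) for e in entries],
            "genes": [";".join(e.genes) for e in entries],
        }
    )
    frame.to_csv(path, sep="\t", index=False)


@dataclass
class HostUsageTable:
    """Codon-usage of genes expressed in one host cell type, as RSCU over
    the 59 synonymous codons."""

    cell_type: str
    codon_values: dict[str, float]
    n_genes: int | None = None

    def __post_init__(self) -> None:
        missing = SYNONYMOUS_CODONS - set(self.codon_values)
        if missing:
            raise ValueError(f"missing codons: {sorted(missing)}")
        extra = set(self.codon_values) - SYNONYMOUS_CODONS
        if extra:
            raise ValueError(f"unexpected codons: {sorted(extra)}")
        neg = [c for c, v in self.codon_values.items() if v < 0]
        if neg:
            raise ValueError(f"negative values for {sorted(neg)}")

    def as_series(self) -> pd.Series:
        return pd.Series(self.codon_values, name=self.cell_type).reindex(
            list(usage_metrics.SYNONYMOUS_CODON_ORDER)
        )


def load_host_table(
    path: str | Path, format: str = "rscu", cell_type: str | None = None
) -> HostUsageTable:
    """Load a host codon-usage table from CSV/TSV.

    The file needs a ``codon`` column plus one value column. With
    ``format="counts"`` the values are absolute codon counts and are
    converted to RSCU internally; ATG and TGG rows, if present, are dropped
    with a logged notice. With ``format="rscu"`` the 59 values are loaded
    verbatim.
    """
    if format not in ("rscu", "counts"):
        raise ValueError(f"unknown format {format!r}")
    path = Path(path)
    sep = "\t" if path.suffix in (".tsv", ".tab") else ","
    frame = pd.read_csv(path, sep=sep, comment="#")
    if "codon" not in frame.columns:
        raise ValueError("host table needs a 'codon' column")
    value_cols = [c for c in frame.columns if c != "codon"]
    if len(value_cols) != 1:
        raise ValueError(f"expected one value column, found {value_cols}")
    codons = [str(c).upper().replace("U", "T") for c in frame["codon"]]
    if len(set(codons)) != len(codons):
        dupes = sorted({c for c in codons if codons.count(c) > 1})
        raise ValueError(f"duplicate codons: {dupes}")
    values = dict(zip(codons, frame[value_cols[0]].astype(float)))
    name = cell_type or value_cols[0]
    if format == "counts":
        for skip in ("ATG", "TGG"):
            if skip in values:
                logger.info("dropping non-synonymous codon %s from %s", skip, name)
                del values[skip]
        missing = SYNONYMOUS_CODONS - set(values)
        if missing:
            raise ValueError(f"missing codons: {sorted(missing)}")
        counts = CodonCounts(
            counts={c: int(round(v)) for c, v in values.items()}, source_id=name
        )
        profile = usage_metrics.rscu(counts)
        return HostUsageTable(cell_type=name, codon_values=dict(profile.values))
    return HostUsageTable(cell_type=name, codon_values=values)


def write_host_table(table: HostUsageTable, path: str | Path) -> None:
    series = table.as_series()
    frame = pd.DataFrame({"codon": series.index, table.cell_type: series.values})
    frame.to_csv(path, index=False)


def _is_at_ending(codon: str) -> bool:
    return codon[2] in "AT"


def at_ending_fraction(source: HostUsageTable | CodonCounts) -> float:
    """Percentage of synonymous-codon usage ending in A or T.

    For codon counts this is the share of synonymous occurrences whose
    third base is A or T. For an RSCU-only table (no counts available) it
    is the RSCU-weighted share: within each family, the summed RSCU of
    A/T-ending synonyms over the degeneracy D gives that family's A/T-ending
    occurrence fraction, and families are weighted equally.
    """
    if isinstance(source, CodonCounts):
        total = sum(source.get(c) for c in SYNONYMOUS_CODONS)
        if total == 0:
            raise ValueError("no synonymous-codon occurrences")
        at = sum(source.get(c) for c in SYNONYMOUS_CODONS if _is_at_ending(c))
        return 100.0 * at / total
    fractions = []
    for aa in usage_metrics.DEGENERATE_AMINO_ACIDS:
        family = STANDARD_CODE.synonym_families[aa]
        d = STANDARD_CODE.degeneracy[aa]
        at_mass = sum(source.codon_values[c] for c in family if _is_at_ending(c))
        fractions.append(at_mass / d)
    return 100.0 * sum(fractions) / len(fractions)
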