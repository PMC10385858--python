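"""End-to-end orchestration of the codon-usage trend analysis.

One call to :func:`run_codon_analysis` takes a FASTA panel plus a region
manifest (and optionally host usage tables) and produces the full report
bundle: per-taxon RSCU / effective number of codons / positional
composition, the RSCU PCA with PC1 anchored to third-position A+T content,
the per-codon correlation screen, position-wise PC1-composition
correlations, group composition summaries with the two-sample t, per-taxon
host-cell correlations with Hotelling comparisons, and the amino-acid PCA
with chi-square group contrasts. All outputs are plain TSV, deterministic
for a fixed config, and stamped with the tool version and a config hash.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .assoc_stats import chisq_2x2, hotelling_dependent_t, pearson_with_t, two_sample_t
from .genetic_code import CodonCounts, positional_composition
from .multivariate import UsageMatrix, orient_component, pca, screen_features
from .sequence_ingest import (
    HostUsageTable,
    at_ending_fraction,
    coding_counts,
    gene_counts,
    load_host_table,
    read_fasta,
    read_manifest,
)
from .usage_metrics import (
    amino_acid_composition,
    effective_number_of_codons,
    profiles_to_frame,
    rscu,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_codon_analysis", "run_gene_level_correlations"]

_POSITION_RULES = {
    1: "first-nonsynonymous",
    2: "second-all-synonymous",
    3: "third-synonymous",
}


@dataclass
class RunConfig:
    """Configuration of one analysis run; CLI flags mirror these fields."""

    manifest: str | Path
    fasta: str | Path
    host_tables: dict[str, str | Path] = field(default_factory=dict)
    center: bool = True
    scale: bool = False
    t_cutoff: float = 4.84
    n_components: int = 2
    out_dir: str | Path | None = None
    seed: int = 0
    log_level: str = "INFO"

    def config_hash(self) -> str:
        payload = {
            "manifest": str(self.manifest),
            "fasta": str(self.fasta),
            "host_tables": {k: str(v) for k, v in sorted(self.host_tables.items())},
            "center": self.center,
            "scale": self.scale,
            "t_cutoff": self.t_cutoff,
            "n_components": self.n_components,
            "seed": self.seed,
        }
        digest = hashlib.sha256(json.dumps(payload, sort_keys=True).encode())
        return digest.hexdigest()[:12]


def _write(frame: pd.DataFrame, path: Path, stamp: str, index: bool = True) -> None:
    with open(path, "w") as fh:
        fh.write(f"# codontrend {__version__} config={stamp}\n")
        frame.to_csv(fh, sep="\t", index=index)


def _load_panel(config: RunConfig) -> tuple[list[CodonCounts], list[str], list[str]]:
    entries = read_manifest(config.manifest)
    seqs = read_fasta(config.fasta)
    counts_list, taxa, groups = [], [], []
    for entry in entries:
        if entry.record_id not in seqs:
            raise KeyError(f"manifest record {entry.record_id!r} not in FASTA")
        counts_list.append(coding_counts(seqs[entry.record_id], entry))
        taxa.append(entry.record_id)
        groups.append(entry.group)
    return counts_list, taxa, groups


def _load_hosts(config: RunConfig) -> dict[str, HostUsageTable]:
    hosts = {}
    for label, path in config.host_tables.items():
        hosts[label] = load_host_table(path, format="rscu", cell_type=label)
    return hosts


def _composition_frame(counts_list: list[CodonCounts], taxa: list[str]) -> pd.DataFrame:
    rows = []
    for counts in counts_list:
        row = {}
        for pos, rule in _POSITION_RULES.items():
            prof = positional_composition(counts, pos, rule)
            for key, val in prof.pct.items():
                row[f"pos{pos}_{key}"] = val
        rows.append(row)
    return pd.DataFrame(rows, index=pd.Index(taxa, name="taxon"))


def run_codon_analysis(config: RunConfig) -> dict[str, pd.DataFrame]:
    """Run the full codon-usage trend analysis; returns the report bundle.

    The bundle maps table names to DataFrames; when ``config.out_dir`` is
    set, each table is also written as ``<out_dir>/<name>.tsv`` with a
    version/config-hash header line.
    """
    stamp = config.config_hash()
    counts_list, taxa, groups = _load_panel(config)
    hosts = _load_hosts(config)
    group_series = pd.Series(groups, index=taxa, name="group")
    group_order = list(dict.fromkeys(groups))
    multi_group = len(group_order) >= 2

    # --- per-taxon usage statistics -------------------------------------
    rscu_profiles = [rscu(c) for c in counts_list]
    rscu_frame = profiles_to_frame(rscu_profiles)
    rscu_frame.index = pd.Index(taxa, name="taxon")
    usage = pd.DataFrame(
        {
            "group": groups,
            "total_codons": [c.total for c in counts_list],
            "enc": [effective_number_of_codons(c).nc for c in counts_list],
            "at_ending_pct": [at_ending_fraction(c) for c in counts_list],
        },
        index=pd.Index(taxa, name="taxon"),
    )
    composition = _composition_frame(counts_list, taxa)

    # --- RSCU PCA, anchored to AT3, plus the codon screen ----------------
    at3 = composition["pos3_A+T"].to_numpy()
    matrix = UsageMatrix(rscu_frame, kind="rscu")
    pca_input = matrix.drop_incomplete_columns()
    result = pca(pca_input, center=config.center, scale=config.scale)
    result = orient_component(result, 0, at3, anchor_name="A+T3")
    k = min(config.n_components, result.scores.shape[1])
    scores = result.scores_frame().iloc[:, :k]
    scores.insert(0, "group", groups)
    scores.index.name = "taxon"
    variance = pd.DataFrame(
        {
            "component": [f"PC{i + 1}" for i in range(len(result.variance_fraction))],
            "variance_fraction": result.variance_fraction,
        }
    )
    pc1 = result.scores[:, 0]
    screen = screen_features(matrix, pc1, t_cutoff=config.t_cutoff)

    # --- Table-1-style position-wise PC1 correlations --------------------
    pos_rows = []
    for pos in (1, 2, 3):
        for key in ("A", "T", "G", "C", "A+T", "G+C"):
            res = pearson_with_t(pc1, composition[f"pos{pos}_{key}"].to_numpy())
            pos_rows.append(
                {
                    "position": pos,
                    "rule": _POSITION_RULES[pos],
                    "base": key,
                    "r": res.r,
                    "t": res.t,
                    "p": res.p,
                    "n": res.n,
                }
            )
    position_correlations = pd.DataFrame(pos_rows)

    # --- group summaries of AT3: mean-of-taxa and pooled-count variants --
    group_rows = []
    for g in group_order:
        members = [i for i, grp in enumerate(groups) if grp == g]
        vals = at3[members]
        pooled = CodonCounts()
        for i in members:
            pooled = pooled + counts_list[i]
        pooled_at3 = positional_composition(pooled, 3, "third-synonymous").pct["A+T"]
        group_rows.append(
            {
                "group": g,
                "n_taxa": len(members),
                "at3_mean": float(np.mean(vals)),
                "at3_sd": float(np.std(vals, ddof=1)) if len(members) > 1 else 0.0,
                "at3_pooled": pooled_at3,
                "pc1_mean": float(np.mean(pc1[members])),
            }
        )
    group_summary = pd.DataFrame(group_rows)
    group_tests = pd.DataFrame(
        columns=["group_a", "group_b", "statistic", "t", "df", "p"]
    )
    if multi_group:
        first, last = group_order[0], group_order[-1]
        a = at3[[i for i, g in enumerate(groups) if g == first]]
        b = at3[[i for i, g in enumerate(groups) if g == last]]
        if a.size >= 2 and b.size >= 2:
            t, df, p = two_sample_t(a, b)
            group_tests = pd.DataFrame(
                [
                    {
                        "group_a": first,
                        "group_b": last,
                        "statistic": "at3_two_sample_t",
                        "t": t,
                        "df": df,
                        "p": p,
                    }
                ]
            )
    else:
        logger.info("single group in manifest; group-comparison stages skipped")

    # --- host-cell correlations and Hotelling comparisons ----------------
    host_corr = pd.DataFrame()
    hotelling = pd.DataFrame()
    if hosts:
        host_series = {label: tab.as_series() for label, tab in hosts.items()}
        corr_rows = []
        for taxon, profile in zip(taxa, rscu_profiles):
            virus = profile.as_series()
            for label, hs in host_series.items():
                res = pearson_with_t(virus.to_numpy(), hs.to_numpy())
                corr_rows.append(
                    {
                        "taxon": taxon,
                        "group": group_series[taxon],
                        "cell_type": label,
                        "r": res.r,
                        "t": res.t,
                        "p": res.p,
                        "n": res.n,
                    }
                )
        host_corr = pd.DataFrame(corr_rows)
        hot_rows = []
        labels = list(host_series)
        for taxon, profile in zip(taxa, rscu_profiles):
            virus = profile.as_series().to_numpy()
            for la, lb in combinations(labels, 2):
                ra = pearson_with_t(virus, host_series[la].to_numpy())
                rb = pearson_with_t(virus, host_series[lb].to_numpy())
                rab = pearson_with_t(
                    host_series[la].to_numpy(), host_series[lb].to_numpy()
                )
                res = hotelling_dependent_t(ra.r, rb.r, rab.r, n=ra.n)
                hot_rows.append(
                    {
                        "taxon": taxon,
                        "cell_type_a": la,
                        "cell_type_b": lb,
                        "r_a": ra.r,
                        "r_b": rb.r,
                        "r_ab": rab.r,
                        "t": res.t,
                        "df": res.df,
                        "p": res.p,
                    }
                )
        hotelling = pd.DataFrame(hot_rows)

    # --- amino-acid composition PCA and chi-square contrasts -------------
    aa_profiles = [amino_acid_composition(c) for c in counts_list]
    aa_frame = pd.DataFrame(
        [p.as_series() for p in aa_profiles], index=pd.Index(taxa, name="taxon")
    )
    aa_result = pca(
        UsageMatrix(aa_frame, kind="aa-composition"),
        center=config.center,
        scale=config.scale,
    )
    aa_result = orient_component(
        aa_result, 0, aa_frame["I"].to_numpy(), anchor_name="Ile content"
    )
    aa_scores = aa_result.scores_frame().iloc[:, :k]
    aa_scores.insert(0, "group", groups)
    aa_scores.index.name = "taxon"
    aa_variance = pd.DataFrame(
        {
            "component": [
                f"PC{i + 1}" for i in range(len(aa_result.variance_fraction))
            ],
            "variance_fraction": aa_result.variance_fraction,
        }
    )
    aa_screen = screen_features(
        UsageMatrix(aa_frame, kind="aa-composition"),
        aa_result.scores[:, 0],
        t_cutoff=config.t_cutoff,
    )
    aa_chisq = pd.DataFrame(
        columns=["amino_acid", "group_a", "group_b", "pct_a", "pct_b", "chi2", "df", "p"]
    )
    if multi_group:
        first, last = group_order[0], group_order[-1]
        pooled = {}
        for g in (first, last):
            tot = CodonCounts()
            for i, grp in enumerate(groups):
                if grp == g:
                    tot = tot + counts_list[i]
            pooled[g] = amino_acid_composition(tot)
        chisq_rows = []
        for aa in ("I", "S", "Y", "L"):
            pa, pb = pooled[first], pooled[last]
            n_a = int(round(pa.pct[aa] / 100.0 * pa.total_aa))
            n_b = int(round(pb.pct[aa] / 100.0 * pb.total_aa))
            res = chisq_2x2(n_a, pa.total_aa - n_a, n_b, pb.total_aa - n_b)
            chisq_rows.append(
                {
                    "amino_acid": aa,
                    "group_a": first,
                    "group_b": last,
                    "pct_a": pa.pct[aa],
                    "pct_b": pb.pct[aa],
                    "chi2": res.chi2,
                    "df": res.df,
                    "p": res.p,
                }
            )
        aa_chisq = pd.DataFrame(chisq_rows)

    bundle: dict[str, pd.DataFrame] = {
        "rscu": rscu_frame,
        "usage": usage,
        "composition": composition,
        "pca_scores": scores,
        "pca_loadings": result.loadings_frame().iloc[:k],
        "pca_variance": variance,
        "codon_screen": screen.table,
        "position_correlations": position_correlations,
        "group_summary": group_summary,
        "group_tests": group_tests,
        "host_correlations": host_corr,
        "hotelling": hotelling,
        "aa_composition": aa_frame,
        "aa_pca_scores": aa_scores,
        "aa_pca_variance": aa_variance,
        "aa_screen": aa_screen.table,
        "aa_chisq": aa_chisq,
    }
    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        indexed = {
            "rscu", "usage", "composition", "pca_scores", "pca_loadings",
            "aa_composition", "aa_pca_scores",
        }
        for name, frame in bundle.items():
            _write(frame, out / f"{name}.tsv", stamp, index=name in indexed)
    return bundle


def run_gene_level_correlations(
    config: RunConfig,
    gene_partition: Mapping[str, Sequence[str]],
) -> pd.DataFrame:
    """Per-gene (and pooled gene-set) virus-host RSCU correlations.

    ``gene_partition`` maps a report label to the manifest gene tags pooled
    under it, e.g. ``{"gag": ["gag"], "accessory": ["tat", "rev", ...]}``.
    Pooling sums raw codon counts over the member genes before computing
    RSCU (equivalent to concatenating the sequences), never averages
    per-gene RSCU vectors.
    """
    entries = read_manifest(config.manifest)
    seqs = read_fasta(config.fasta)
    hosts = _load_hosts(config)
    if not hosts:
        raise ValueError("gene-level correlations require host tables")
    host_series = {label: tab.as_series() for label, tab in hosts.items()}
    rows = []
    for entry in entries:
        per_gene = gene_counts(seqs[entry.record_id], entry)
        for label, members in gene_partition.items():
            missing = [g for g in members if g not in per_gene]
            if missing:
                raise KeyError(
                    f"{entry.record_id}: gene tag(s) {missing} absent from manifest"
                )
            pooled = CodonCounts()
            for g in members:
                pooled = pooled + per_gene[g]
            virus = rscu(pooled).as_series().to_numpy()
            for cell_type, hs in host_series.items():
                res = pearson_with_t(virus, hs.to_numpy())
                rows.append(
                    {
                        "taxon": entry.record_id,
                        "group": entry.group,
                        "gene_set": label,
                        "cell_type": cell_type,
                        "r": res.r,
                        "t": res.t,
                        "p": res.p,
                        "n": res.n,
                    }
                )
    report = pd.DataFrame(rows)
    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        _write(report, out / "gene_level_correlations.tsv", config.config_hash(), index=False)
    return report
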