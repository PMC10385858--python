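#!/usr/bin/env python
"""PCA trend extraction: codon usage and amino-acid composition.

Runs the RSCU PCA with PC1 anchored to third-position A+T content, the
per-codon correlation screen at the stringent t cutoff, the Table-style
position-wise PC1-composition correlations, the between-extreme-groups
two-sample t for AT3, and the amino-acid-composition PCA with chi-square
contrasts of Ile/Ser/Tyr/Leu. Writes the multivariate tables of the report
bundle to results/bundle/.
"""

import argparse
import importlib.util
from pathlib import Path

from codontrend import run_codon_analysis
from codontrend.assoc_stats import pearson_with_t

_spec = importlib.util.spec_from_file_location(
    "codon_usage_driver", Path(__file__).parent / "02_codon_usage.py"
)
_mod = importlib.util.module_from_spec(_spec)
_spec.loader.exec_module(_mod)
build_config = _mod.build_config


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--data", type=Path, default=Path("results/data"))
    parser.add_argument("--out", type=Path, default=Path("results/bundle"))
    args = parser.parse_args()

    bundle = run_codon_analysis(build_config(args.data, args.out))
    var = bundle["pca_variance"]["variance_fraction"]
    scores = bundle["pca_scores"]
    at3 = bundle["composition"]["pos3_A+T"]
    r = pearson_with_t(scores["PC1"].to_numpy(), at3.to_numpy())
    print(f"RSCU PCA: PC1 {100 * var.iloc[0]:.1f}% of variance, "
          f"PC2 {100 * var.iloc[1]:.1f}%")
    print(f"  corr(PC1, AT3): r = {r.r:.2f} (t = {r.t:.2f}, n = {r.n})")
    screen = bundle["codon_screen"]
    pos = screen[screen["set"] == "positive"]["feature"]
    neg = screen[screen["set"] == "negative"]["feature"]
    print(f"  codon screen at |t| > 4.84: {len(pos)} positive "
          f"({sum(c[2] in 'AT' for c in pos)} A/T-ending), "
          f"{len(neg)} negative ({sum(c[2] in 'GC' for c in neg)} G/C-ending)")
    for row in bundle["group_tests"].itertuples(index=False):
        print(f"  AT3 {row.group_a} vs {row.group_b}: t = {row.t:.2f}, "
              f"df = {row.df:.0f}, p = {row.p:.2g}")
    aa_var = bundle["aa_pca_variance"]["variance_fraction"]
    print(f"amino-acid PCA: PC1 {100 * aa_var.iloc[0]:.1f}%, "
          f"PC2 {100 * aa_var.iloc[1]:.1f}%")
    for row in bundle["aa_chisq"].itertuples(index=False):
        print(f"  {row.amino_acid}: {row.pct_a:.1f}% vs {row.pct_b:.1f}% "
              f"(chi2 = {row.chi2:.2f}, p = {row.p:.2g})")


if __name__ == "__main__":
    main()
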