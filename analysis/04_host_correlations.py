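#!/usr/bin/env python
"""Virus-host codon-usage correlations and Hotelling comparisons.

Correlates each taxon's RSCU with the monocyte-, B-cell- and T-cell-like
usage tables, tests per taxon whether the monocyte correlation exceeds each
lymphocyte correlation (Hotelling's test for dependent correlations), and
repeats the correlation per gene (gag, pol, env, pooled accessory). Writes
the host-correlation tables of the bundle plus the gene-level report to
results/bundle/.
"""

import argparse
import importlib.util
from pathlib import Path

from codontrend import run_codon_analysis, run_gene_level_correlations

_spec = importlib.util.spec_from_file_location(
    "codon_usage_driver", Path(__file__).parent / "02_codon_usage.py"
)
_mod = importlib.util.module_from_spec(_spec)
_spec.loader.exec_module(_mod)
build_config = _mod.build_config

GENE_PARTITION = {
    "gag": ["gag"],
    "pol": ["pol"],
    "env": ["env"],
    "accessory": ["accessory"],
}


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--data", type=Path, default=Path("results/data"))
    parser.add_argument("--out", type=Path, default=Path("results/bundle"))
    args = parser.parse_args()

    config = build_config(args.data, args.out)
    bundle = run_codon_analysis(config)
    corr = bundle["host_correlations"]
    print("per-taxon RSCU correlation with host usage:")
    for cell, sub in corr.groupby("cell_type"):
        print(f"  {cell:9s} mean r = {sub['r'].mean():+.2f} "
              f"(sd {sub['r'].std():.2f})")
    wide = corr.pivot(index="taxon", columns="cell_type", values="r")
    wins = int((wide["monocyte"] > wide[["b_cell", "t_cell"]].max(axis=1)).sum())
    print(f"  monocyte-like table is the best correlate for {wins}/{len(wide)} taxa")
    hot = bundle["hotelling"]
    sig = hot[(hot["cell_type_a"] == "monocyte") & (hot["p"] < 0.05) & (hot["t"] > 0)]
    print(f"  Hotelling: monocyte significantly higher in "
          f"{len(sig)}/{len(hot[hot['cell_type_a'] == 'monocyte'])} comparisons")

    report = run_gene_level_correlations(config, GENE_PARTITION)
    print("gene-level mean r with host usage:")
    for (gene, cell), sub in report.groupby(["gene_set", "cell_type"]):
        print(f"  {gene:9s} vs {cell:9s} r = {sub['r'].mean():+.2f}")


if __name__ == "__main__":
    main()
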