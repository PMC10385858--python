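# codontrend

Codon-usage and amino-acid-composition trend analysis for viral coding
regions, built around the questions raised by primate lentiviruses (SIV,
HIV-1, HIV-2): do related virus lineages show a directed trend in their use
of synonymous codons, does that trend extend to nonsynonymous positions and
hence amino-acid composition, and does viral codon usage track the usage of
genes expressed in particular host cell types?

The package is aimed at molecular-evolution researchers who have a panel of
genome sequences with known coding intervals and want the full chain of
statistics from raw codon counts to multivariate trend tests, with every
step reproducible and testable offline on synthetic panels.

## The statistics at its core

For a coding region with codon counts `N_codon`, grouped into amino-acid
families with counts `N_aa` and degeneracy `D ∈ {2, 3, 4, 6}`:

* **RSCU** (relative synonymous codon usage):
  `RSCU = (N_codon / N_aa) × D` — 1 under uniform synonym usage, `D` under
  exclusive preference. Computed over the 59 synonymous codons (61 sense
  codons minus ATG and TGG).
* **Nc** (effective number of codons, Wright's estimator): per-family
  homozygosity `F̂ = (n Σ p̂² − 1)/(n − 1)` averaged within degeneracy
  classes, then `Nc = 2 + 9/F̄₂ + 1/F̄₃ + 5/F̄₄ + 3/F̄₆`, capped into
  [20, 61]. 20 means one codon per amino acid; 61 means no bias.
* **Positional composition**: occurrence-weighted % A/T/G/C at codon
  positions 1–3. First-position analyses exclude the eight Arg/Leu synonyms
  (AGA, CGA, AGG, CGG, TTA, CTA, TTG, CTG) whose first-position
  substitutions can be silent.
* **PCA trend extraction**: covariance PCA of the taxa × 59 RSCU matrix
  (or taxa × 18 amino-acid matrix), with PC1's arbitrary sign anchored to
  an external covariate (third-position A+T for codon usage, Ile content
  for amino acids), plus a per-feature Pearson screen at a stringent
  t cutoff (default 4.84, ≈ p = 10⁻⁵).
* **Virus–host comparison**: Pearson r between a virus's RSCU vector and a
  host cell type's usage table, with Hotelling's t for two dependent
  correlations, `t = (r₁₂ − r₁₃)·√[(n−3)(1+r₂₃)] / √(2|R|)`, df = n − 3,
  to test whether one cell type correlates significantly better than
  another.

## Worked example

The repository is organised as an analysis project: numbered drivers under
`analysis/` run the pipeline on a synthetic study panel whose structure
mirrors the real one (8 groups from monkey-infecting SIV to pandemic HIV-1
group M, third-position A+T rising 65.4% → 70.4%, Ile/Ser enriched and
Tyr/Leu depleted along the gradient, 54 taxa × 8000 codons), plus
monocyte-like (53.4% A/T-ending), B-cell-like (45.2%) and T-cell-like
(46.7%) host usage tables.

```
python analysis/01_simulate_panel.py --seed 1   # writes results/data/
python analysis/02_codon_usage.py               # writes results/bundle/
python analysis/03_pca_trend.py
python analysis/04_host_correlations.py
```

Output of the last two (seed 1):

```
RSCU PCA: PC1 22.8% of variance, PC2 6.5%
  corr(PC1, AT3): r = 0.99 (t = 51.86, n = 54)
  codon screen at |t| > 4.84: 8 positive (8 A/T-ending), 11 negative (11 G/C-ending)
  AT3 SIV-monkey vs HIV-1-M: t = -27.51, df = 29, p = 2.5e-22
amino-acid PCA: PC1 27.7%, PC2 10.5%
  I: 7.2% vs 8.2% (chi2 = 78.02, p = 1e-18)
  ...
per-taxon RSCU correlation with host usage:
  b_cell    mean r = -0.67 (sd 0.03)
  monocyte  mean r = +0.68 (sd 0.03)
  t_cell    mean r = -0.55 (sd 0.04)
  monocyte-like table is the best correlate for 54/54 taxa
  Hotelling: monocyte significantly higher in 108/108 comparisons
```

Reading this: PC1 of the RSCU matrix recovers the built-in third-position
A+T gradient almost perfectly (r = 0.99); every codon the screen selects as
positively trending ends in A/T and every negative one in G/C; the
between-extreme-groups difference in A+T content is decisive; and the
monocyte-like host table out-correlates both lymphocyte-like tables for
every taxon, each time significantly by Hotelling's test. The same chain of
inferences, run on real accession panels, is how the underlying biological
question (virus–cell-type codon adaptation) is addressed.

The same machinery is exposed as a CLI (`codontrend run-all`,
`codontrend simulate-panel`, `codontrend screen`, ... — see
`codontrend --help`) and as an importable library (`import codontrend`).

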