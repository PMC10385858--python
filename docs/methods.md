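# Methods

This note records the statistical model and procedures implemented in
`codontrend`, the conventions and tunable parameters that matter, what the
synthetic-data generator does and does not emulate, and the design choices
made where the design was genuinely open.

## Codon counting and composition

Coding sequences are read in frame from FASTA plus a region manifest of
1-based inclusive intervals (GenBank convention) with optional exclusion
spans (e.g., a structured RNA element inside a gene). Internally all
arithmetic is 0-based half-open. Each interval is validated independently
with strict stop handling — a stop triplet before the interval's last
position is an error, so a frame slip cannot pass silently — and a
terminal stop is tallied separately, never counted as a sense codon.
Whether gene-terminal stops are kept or dropped is immaterial for the
multi-kilobase regions this package targets (one codon in thousands), but
the convention is fixed and tested. Triplets containing any non-ACGT
symbol are skipped whole and tallied, never partially counted, so every
composition denominator is consistent. Only the standard genetic code
(translation table 1) is exposed: the package targets primate/retroviral
sense-strand coding regions, where no other table applies.

Positional composition is occurrence-weighted: each codon occurrence
contributes its base at the chosen position, making the result a property
of the sequence rather than of the codon inventory. Third- and
second-position analyses use all 59 synonymous codons; first-position
analyses exclude the eight Arg/Leu synonyms {AGA, CGA, AGG, CGG, TTA, CTA,
TTG, CTG} so that the first position is purely nonsynonymous. (By brute
force over the 59 synonyms, 8 of 177 possible first-position substitutions
are silent, ≈ 4.5%; the exclusion removes exactly those.)

## RSCU and the effective number of codons

RSCU(c) = (N_c / N_aa) · D for each synonymous codon. Families with zero
observations are flagged *undefined* rather than being assigned an
artificial value; flagged codons become NaN in matrix form and are
excluded pairwise from correlations (never imputed), so degenerate inputs
cannot inject fake zeros into r.

Nc follows Wright's class-averaged homozygosity estimator. Per family with
n ≥ 2, F̂ = (n Σ p̂² − 1)/(n − 1); families with n < 2 or F̂ ≤ 0 are dropped
from their class mean; the single 3-fold family (Ile), if unusable, has F̄₃
imputed as (F̄₂ + F̄₄)/2. The 6-fold families (Leu, Arg, Ser) are treated as
single 6-fold families, not split 4+2 — the 2 + 9 + 1 + 5 + 3 = 20 class
structure of the formula requires it. The raw estimate can exceed 61 in
finite samples (uniform usage at 1000 counts/codon gives 61.04); the
returned value is capped into the statistic's theoretical range [20, 61],
with the raw value retained. Note the estimator's finite-sample bias is
approximately 130/n effective codons for near-uniform usage at n counts
per family, so scale-invariance holds only in the large-n limit (counts in
the low thousands per family for a 0.05 tolerance); panel taxa at 8000
codons sit near that regime.

Amino-acid composition is reported over the 18 degenerate families only
(Met and Trp excluded from numerator and denominator), keeping profiles
comparable to the 59-codon RSCU universe; the 18-dimensional convention is
explicit in the type so it cannot be silently mixed with 20-dimensional
profiles.

## PCA and the correlation screen

PCA is performed on the column-centered data matrix (covariance PCA) by
default; `scale=True` switches to correlation PCA. RSCU columns share a
common scale, which is why unscaled is the default, but variance fractions
are preprocessing-sensitive, so both flags are exposed and recorded in
every output. Both orientations (taxa as observations, or the transposed
matrix with codons as observations) are supported; orientation is always
an explicit argument. Components carry a canonical sign
(largest-magnitude loading positive) for determinism, and
`orient_component` then anchors a component to an external covariate —
PC1 is anchored to third-position A+T for RSCU matrices and to Ile content
for amino-acid matrices — flipping it iff the correlation with the anchor
is negative (idempotent by construction).

The screen correlates each feature with a component score using pairwise
exclusion of undefined entries; t = r√(n−2)/√(1−r²) with two-sided p.
The selection cutoff is a user parameter with default t = 4.84, a very
stringent level (≈ p = 10⁻⁵ at the panel sizes involved); it is treated as
a given constant rather than re-derived from a p-value, because the
degrees of freedom such a derivation should use (features vs taxa) is
ambiguous in the transposed-orientation analyses.

**Selection effect.** Screening PC1 against the very features PCA was
fitted on is not a calibrated null procedure: PC1 maximises alignment with
the sample covariance, and within a family RSCU values are exactly linearly
dependent (they sum to D), so even on panels with *no* group structure PC1
aligns with some family's sampling noise and the screen typically selects
1–3 codons at t > 4.84 regardless of sequencing depth or panel size. The
cutoff does control false selection against covariates independent of the
panel (tested: 0 selections in ≥ 95% of null seeds). Screen output on
observational panels should therefore be read as a ranking of
trend-associated codons, not as a family-wise error-controlled test.

## Inferential toolkit

* Pearson r with its t test (df = n − 2, two-sided). |r| = 1 (to within
  1e-12, i.e., numerically collinear input) is reported with sentinels
  t = ±∞, p = 0 rather than as an error, because degenerate synthetic
  fixtures legitimately produce it.
* Hotelling's (1940) t for two dependent correlations sharing a variable,
  df = n − 3; the implied 3×3 correlation matrix must be positive
  definite. Williams' modification is available as an option for small n.
  The default variant's type-I error at n = 59 is calibrated to
  0.05 ± 0.01 in the test suite (10,000-replicate Monte Carlo).
* 2×2 contingency chi-square without continuity correction by default (the
  pooled amino-acid counts this package compares are in the thousands,
  where Yates' correction is negligible); a flag enables it. The
  amino-acid contrast compares, for one amino acid, (count of that amino
  acid vs all others) × (group A vs group B), with groups pooled by
  summing member taxa's raw codon counts — "overall content" as pooled
  counts, not mean of percentages; group summaries report both variants
  side by side because the two conventions differ in how they weight
  unequal-length genomes.
* Two-sample Student t (pooled variance; Welch optional).
* p-values are two-sided throughout; no multiple-testing correction is
  applied anywhere (the workflow reports a small, pre-specified set of
  tests; users running many contrasts should correct externally).

## Synthetic data generator

The generator emulates exactly the statistical structure the analysis
consumes: groups of taxa whose codons are drawn i.i.d. with, per
amino-acid family, probability mass `target_AT3` spread uniformly over the
A/T-ending synonyms and the rest over the G/C-ending synonyms. Since every
degenerate family of the standard code has both kinds of synonym, the
expected occurrence-weighted AT3 equals the target exactly, independent of
amino-acid frequencies. Amino-acid frequencies follow a base distribution
(uniform over the 18 families by default; a lentivirus-like Ile/Ser-rich
preset is included) multiplied by per-group shift weights.

The default study panel has 8 groups in trend order (monkey-infecting SIV
through pandemic HIV-1 group M) totalling 54 taxa at 8000 codons each,
with AT3 targets linearly spaced 65.4% → 70.4% — the group means and
endpoints of the real-data gradient — and an amino-acid drift with
endpoint ratios Ile 6.7→7.8%, Ser 4.4→5.2%, Tyr 3.7→3.1%, Leu 8.6→8.2%.
Host tables are multinomial draws (200,000 codons) at a target A/T-ending
share: 53.4% (monocyte-like), 45.2% (B-cell-like), 46.7% (T-cell-like).
All generator outputs are pure functions of their spec, seed included, and
are written in the exact formats the readers consume, so synthetic runs
exercise the real I/O paths.

What the generator does *not* emulate — and hence what passing tests do
not show about real data: phylogenetic correlation between taxa (taxa are
independent draws, so between-group tests are anti-conservative relative
to a phylogenetically structured panel), positional autocorrelation and
RNA-structure constraints (e.g., conserved structural elements that pin
silent positions), overlapping reading frames, CpG suppression, and
indels. Real-data effect sizes also differ: the synthetic host tables have
family-balanced usage, which makes lymphocyte-like correlations clearly
negative where real transcriptome tables give near-zero correlations.

With one single-taxon group and adjacent groups spaced ~0.7 AT3 points
(per-taxon sampling noise ~0.5 points at 8000 codons), occasional
adjacent-group rank swaps in mean PC1 are expected and observed in roughly
a third of seeds; recovery is asserted as near-perfect rank agreement
(Spearman ρ ≥ 0.9 every seed, mean ≥ 0.97, endpoints always ordered)
rather than perfect ordering.

## Problem sizes used in the checks

The test suite and drivers run entirely on synthetic panels: the 54-taxon,
8000-codon study panel for recovery checks; 24-taxon, 1500-codon panels
(20 seeds) for null-screen behaviour; 10,000 Monte-Carlo replicates at
n = 59 for the Hotelling calibration. These sizes give sampling noise well
inside the asserted margins while keeping a full run in seconds.

## Known limitations

* Variance fractions from PCA depend on the center/scale choice; when
  comparing against published values with unstated preprocessing, expect
  tolerance-level agreement only.
* Wright's Nc is reported in its original form; later bias-corrected
  variants are out of scope and will differ in the second decimal at
  typical depths.
* The loader for host usage tables accepts RSCU or raw counts; for
  RSCU-only tables, the A/T-ending share is an RSCU-weighted,
  equal-family-weight approximation of the occurrence share (exact only
  under uniform amino-acid usage).
* No ORF detection or GenBank feature parsing: coordinates come from the
  manifest, and the forward strand only.
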