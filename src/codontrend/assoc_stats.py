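"""Inferential toolkit: Pearson correlation with its t test, Hotelling's
test for two dependent correlations, 2x2 contingency chi-square, and the
two-sample Student t.

The Hotelling test asks whether two Pearson correlations r12 and r13 that
share variable 1 (e.g., a virus's codon usage correlated with two host cell
types) differ, accounting for the correlation r23 between the two non-shared
variables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "CorrelationResult",
    "HotellingResult",
    "ChiSquareResult",
    "pearson_with_t",
    "hotelling_dependent_t",
    "chisq_2x2",
    "two_sample_t",
]


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    n: int
    t: float
    df: int
    p: float


@dataclass(frozen=True)
class HotellingResult:
    r12: float
    r13: float
    r23: float
    n: int
    t: float
    df: int
    p: float
    variant: str = "hotelling-1940"


@dataclass(frozen=True)
class ChiSquareResult:
    chi2: float
    df: int
    p: float
    table: tuple[tuple[int, int], tuple[int, int]]


def t_from_r(r: float, n: int) -> float:
    """Student t for a Pearson correlation: t = r sqrt(n-2) / sqrt(1-r^2).

    Returns signed infinity for |r| = 1 (degenerate, perfectly collinear
    input, up to floating-point roundoff) rather than raising.
    """
    if abs(r) >= 1.0 - 1e-12:
        return math.copysign(math.inf, r)
    return r * math.sqrt(n - 2) / math.sqrt(1.0 - r * r)


def pearson_with_t(x, y) -> CorrelationResult:
    """Pearson product-moment correlation with its two-sided t test.

    NaN pairs are excluded pairwise before computing r (used for codons
    whose RSCU is undefined in one of the two profiles).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    n = x.size
    if n < 4:
        raise ValueError(f"need at least 4 paired observations, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in x or y")
    r = float(stats.pearsonr(x, y).statistic)
    t = t_from_r(r, n)
    if math.isinf(t):
        p = 0.0
    else:
        p = float(2.0 * stats.t.sf(abs(t), n - 2))
    return CorrelationResult(r=r, n=n, t=t, df=n - 2, p=p)


def hotelling_dependent_t(
    r12: float, r13: float, r23: float, n: int, variant: str = "hotelling-1940"
) -> HotellingResult:
    """Test whether two dependent correlations sharing variable 1 differ.

    The 1940 statistic is

        t = (r12 - r13) sqrt((n-3)(1+r23)) / sqrt(2 |R|),

    with |R| = 1 - r12^2 - r13^2 - r23^2 + 2 r12 r13 r23 the determinant of
    the 3x3 correlation matrix, referred to Student's t with n-3 degrees of
    freedom. ``variant="williams"`` applies Williams' modification, which is
    better calibrated for small n.
    """
    if n <= 3:
        raise ValueError("need n > 3")
    for name, r in (("r12", r12), ("r13", r13), ("r23", r23)):
        if not -1.0 < r < 1.0:
            raise ValueError(f"{name}={r} outside (-1, 1)")
    det = 1.0 - r12**2 - r13**2 - r23**2 + 2.0 * r12 * r13 * r23
    if det <= 0.0:
        raise ValueError(
            "correlation triple is not positive definite "
            f"(|R| = {det:.3g} <= 0)"
        )
    df = n - 3
    if variant == "hotelling-1940":
        t = (r12 - r13) * math.sqrt((n - 3) * (1.0 + r23)) / math.sqrt(2.0 * det)
    elif variant == "williams":
        r_bar = 0.5 * (r12 + r13)
        denom = (
            2.0 * det * (n - 1) / (n - 3) + r_bar**2 * (1.0 - r23) ** 3
        )
        t = (r12 - r13) * math.sqrt((n - 1) * (1.0 + r23) / denom)
    else:
        raise ValueError(f"unknown variant {variant!r}")
    p = float(2.0 * stats.t.sf(abs(t), df))
    return HotellingResult(
        r12=r12, r13=r13, r23=r23, n=n, t=t, df=df, p=p, variant=variant
    )


def chisq_2x2(
    a: int, b: int, c: int, d: int, continuity: bool = False
) -> ChiSquareResult:
    """Pearson chi-square for the 2x2 table [[a, b], [c, d]], df = 1.

    Continuity (Yates) correction is off by default; the counts in the
    analyses this package targets are large enough that it is negligible.
    """
    table = np.array([[a, b], [c, d]], dtype=np.int64)
    if (table < 0).any():
        raise ValueError("counts must be non-negative")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("zero row or column margin")
    chi2, p, df, _ = stats.chi2_contingency(table, correction=continuity)
    return ChiSquareResult(
        chi2=float(chi2),
        df=int(df),
        p=float(p),
        table=((int(a), int(b)), (int(c), int(d))),
    )


def two_sample_t(group_a, group_b, pooled: bool = True):
    """Two-sample t test of group means (Student pooled-variance by
    default, Welch if ``pooled=False``). Returns (t, df, p)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    if pooled and np.ptp(a) == 0 and np.ptp(b) == 0:
        raise ValueError("zero pooled variance")
    res = stats.ttest_ind(a, b, equal_var=pooled)
    if pooled:
        df = a.size + b.size - 2
    else:
        df = float(res.df)
    return float(res.statistic), df, float(res.pvalue)
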