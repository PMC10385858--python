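"""PCA over usage matrices with a deterministic sign convention, plus the
component-versus-feature correlation screen.

Two orientations are meaningful: taxa as observations and codons as
variables (the usual layout), or the transpose with codons as observations
— both are supported, and the orientation is always an explicit choice of
the caller, never inferred from the matrix shape.

The sign of a principal component is mathematically arbitrary. Components
are first given a canonical sign (largest-magnitude loading positive), and
:func:`orient_component` can then anchor a component to an external
covariate (e.g., fix PC1 to increase with third-position A+T content) so
that plots and downstream correlations have a stable direction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA as _SKPCA

from .assoc_stats import t_from_r
from scipy import stats as _scipy_stats

__all__ = ["UsageMatrix", "PCAResult", "ScreenResult", "pca", "orient_component", "screen_features"]


@dataclass
class UsageMatrix:
    """A taxa-by-feature (or transposed) real matrix with labelled axes."""

    frame: pd.DataFrame
    kind: str = "rscu"

    @property
    def row_ids(self) -> list[str]:
        return list(self.frame.index)

    @property
    def col_ids(self) -> list[str]:
        return list(self.frame.columns)

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy(dtype=float)

    def transposed(self) -> "UsageMatrix":
        return UsageMatrix(frame=self.frame.T, kind=self.kind)

    def drop_incomplete_columns(self) -> "UsageMatrix":
        """Drop columns containing NaN (undefined entries) — needed before
        PCA, which requires a complete matrix; correlations instead use
        pairwise exclusion."""
        return UsageMatrix(frame=self.frame.dropna(axis=1), kind=self.kind)


@dataclass
class PCAResult:
    scores: np.ndarray            # observations x components
    loadings: np.ndarray          # components x features
    variance_fraction: np.ndarray
    row_ids: list[str]
    col_ids: list[str]
    orientation_anchor: str = "canonical (largest-|loading| positive)"
    center: bool = True
    scale: bool = False

    def scores_frame(self) -> pd.DataFrame:
        cols = [f"PC{i + 1}" for i in range(self.scores.shape[1])]
        return pd.DataFrame(self.scores, index=self.row_ids, columns=cols)

    def loadings_frame(self) -> pd.DataFrame:
        rows = [f"PC{i + 1}" for i in range(self.loadings.shape[0])]
        return pd.DataFrame(self.loadings, index=rows, columns=self.col_ids)


@dataclass
class ScreenResult:
    """Per-feature Pearson screen against a component score."""

    table: pd.DataFrame           # feature, r, t, p, n, set
    positive_set: list[str] = field(default_factory=list)
    negative_set: list[str] = field(default_factory=list)
    t_cutoff: float = 0.0


def _canonical_signs(loadings: np.ndarray) -> np.ndarray:
    """Sign per component making its largest-|value| loading positive."""
    idx = np.argmax(np.abs(loadings), axis=1)
    picked = loadings[np.arange(loadings.shape[0]), idx]
    signs = np.where(picked < 0, -1.0, 1.0)
    return signs


def pca(matrix: UsageMatrix, center: bool = True, scale: bool = False) -> PCAResult:
    """Principal component analysis of a usage matrix.

    ``center=True, scale=False`` (the default) is covariance PCA of the
    column-centered data; ``scale=True`` standardises columns first, i.e.
    correlation PCA. Output is deterministic for fixed input: components
    are ordered by variance and carry the canonical sign.
    """
    X = matrix.values
    if np.isnan(X).any():
        raise ValueError(
            "matrix contains NaN; apply drop_incomplete_columns() first"
        )
    n, p = X.shape
    if n < 2 or p < 2:
        raise ValueError("need at least 2 rows and 2 columns")
    if np.unique(X, axis=0).shape[0] < 2:
        raise ValueError("degenerate matrix: fewer than 2 distinct rows")
    if scale:
        sd = X.std(axis=0, ddof=1)
        if (sd == 0).any():
            bad = [matrix.col_ids[i] for i in np.flatnonzero(sd == 0)]
            raise ValueError(f"constant columns under scale=True: {bad}")
        X = X / sd
    if center:
        model = _SKPCA(n_components=min(n, p), svd_solver="full")
        scores = model.fit_transform(X)
        loadings = model.components_
        var_frac = model.explained_variance_ratio_
    else:
        # uncentered SVD: variance fractions relative to total sum of squares
        U, s, Vt = np.linalg.svd(X, full_matrices=False)
        scores = U * s
        loadings = Vt
        var_frac = s**2 / np.sum(s**2)
    signs = _canonical_signs(loadings)
    loadings = loadings * signs[:, None]
    scores = scores * signs[None, :]
    return PCAResult(
        scores=scores,
        loadings=loadings,
        variance_fraction=np.asarray(var_frac, dtype=float),
        row_ids=matrix.row_ids,
        col_ids=matrix.col_ids,
        center=center,
        scale=scale,
    )


def orient_component(result: PCAResult, component: int, anchor, anchor_name: str = "anchor") -> PCAResult:
    """Fix the sign of one component against an external covariate.

    The component (0-based index) is negated iff the Pearson correlation
    between its scores and ``anchor`` is negative; applying the same anchor
    twice is a no-op.
    """
    anchor = np.asarray(anchor, dtype=float)
    if anchor.shape != (result.scores.shape[0],):
        raise ValueError("anchor must have one value per observation")
    if np.ptp(anchor) == 0:
        raise ValueError("zero-variance anchor")
    comp_scores = result.scores[:, component]
    r = float(np.corrcoef(comp_scores, anchor)[0, 1])
    if r >= 0:
        return replace(
            result,
            orientation_anchor=f"PC{component + 1} oriented by {anchor_name} (kept)",
        )
    scores = result.scores.copy()
    loadings = result.loadings.copy()
    scores[:, component] *= -1.0
    loadings[component, :] *= -1.0
    return replace(
        result,
        scores=scores,
        loadings=loadings,
        orientation_anchor=f"PC{component + 1} oriented by {anchor_name} (flipped)",
    )


def screen_features(matrix: UsageMatrix, scores, t_cutoff: float = 4.84) -> ScreenResult:
    """Pearson screen of every matrix column against a component score.

    For each feature, r is computed with pairwise exclusion of NaN entries,
    t = r sqrt(n-2)/sqrt(1-r^2), and two-sided p from Student's t. Features
    with |t| strictly above the cutoff are partitioned by the sign of r.
    The default cutoff 4.84 corresponds to a very stringent significance
    level (about 1e-5).
    """
    s = np.asarray(scores, dtype=float)
    X = matrix.values
    if s.shape != (X.shape[0],):
        raise ValueError("scores must align with matrix rows")
    rows = []
    positive, negative = [], []
    for j, feature in enumerate(matrix.col_ids):
        x = X[:, j]
        keep = ~(np.isnan(x) | np.isnan(s))
        n = int(keep.sum())
        if n < 4:
            raise ValueError(
                f"feature {feature!r}: only {n} paired observations after "
                "exclusions"
            )
        xk, sk = x[keep], s[keep]
        if np.ptp(xk) == 0:
            r, t, p = float("nan"), float("nan"), float("nan")
        else:
            r = float(np.corrcoef(xk, sk)[0, 1])
            t = t_from_r(r, n)
            p = 0.0 if math.isinf(t) else float(
                2.0 * _scipy_stats.t.sf(abs(t), n - 2)
            )
            if abs(t) > t_cutoff:
                (positive if r > 0 else negative).append(feature)
        rows.append({"feature": feature, "r": r, "t": t, "p": p, "n": n})
    table = pd.DataFrame(rows)
    table["set"] = [
        "positive" if f in positive else "negative" if f in negative else ""
        for f in table["feature"]
    ]
    return ScreenResult(
        table=table,
        positive_set=positive,
        negative_set=negative,
        t_cutoff=t_cutoff,
    )
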