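"""Expression normalization and principal component analysis.

Quantile normalization across samples (the classic microarray dialect with
mean-of-spanned-reference-values tie handling), log2(x+1) transformation,
row mean-centering, and SVD-based PCA with a deterministic sign convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .models_io import ExpressionMatrix

__all__ = ["PcaResult", "quantile_normalize", "log2p1", "mean_center", "pca"]


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample (column) onto the mean order-statistic distribution.

    The reference distribution is the across-column mean of sorted values;
    each value is replaced by the reference value at its within-column rank.
    Ties within a column receive the mean of the reference values their
    ranks span, so the operation is deterministic under zero inflation.
    """
    if matrix.scale_tag != "raw":
        raise ValueError(f"expected raw scale, got {matrix.scale_tag!r}")
    X = matrix.data.to_numpy(dtype=float)
    n_rows, n_cols = X.shape
    if n_cols < 2:
        raise ValueError("quantile normalization needs at least 2 columns")
    reference = np.sort(X, axis=0).mean(axis=1)
    out = np.empty_like(X)
    for j in range(n_cols):
        ranks = scipy.stats.rankdata(X[:, j], method="average")  # 1-based midranks
        # midrank r maps to the mean of reference values spanned by the tie run;
        # for a run spanning ranks r-k..r+k that mean equals the midrank lookup
        # on the cumulative average, computed exactly per tie group
        order = np.argsort(X[:, j], kind="mergesort")
        sorted_ref_cummean = np.concatenate([[0.0], np.cumsum(reference)])
        col = np.empty(n_rows)
        # group equal values; assign each group the mean of its reference span
        vals = X[order, j]
        start = 0
        while start < n_rows:
            end = start
            while end < n_rows and vals[end] == vals[start]:
                end += 1
            group_mean = (
                sorted_ref_cummean[end] - sorted_ref_cummean[start]
            ) / (end - start)
            col[order[start:end]] = group_mean
            start = end
        out[:, j] = col
    return ExpressionMatrix(
        pd.DataFrame(out, index=matrix.data.index, columns=matrix.data.columns),
        scale_tag="quantile_normalized",
    )


def log2p1(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Elementwise log2(x + 1)."""
    if matrix.scale_tag not in ("raw", "quantile_normalized"):
        raise ValueError(f"cannot log-transform scale {matrix.scale_tag!r}")
    return ExpressionMatrix(np.log2(matrix.data + 1.0), scale_tag="log2p1")


def mean_center(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Subtract each row's (feature's) mean; idempotent."""
    centered = matrix.data.sub(matrix.data.mean(axis=1), axis=0)
    return ExpressionMatrix(centered, scale_tag="centered")


@dataclass(frozen=True)
class PcaResult:
    """Scores (samples x k), loadings (features x k) and explained variance."""

    scores: pd.DataFrame
    loadings: pd.DataFrame
    explained_variance_fraction: np.ndarray

    def __post_init__(self):
        f = self.explained_variance_fraction
        if np.any(np.diff(f) > 1e-12) or np.any(f < -1e-12) or f.sum() > 1 + 1e-9:
            raise ValueError("explained variance fractions invalid")


def pca(matrix: ExpressionMatrix, k: int) -> PcaResult:
    """PCA of a row-centered matrix (features as rows, samples as columns).

    Uses the SVD of the centered matrix; samples are projected onto the
    top-k right singular vectors.  Sign convention: the largest-magnitude
    loading of each component is made positive, so results are
    deterministic and invariant to sample order up to permutation.
    """
    X = matrix.data.to_numpy(dtype=float)
    if k < 1 or k > min(X.shape):
        raise ValueError(f"k={k} outside 1..min(dims)={min(X.shape)}")
    Xc = X - X.mean(axis=1, keepdims=True)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    # deterministic sign: largest-|loading| entry of each component positive
    for comp in range(len(s)):
        idx = np.argmax(np.abs(U[:, comp]))
        if U[idx, comp] < 0:
            U[:, comp] = -U[:, comp]
            Vt[comp, :] = -Vt[comp, :]
    total_var = float((s**2).sum())
    frac = (s**2) / total_var if total_var > 0 else np.zeros_like(s)
    cols = [f"PC{c + 1}" for c in range(k)]
    scores = pd.DataFrame(
        (Vt[:k, :] * s[:k, None]).T, index=matrix.data.columns, columns=cols
    )
    loadings = pd.DataFrame(U[:, :k], index=matrix.data.index, columns=cols)
    return PcaResult(scores, loadings, frac[:k])
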