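"""Differential expression and differential isoform-usage testing.

Gene-level subtype differences are tested by Wilcoxon rank-sum and by an
ordinary least squares model ``y ~ m0 + subtype``.  Subtype-specific
isoform usage is tested by the two-factor fixed-effects model

    y ~ m0 + subtype + isoform + subtype*isoform + E

where observations are stacked (sample, isoform) pairs of log2(FPKM+1)
values and the interaction F-test (extra sum of squares, full vs
no-interaction model) flags genes whose isoform usage depends on subtype.
Within-sample correlation between isoforms is ignored, i.e. all effects
are fixed and the fit is OLS row-stacked — a deliberate statistical
simplification documented in the methods note.

Multiple testing is controlled by Storey's q-value with the smoothing
estimator of pi0 evaluated on a lambda grid.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import scipy.stats

from .models_io import ExpressionMatrix, SampleAnnotation, TranscriptModel, group_by_gene
from .normalization import log2p1

__all__ = [
    "GeneTestResult",
    "IsoformPairResult",
    "QValueResult",
    "wilcoxon_de",
    "lm_subtype_de",
    "isoform_interaction_test",
    "pairwise_interaction_tests",
    "storey_qvalues",
    "IsoformUsageModel",
    "IsoformUsageResults",
]


@dataclass
class GeneTestResult:
    gene_id: str
    method: str  # wilcoxon | lm_subtype | lm_interaction
    statistic: float
    p: float
    q: Optional[float] = None
    betas: Dict[str, float] = field(default_factory=dict)


@dataclass
class IsoformPairResult:
    """Interaction-test outcome for one isoform pair (iso_a < iso_b).

    ``beta`` is the subtype x isoform interaction coefficient with ERpos
    and ``iso_a`` as reference levels: positive beta means ``iso_b`` is
    relatively favored in TN samples.
    """

    gene_id: str
    iso_a: str
    iso_b: str
    beta: float
    F: float
    p: float
    q: Optional[float] = None
    structural_diff: Optional[object] = None

    def __post_init__(self):
        if not self.iso_a < self.iso_b:
            raise ValueError("pair must be ordered iso_a < iso_b")

    @property
    def tn_favored_isoform(self) -> str:
        return self.iso_b if self.beta >= 0 else self.iso_a


@dataclass
class QValueResult:
    pvalues: np.ndarray
    qvalues: np.ndarray
    pi0: float
    lambda_grid: np.ndarray


# ---------------------------------------------------------------------------
# helpers


def _split_by_subtype(
    matrix: ExpressionMatrix, annotations: Sequence[SampleAnnotation]
) -> Tuple[np.ndarray, np.ndarray]:
    by_id = {a.sample_id: a.subtype for a in annotations}
    missing = [c for c in matrix.col_ids if c not in by_id]
    if missing:
        raise ValueError(f"samples missing annotation: {missing[:5]}")
    er = [c for c in matrix.col_ids if by_id[c] == "ERpos"]
    tn = [c for c in matrix.col_ids if by_id[c] == "TN"]
    if not er or not tn:
        raise ValueError("both subtypes must be present among the samples")
    return (
        matrix.data[er].to_numpy(dtype=float),
        matrix.data[tn].to_numpy(dtype=float),
    )


def _as_log_scale(matrix: ExpressionMatrix) -> ExpressionMatrix:
    if matrix.scale_tag in ("raw", "quantile_normalized"):
        return log2p1(matrix)
    return matrix


# ---------------------------------------------------------------------------
# gene-level DE


def wilcoxon_de(
    matrix: ExpressionMatrix, annotations: Sequence[SampleAnnotation]
) -> List[GeneTestResult]:
    """Two-sided Wilcoxon rank-sum test of each row between subtypes.

    Exact p-values when the combined sample size is at most 25 and there
    are no ties; otherwise the normal approximation with midranks, tie
    correction and continuity correction.  Rows constant across all
    samples get p = 1.
    """
    X_er, X_tn = _split_by_subtype(matrix, annotations)
    if X_er.shape[1] < 2 or X_tn.shape[1] < 2:
        raise ValueError("need >= 2 samples per subtype")
    results = []
    for i, row_id in enumerate(matrix.row_ids):
        x, y = X_er[i], X_tn[i]
        if np.ptp(np.concatenate([x, y])) == 0:
            results.append(GeneTestResult(row_id, "wilcoxon", 0.0, 1.0))
            continue
        n_total = len(x) + len(y)
        has_ties = len(np.unique(np.concatenate([x, y]))) < n_total
        method = "exact" if (n_total <= 25 and not has_ties) else "asymptotic"
        res = scipy.stats.mannwhitneyu(
            x, y, alternative="two-sided", method=method, use_continuity=True
        )
        results.append(
            GeneTestResult(row_id, "wilcoxon", float(res.statistic), float(res.pvalue))
        )
    return results


def lm_subtype_de(
    matrix: ExpressionMatrix, annotations: Sequence[SampleAnnotation]
) -> List[GeneTestResult]:
    """Per-row OLS fit of ``y ~ m0 + subtype`` with a t-test on the subtype beta.

    beta_subtype = mean(TN) - mean(ERpos) on the (log) response scale, with
    ERpos as the reference level.  For balanced or unbalanced two-group
    data this is the classical equal-variance two-sample t-test.
    """
    log_mat = _as_log_scale(matrix)
    X_er, X_tn = _split_by_subtype(log_mat, annotations)
    n1, n2 = X_er.shape[1], X_tn.shape[1]
    results = []
    for i, row_id in enumerate(matrix.row_ids):
        x, y = X_er[i], X_tn[i]
        beta = float(y.mean() - x.mean())
        df = n1 + n2 - 2
        pooled = ((x - x.mean()) ** 2).sum() + ((y - y.mean()) ** 2).sum()
        s2 = pooled / df if df > 0 else 0.0
        se = np.sqrt(s2 * (1.0 / n1 + 1.0 / n2))
        if se == 0:
            t, p = 0.0, 1.0
        else:
            t = beta / se
            p = float(2.0 * scipy.stats.t.sf(abs(t), df))
        results.append(
            GeneTestResult(
                row_id, "lm_subtype", float(t), p, betas={"subtype[TN]": beta}
            )
        )
    return results


# ---------------------------------------------------------------------------
# interaction tests


def _interaction_fit(
    Y: np.ndarray, is_tn: np.ndarray
) -> Tuple[float, float, int, int, np.ndarray]:
    """OLS extra-sum-of-squares F for subtype x isoform interaction.

    Y is an (L isoforms x n samples) block of log-scale responses; rows are
    stacked into (sample, isoform) observations.  Returns (F, p, df1, df2,
    betas of the full model in treatment coding).
    """
    L, n = Y.shape
    N = L * n
    y = Y.reshape(-1)  # isoform-major stacking
    tn = np.tile(is_tn, L)
    cols = [np.ones(N), tn]
    for l in range(1, L):
        iso = np.zeros(N)
        iso[l * n : (l + 1) * n] = 1.0
        cols.append(iso)
    X_red = np.column_stack(cols)
    inter_cols = [X_red[:, 1] * X_red[:, 2 + l] for l in range(L - 1)]
    X_full = np.column_stack(cols + inter_cols)

    beta_full, _, _, _ = np.linalg.lstsq(X_full, y, rcond=None)
    rss_full = float(((y - X_full @ beta_full) ** 2).sum())
    beta_red, _, _, _ = np.linalg.lstsq(X_red, y, rcond=None)
    rss_red = float(((y - X_red @ beta_red) ** 2).sum())

    df1 = L - 1
    df2 = N - 2 * L
    if df2 <= 0:
        raise ValueError("not enough observations for the interaction test")
    if rss_full <= 1e-12 * max(1.0, float((y**2).sum())):
        # saturated / noise-free fit: no residual variance to test against
        return 0.0, 1.0, df1, df2, beta_full
    F = ((rss_red - rss_full) / df1) / (rss_full / df2)
    F = max(F, 0.0)
    p = float(scipy.stats.f.sf(F, df1, df2))
    return float(F), p, df1, df2, beta_full


def isoform_interaction_test(
    gene_block: ExpressionMatrix,
    annotations: Sequence[SampleAnnotation],
    gene_id: Optional[str] = None,
) -> GeneTestResult:
    """Subtype x isoform interaction ANOVA for one gene's isoform block.

    The F statistic compares the full model against the no-interaction
    model; degrees of freedom are ((L-1), N - 2L) with N = samples x L
    stacked observations.  Raises for single-isoform genes.
    """
    if gene_block.shape[0] < 2:
        raise ValueError(
            f"gene {gene_id or gene_block.row_ids} has a single isoform; "
            "the interaction model needs >= 2"
        )
    log_block = _as_log_scale(gene_block)
    by_id = {a.sample_id: a.subtype for a in annotations}
    is_tn = np.array(
        [1.0 if by_id[c] == "TN" else 0.0 for c in gene_block.col_ids]
    )
    if is_tn.min() == is_tn.max():
        raise ValueError("both subtypes must be present")
    # rows sorted so the reference isoform is deterministic
    order = np.argsort(gene_block.row_ids)
    tx_ids = [gene_block.row_ids[k] for k in order]
    Y = log_block.data.to_numpy(dtype=float)[order]
    F, p, df1, df2, beta = _interaction_fit(Y, is_tn)
    L = len(tx_ids)
    betas = {"m0": float(beta[0]), "subtype[TN]": float(beta[1])}
    for l in range(1, L):
        betas[f"isoform[{tx_ids[l]}]"] = float(beta[1 + l])
        betas[f"subtype[TN]:isoform[{tx_ids[l]}]"] = float(beta[1 + L + l - 1])
    return GeneTestResult(
        gene_id or tx_ids[0].rsplit(".", 1)[0], "lm_interaction", F, p, betas=betas
    )


def detected_rows(matrix: ExpressionMatrix, min_samples: int = 2) -> List[str]:
    """Transcripts detected (abundance > 0) in at least ``min_samples`` samples."""
    counts = (matrix.data > 0).sum(axis=1)
    return list(matrix.data.index[counts >= min_samples])


def pairwise_interaction_tests(
    matrix: ExpressionMatrix,
    models: Sequence[TranscriptModel],
    annotations: Sequence[SampleAnnotation],
    min_detected_samples: int = 2,
) -> List[IsoformPairResult]:
    """Interaction test for every unordered isoform pair of multi-isoform genes.

    Each pair is tested with the two-isoform (L=2) interaction model; the
    single interaction beta gives the subtype direction.  q-values are
    computed jointly over all emitted pairs.
    """
    log_mat = _as_log_scale(matrix)
    by_id = {a.sample_id: a.subtype for a in annotations}
    is_tn = np.array([1.0 if by_id[c] == "TN" else 0.0 for c in matrix.col_ids])
    detected = set(detected_rows(matrix, min_detected_samples))
    genes = group_by_gene(models)
    results: List[IsoformPairResult] = []
    for gene_id in sorted(genes):
        tx_ids = sorted(
            tx.transcript_id
            for tx in genes[gene_id]
            if tx.transcript_id in detected and tx.transcript_id in matrix.data.index
        )
        if len(tx_ids) < 2:
            continue
        for iso_a, iso_b in itertools.combinations(tx_ids, 2):
            Y = log_mat.data.loc[[iso_a, iso_b]].to_numpy(dtype=float)
            F, p, _, _, beta = _interaction_fit(Y, is_tn)
            results.append(
                IsoformPairResult(
                    gene_id=gene_id,
                    iso_a=iso_a,
                    iso_b=iso_b,
                    beta=float(beta[-1]),
                    F=F,
                    p=p,
                )
            )
    if results:
        qres = storey_qvalues(np.array([r.p for r in results]))
        for r, q in zip(results, qres.qvalues):
            r.q = float(q)
    return results


# ---------------------------------------------------------------------------
# Storey q-values


def storey_qvalues(
    pvalues: Sequence[float],
    lambda_grid: Optional[np.ndarray] = None,
    pi0: Optional[float] = None,
) -> QValueResult:
    """Storey q-values with the smoothed pi0 estimator.

    pi0(lambda) = #{p > lambda} / (m (1 - lambda)) over the grid
    0.05..0.95 is smoothed by a cubic polynomial in lambda, evaluated at
    lambda = 0.95 and clamped to (0, 1].  q(p_(i)) = min_{j>=i}
    pi0 * m * p_(j) / j, so q-values are monotone in p and tied p-values
    share a q.  Fewer than 20 p-values falls back to pi0 = 1 (BH).
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("pvalues must be a non-empty 1-d sequence")
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if lambda_grid is None:
        lambda_grid = np.arange(0.05, 0.96, 0.05)
    lambda_grid = np.asarray(lambda_grid, dtype=float)

    if pi0 is None:
        if m < 20:
            warnings.warn(
                f"only {m} p-values; falling back to pi0 = 1 (Benjamini-Hochberg)",
                stacklevel=2,
            )
            pi0 = 1.0
        else:
            pi0_lambda = np.array(
                [(p > lam).sum() / (m * (1.0 - lam)) for lam in lambda_grid]
            )
            coeffs = np.polyfit(lambda_grid, pi0_lambda, deg=3)
            pi0 = float(np.polyval(coeffs, 0.95))
            pi0 = min(max(pi0, 1.0 / m), 1.0)
    if not 0.0 < pi0 <= 1.0:
        raise ValueError(f"pi0 must be in (0, 1], got {pi0}")

    order = np.argsort(p, kind="mergesort")
    q_sorted = pi0 * m * p[order] / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return QValueResult(pvalues=p, qvalues=q, pi0=pi0, lambda_grid=lambda_grid)


# ---------------------------------------------------------------------------
# model / results facade


class IsoformUsageModel:
    """Differential isoform-usage model for a two-subtype cohort.

    Bundles an abundance matrix, sample annotations and gene models, and on
    ``fit()`` runs the pairwise subtype x isoform interaction ANOVA with
    Storey FDR, returning an :class:`IsoformUsageResults`.
    """

    def __init__(
        self,
        expression: ExpressionMatrix,
        annotations: Sequence[SampleAnnotation],
        models: Sequence[TranscriptModel],
        min_detected_samples: int = 2,
    ):
        self.expression = expression
        self.annotations = list(annotations)
        self.models = list(models)
        self.min_detected_samples = min_detected_samples

    @classmethod
    def from_files(cls, expression_path, sample_sheet_path, gtf_path, **kwargs):
        from . import models_io

        return cls(
            models_io.read_expression_table(expression_path),
            models_io.read_sample_sheet(sample_sheet_path),
            models_io.read_gtf(gtf_path),
            **kwargs,
        )

    def fit(self) -> "IsoformUsageResults":
        pairs = pairwise_interaction_tests(
            self.expression,
            self.models,
            self.annotations,
            self.min_detected_samples,
        )
        gene_results = []
        detected = set(detected_rows(self.expression, self.min_detected_samples))
        genes = group_by_gene(self.models)
        for gene_id in sorted(genes):
            tx_ids = sorted(
                tx.transcript_id
                for tx in genes[gene_id]
                if tx.transcript_id in detected
                and tx.transcript_id in self.expression.data.index
            )
            if len(tx_ids) < 2:
                continue
            block = self.expression.subset_rows(tx_ids)
            gene_results.append(
                isoform_interaction_test(block, self.annotations, gene_id=gene_id)
            )
        if gene_results:
            qres = storey_qvalues(np.array([g.p for g in gene_results]))
            for g, qv in zip(gene_results, qres.qvalues):
                g.q = float(qv)
        return IsoformUsageResults(self, pairs, gene_results)


class IsoformUsageResults:
    """Fitted pairwise interaction results with FDR control."""

    def __init__(self, model, pair_results, gene_results):
        self.model = model
        self.pair_results: List[IsoformPairResult] = pair_results
        self.gene_results: List[GeneTestResult] = gene_results

    @property
    def pairs_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "gene_id": r.gene_id,
                    "iso_a": r.iso_a,
                    "iso_b": r.iso_b,
                    "F": r.F,
                    "p": r.p,
                    "q": r.q,
                    "beta": r.beta,
                    "tn_favored_isoform": r.tn_favored_isoform,
                }
                for r in self.pair_results
            ]
        )

    def significant_pairs(self, fdr: float = 0.05) -> List[IsoformPairResult]:
        return [r for r in self.pair_results if r.q is not None and r.q < fdr]

    def significant_genes(self, fdr: float = 0.05) -> List[str]:
        return sorted(
            {g.gene_id for g in self.gene_results if g.q is not None and g.q < fdr}
        )

    def summary(self, fdr: float = 0.05) -> str:
        n_genes = len(self.gene_results)
        n_pairs = len(self.pair_results)
        sig_pairs = self.significant_pairs(fdr)
        sig_genes = self.significant_genes(fdr)
        lines = [
            "Isoform usage interaction analysis",
            "=" * 44,
            f"multi-isoform genes tested   {n_genes:8d}",
            f"isoform pairs tested         {n_pairs:8d}",
            f"significant genes (q<{fdr:g})   {len(sig_genes):8d}",
            f"significant pairs (q<{fdr:g})   {len(sig_pairs):8d}",
        ]
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        self.pairs_frame.to_csv(path, sep="\t", index=False)
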