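"""Cross-platform replication: NanoString normalization and subtype transfer.

NanoString probe counts are normalized by a negative-binomial log-link
regression with terms for assay (cartridge), well, log median
negative-control count, log median housekeeping count and transcript
identity; the Pearson residuals of that fit are the normalized expression
values carried into all downstream analyses.  Isoform-pair log-ratios link
the RNA-seq and NanoString measurements of the same samples (concordance =
shared sign).  A ridge-penalized logistic classifier trained on one cohort
and applied to another quantifies, via ROC/AUC, how well isoform
expression alone separates the ER+ and TN subtypes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.special
import statsmodels.api as sm
import statsmodels.formula.api as smf
from sklearn.linear_model import LogisticRegression

from .models_io import ExpressionMatrix, SampleAnnotation
from .synthetic import NanoStringData

__all__ = [
    "NanostringModel",
    "fit_nanostring_model",
    "platform_concordance",
    "select_probe_panel",
    "ClassifierModel",
    "train_logistic",
    "predict_and_roc",
    "rank_auc",
    "RocResult",
]


@dataclass
class NanostringModel:
    """Fitted negative-binomial normalization model."""

    coefficients: pd.Series
    theta: float
    deviance: float
    n_iterations: int

    def summary(self) -> str:
        lines = [
            "NanoString negative-binomial normalization",
            "=" * 44,
            f"dispersion theta   {self.theta:10.3f}",
            f"deviance           {self.deviance:10.3f}",
            f"outer iterations   {self.n_iterations:10d}",
            f"coefficients       {len(self.coefficients):10d}",
        ]
        return "\n".join(lines)


def _nb_loglik(y: np.ndarray, mu: np.ndarray, theta: float) -> float:
    return float(
        np.sum(
            scipy.special.gammaln(y + theta)
            - scipy.special.gammaln(theta)
            - scipy.special.gammaln(y + 1.0)
            + theta * np.log(theta / (theta + mu))
            + y * np.log(mu / (theta + mu))
        )
    )


def fit_nanostring_model(
    data: NanoStringData,
    theta0: float = 10.0,
    tol: float = 1e-8,
    max_iter: int = 100,
    residual_type: str = "pearson",
) -> Tuple[NanostringModel, ExpressionMatrix]:
    """Normalize NanoString counts by NB regression; return Pearson residuals.

    Endogenous-probe counts are modeled on the log link with terms for
    assay, well, per-sample log(median negative-control + 1) and
    log(median housekeeping + 1) covariates (free slopes), and transcript
    identity.  The GLM fit (IRLS) alternates with maximum-likelihood
    updates of the dispersion theta until the relative deviance change
    falls below ``tol``.  The residual matrix (probes x samples) carries
    scale_tag ``residual``.
    """
    counts = data.counts
    if not np.allclose(counts.to_numpy(), counts.to_numpy().astype(int)):
        raise ValueError("counts must be non-negative integers")
    if (counts.to_numpy() < 0).any():
        raise ValueError("counts must be non-negative integers")
    if residual_type not in ("pearson", "deviance"):
        raise ValueError("residual_type must be 'pearson' or 'deviance'")

    neg = counts.loc[data.probe_class == "negative"]
    hk = counts.loc[data.probe_class == "housekeeping"]
    endo = counts.loc[data.probe_class == "endogenous"]
    if neg.empty or hk.empty or endo.empty:
        raise ValueError(
            "need endogenous, negative and housekeeping probes to normalize"
        )
    info = data.sample_info.set_index("sample_id")
    log_neg = np.log(neg.median(axis=0) + 1.0)
    log_hk = np.log(hk.median(axis=0) + 1.0)

    long = (
        endo.stack()
        .rename("count")
        .reset_index()
        .rename(columns={"level_0": "probe", "level_1": "sample"})
    )
    long.columns = ["probe", "sample", "count"]
    long["assay"] = info.loc[long["sample"], "assay"].to_numpy()
    long["well"] = info.loc[long["sample"], "well"].to_numpy()
    long["log_neg"] = log_neg[long["sample"]].to_numpy()
    long["log_hk"] = log_hk[long["sample"]].to_numpy()

    formula = "count ~ C(assay) + C(well) + log_neg + log_hk + C(probe)"
    theta = theta0
    prev_dev = np.inf
    fit = None
    for it in range(1, max_iter + 1):
        model = smf.glm(
            formula, data=long, family=sm.families.NegativeBinomial(alpha=1.0 / theta)
        )
        fit = model.fit()
        mu = np.maximum(np.asarray(fit.fittedvalues), 1e-10)
        y = long["count"].to_numpy(dtype=float)

        res = scipy.optimize.minimize_scalar(
            lambda lt: -_nb_loglik(y, mu, float(np.exp(lt))),
            bounds=(np.log(1e-2), np.log(1e4)),
            method="bounded",
            options={"xatol": 1e-8},
        )
        theta = float(np.exp(res.x))
        dev = float(fit.deviance)
        if np.isfinite(prev_dev) and abs(prev_dev - dev) <= tol * max(abs(dev), 1.0):
            break
        prev_dev = dev
    else:
        raise RuntimeError(
            f"NB normalization failed to converge after {max_iter} iterations "
            f"(deviance {prev_dev:.6g})"
        )

    mu = np.maximum(np.asarray(fit.fittedvalues), 1e-10)
    y = long["count"].to_numpy(dtype=float)
    if residual_type == "pearson":
        resid = (y - mu) / np.sqrt(mu + mu**2 / theta)
    else:
        resid = np.asarray(fit.resid_deviance)
    long = long.assign(resid=resid)
    resid_mat = long.pivot(index="probe", columns="sample", values="resid")
    resid_mat = resid_mat.loc[endo.index, counts.columns]
    resid_mat.columns.name = None
    resid_mat.index.name = None

    ns_model = NanostringModel(
        coefficients=fit.params,
        theta=theta,
        deviance=float(fit.deviance),
        n_iterations=it,
    )
    return ns_model, ExpressionMatrix(resid_mat, scale_tag="residual")


# ---------------------------------------------------------------------------
# RNA-seq <-> NanoString concordance


def select_probe_panel(
    rnaseq: ExpressionMatrix,
    candidate_pairs: Sequence[Tuple[str, str]],
    max_abs_mean_log_ratio: float = 1.5,
    n_pairs: Optional[int] = 106,
    epsilon: float = 1.0,
) -> List[Tuple[str, str]]:
    """Emulate probe-panel design for differential isoform pairs.

    Probe pairs can only discriminate isoform usage cleanly when the two
    isoforms have comparable overall abundance, so the panel keeps pairs
    whose cohort-mean log2 ratio magnitude is below the threshold (their
    per-sample ratio then crosses zero between subtypes), up to ``n_pairs``
    pairs in the input order.
    """
    selected = []
    for iso_a, iso_b in candidate_pairs:
        ratio = np.log2(
            (rnaseq.data.loc[iso_a] + epsilon) / (rnaseq.data.loc[iso_b] + epsilon)
        )
        if abs(float(ratio.mean())) < max_abs_mean_log_ratio:
            selected.append((iso_a, iso_b))
        if n_pairs is not None and len(selected) >= n_pairs:
            break
    return selected


def platform_concordance(
    rnaseq: ExpressionMatrix,
    nanostring_resid: ExpressionMatrix,
    pairs: Sequence[Tuple[str, str]],
    epsilon: float = 1.0,
) -> Tuple[pd.Series, pd.DataFrame]:
    """Per-sample sign concordance of isoform-pair ratios across platforms.

    For each pair and shared sample the RNA-seq side is
    log2((FPKM_a + eps) / (FPKM_b + eps)) and the NanoString side is the
    residual difference; a pair is concordant in a sample when the two
    values share sign.  The per-sample fraction counts only pairs with
    both values nonzero.  Returns (per-sample fractions, long table of
    quadrant labels).
    """
    samples = [c for c in rnaseq.col_ids if c in nanostring_resid.data.columns]
    if not samples:
        raise ValueError("no shared samples between the platforms")
    records = []
    for iso_a, iso_b in pairs:
        r = np.log2(
            (rnaseq.data.loc[iso_a, samples] + epsilon)
            / (rnaseq.data.loc[iso_b, samples] + epsilon)
        )
        nsd = (
            nanostring_resid.data.loc[iso_a, samples]
            - nanostring_resid.data.loc[iso_b, samples]
        )
        for s in samples:
            rv, nv = float(r[s]), float(nsd[s])
            records.append(
                {
                    "iso_a": iso_a,
                    "iso_b": iso_b,
                    "sample": s,
                    "rnaseq_log_ratio": rv,
                    "nanostring_diff": nv,
                    "concordant": (rv * nv > 0),
                    "informative": (rv != 0 and nv != 0),
                }
            )
    table = pd.DataFrame(records)
    informative = table[table["informative"]]
    per_sample = informative.groupby("sample")["concordant"].mean()
    return per_sample.reindex(samples), table


# ---------------------------------------------------------------------------
# logistic subtype classifier


@dataclass
class ClassifierModel:
    """L2-penalized logistic subtype classifier (positive class = TN).

    Features are standardized with the training mean/sd; the penalty never
    touches the intercept.  With zero features the model reduces to the
    class-prior log-odds (scores constant, AUC 0.5).
    """

    feature_ids: List[str]
    weights: np.ndarray
    intercept: float
    feature_mean: np.ndarray
    feature_sd: np.ndarray
    l2_strength: float

    def decision_scores(self, features: ExpressionMatrix) -> pd.Series:
        if not self.feature_ids:
            return pd.Series(self.intercept, index=features.col_ids)
        X = features.data.loc[self.feature_ids].to_numpy(dtype=float).T
        Z = (X - self.feature_mean) / self.feature_sd
        return pd.Series(Z @ self.weights + self.intercept, index=features.col_ids)

    def predict_subtype(self, features: ExpressionMatrix) -> pd.Series:
        scores = self.decision_scores(features)
        return scores.map(lambda s: "TN" if s > 0 else "ERpos")


def _labels_to_binary(
    sample_ids: Sequence[str], labels
) -> np.ndarray:
    if isinstance(labels, dict):
        mapping = labels
    else:
        mapping = {a.sample_id: a.subtype for a in labels}
    missing = [s for s in sample_ids if s not in mapping]
    if missing:
        raise ValueError(f"samples without labels: {missing[:5]}")
    y = np.array([1 if mapping[s] == "TN" else 0 for s in sample_ids])
    return y


def train_logistic(
    features: ExpressionMatrix, labels, l2_strength: float = 1.0
) -> ClassifierModel:
    """Fit the ridge-logistic subtype classifier on standardized features.

    ``features`` is features x samples; ``labels`` a sample->subtype dict
    or a list of SampleAnnotation.  The binomial log-likelihood is
    maximized with an L2 penalty of the given strength on the
    standardized-feature weights (intercept unpenalized), deterministically.
    """
    sample_ids = features.col_ids
    y = _labels_to_binary(sample_ids, labels)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present in the training labels")
    if features.shape[0] == 0:
        prior = y.mean()
        return ClassifierModel(
            feature_ids=[],
            weights=np.zeros(0),
            intercept=float(np.log(prior / (1 - prior))),
            feature_mean=np.zeros(0),
            feature_sd=np.ones(0),
            l2_strength=l2_strength,
        )
    X = features.data.to_numpy(dtype=float).T
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    Z = (X - mean) / sd
    clf = LogisticRegression(
        C=1.0 / l2_strength, solver="lbfgs", max_iter=5000, tol=1e-10
    )
    clf.fit(Z, y)
    return ClassifierModel(
        feature_ids=features.row_ids,
        weights=clf.coef_.ravel().copy(),
        intercept=float(clf.intercept_[0]),
        feature_mean=mean,
        feature_sd=sd,
        l2_strength=l2_strength,
    )


@dataclass
class RocResult:
    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float

    def __post_init__(self):
        if np.any(np.diff(self.tpr) < -1e-12) or np.any(np.diff(self.fpr) < -1e-12):
            raise ValueError("TPR/FPR must be non-decreasing along the sweep")


def rank_auc(scores: np.ndarray, y: np.ndarray) -> float:
    """AUC via the Mann-Whitney rank form U / (n1 * n0), ties counted half."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y)
    pos, neg = scores[y == 1], scores[y == 0]
    if len(pos) == 0 or len(neg) == 0:
        return 0.5
    greater = (pos[:, None] > neg[None, :]).sum()
    equal = (pos[:, None] == neg[None, :]).sum()
    return float((greater + 0.5 * equal) / (len(pos) * len(neg)))


def predict_and_roc(
    model: ClassifierModel, features: ExpressionMatrix, labels
) -> RocResult:
    """Score samples with the classifier and sweep an ROC curve.

    All distinct scores serve as thresholds; AUC is the trapezoidal area,
    which equals the rank (Mann-Whitney) form.
    """
    scores = model.decision_scores(features).to_numpy()
    y = _labels_to_binary(features.col_ids, labels)
    return roc_from_scores(scores, y)


def roc_from_scores(scores: np.ndarray, y: np.ndarray) -> RocResult:
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs both classes")
    thresholds = np.concatenate([[np.inf], np.unique(scores)[::-1]])
    tpr = np.empty(len(thresholds))
    fpr = np.empty(len(thresholds))
    for i, t in enumerate(thresholds):
        pred = scores >= t
        tpr[i] = (pred & (y == 1)).sum() / n_pos
        fpr[i] = (pred & (y == 0)).sum() / n_neg
    auc = float(np.trapezoid(tpr, fpr))
    return RocResult(thresholds=thresholds, tpr=tpr, fpr=fpr, auc=auc)
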