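"""2x2 contingency machinery: exact Fisher tests, odds ratios, overlaps.

All set-overlap, direction-concordance and binding-site enrichment
questions reduce to labeled 2x2 tables.  The two-sided Fisher p-value uses
the probability-mass rule (sum of the hypergeometric probabilities of all
margin-preserving tables no more probable than the observed one), computed
in log space so that very small p-values do not underflow.  The odds ratio
is the sample cross-product (a*d)/(b*c) with a Woolf logit 95% interval;
zero cells get the Haldane-Anscombe 0.5 correction for the interval only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Sequence, Set, Tuple

import numpy as np
from scipy.special import gammaln, logsumexp

from .models_io import IntervalTrack, TranscriptModel, group_by_gene

__all__ = [
    "ContingencyTable2x2",
    "OverlapResult",
    "fisher_exact_2x2",
    "odds_ratio_ci",
    "overlap_result",
    "build_overlap_table",
    "direction_concordance_table",
    "gene_binding_overlap",
    "set_enrichment",
]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Labeled 2x2 counts; rows = first factor, columns = second factor."""

    a: int
    b: int
    c: int
    d: int
    row_labels: Tuple[str, str] = ("in_A", "not_A")
    col_labels: Tuple[str, str] = ("in_B", "not_B")

    def __post_init__(self):
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ValueError(f"cell {name} must be a non-negative integer")
        if self.n == 0:
            raise ValueError("table total must be positive")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=int)

    def transpose(self) -> "ContingencyTable2x2":
        return ContingencyTable2x2(
            self.a, self.c, self.b, self.d, self.col_labels, self.row_labels
        )


def _log_hypergeom_pmf(x, r1, c1, n):
    """log P(X = x) for the 2x2 hypergeometric with margins r1, c1, total n."""
    return (
        gammaln(r1 + 1)
        - gammaln(x + 1)
        - gammaln(r1 - x + 1)
        + gammaln(n - r1 + 1)
        - gammaln(c1 - x + 1)
        - gammaln(n - r1 - c1 + x + 1)
        - (gammaln(n + 1) - gammaln(c1 + 1) - gammaln(n - c1 + 1))
    )


def fisher_exact_2x2(table: ContingencyTable2x2) -> float:
    """Two-sided exact Fisher p by the probability-mass rule, in log space.

    p = sum of P(table') over all tables with the observed margins whose
    hypergeometric probability is at most that of the observed table (up
    to a 1e-7 relative log tolerance for ties).
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    r1, c1, n = a + b, a + c, table.n
    lo = max(0, c1 - (c + d))
    hi = min(r1, c1)
    if lo == hi:
        return 1.0
    xs = np.arange(lo, hi + 1)
    logp = _log_hypergeom_pmf(xs, r1, c1, n)
    log_obs = _log_hypergeom_pmf(np.array([a]), r1, c1, n)[0]
    mask = logp <= log_obs + 1e-7
    p = float(np.exp(logsumexp(logp[mask])))
    return min(p, 1.0)


def odds_ratio_ci(
    table: ContingencyTable2x2, z: float = 1.959963984540054
) -> Tuple[float, float, float]:
    """Cross-product odds ratio with a Woolf logit 95% interval.

    The point estimate is (a*d)/(b*c), possibly 0 or inf.  Any zero cell
    triggers the Haldane-Anscombe 0.5 correction of all cells for the
    interval (the point estimate is reported uncorrected).
    """
    a, b, c, d = (float(x) for x in (table.a, table.b, table.c, table.d))
    if b * c == 0:
        # 0/0 is undefined; a positive numerator over zero is infinite
        point = np.nan if a * d == 0 else np.inf
    else:
        point = (a * d) / (b * c)
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    log_or = np.log((a * d) / (b * c))
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return float(point), float(np.exp(log_or - z * se)), float(np.exp(log_or + z * se))


@dataclass(frozen=True)
class OverlapResult:
    """2x2 table with its Fisher p, odds ratio and Woolf 95% CI."""

    table: ContingencyTable2x2
    odds_ratio: float = field(init=False)
    ci_low: float = field(init=False)
    ci_high: float = field(init=False)
    fisher_p: float = field(init=False)

    def __post_init__(self):
        or_, lo, hi = odds_ratio_ci(self.table)
        object.__setattr__(self, "odds_ratio", or_)
        object.__setattr__(self, "ci_low", lo)
        object.__setattr__(self, "ci_high", hi)
        object.__setattr__(self, "fisher_p", fisher_exact_2x2(self.table))

    def summary(self) -> str:
        t = self.table
        return (
            f"{t.row_labels[0]}/{t.col_labels[0]}: "
            f"[[{t.a}, {t.b}], [{t.c}, {t.d}]]  "
            f"OR = {self.odds_ratio:.2f} "
            f"({self.ci_low:.2f}-{self.ci_high:.2f}), "
            f"Fisher p = {self.fisher_p:.3g}"
        )

    def to_dict(self) -> Dict:
        t = self.table
        return {
            "a": t.a,
            "b": t.b,
            "c": t.c,
            "d": t.d,
            "odds_ratio": self.odds_ratio,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "fisher_p": self.fisher_p,
        }


def overlap_result(table: ContingencyTable2x2) -> OverlapResult:
    return OverlapResult(table)


def build_overlap_table(
    set_a: Set, set_b: Set, universe: Set,
    labels: Tuple[str, str] = ("A", "B"),
) -> ContingencyTable2x2:
    """Overlap table in the subtype_and_KD / subtype_not_KD / KD_not_subtype
    / neither orientation: a=|A&B|, b=|A-B|, c=|B-A|, d=|U-(A|B)|."""
    set_a, set_b, universe = set(set_a), set(set_b), set(universe)
    if not set_a <= universe or not set_b <= universe:
        raise ValueError("both sets must be subsets of the universe")
    a = len(set_a & set_b)
    b = len(set_a - set_b)
    c = len(set_b - set_a)
    d = len(universe - (set_a | set_b))
    la, lb = labels
    return ContingencyTable2x2(
        a, b, c, d,
        row_labels=(f"{la}_and_{lb}", f"{la}_not_{lb}"),
        col_labels=(f"{lb}_not_{la}", f"not_{lb}_not_{la}"),
    )


def direction_concordance_table(
    kd_changes: Dict[str, float], subtype_changes: Dict[str, float]
) -> ContingencyTable2x2:
    """Cross-classify isoforms by knockdown direction x TN direction.

    Only isoforms with a nonzero signed change in both maps enter.  Cell
    layout follows the knockdownUp_tnDown / knockdownDown_tnDown /
    knockdownUp_tnUp / knockdownDown_tnUp convention, so the cross-product
    odds ratio is large when knockdown-up coincides with TN-down.
    """
    shared = [
        t
        for t in kd_changes
        if t in subtype_changes
        and kd_changes[t] != 0
        and subtype_changes[t] != 0
    ]
    if not shared:
        raise ValueError("no isoforms with nonzero change in both inputs")
    a = sum(1 for t in shared if kd_changes[t] > 0 and subtype_changes[t] < 0)
    b = sum(1 for t in shared if kd_changes[t] < 0 and subtype_changes[t] < 0)
    c = sum(1 for t in shared if kd_changes[t] > 0 and subtype_changes[t] > 0)
    d = sum(1 for t in shared if kd_changes[t] < 0 and subtype_changes[t] > 0)
    return ContingencyTable2x2(
        a, b, c, d,
        row_labels=("knockdownUp_tnDown", "knockdownDown_tnDown"),
        col_labels=("knockdownUp_tnUp", "knockdownDown_tnUp"),
    )


def gene_binding_overlap(
    track: IntervalTrack,
    models: Sequence[TranscriptModel],
    gene_set: Set[str],
    universe: Set[str],
    window: int = 25_000,
) -> ContingencyTable2x2:
    """Cross-classify genes by binding status x membership in ``gene_set``.

    A gene is bound iff any track interval overlaps its span extended by
    ``window`` bases on each side.  The universe of genes must be supplied
    explicitly; membership sets are intersected against it.
    """
    genes = group_by_gene(models)
    unknown = set(universe) - set(genes)
    if unknown:
        raise ValueError(f"universe genes without models: {sorted(unknown)[:5]}")
    bound = set()
    for gene_id in universe:
        txs = genes[gene_id]
        start = min(tx.span[0] for tx in txs)
        end = max(tx.span[1] for tx in txs)
        if track.overlapping(txs[0].chrom, max(0, start - window), end + window):
            bound.add(gene_id)
    return build_overlap_table(
        bound, set(gene_set) & set(universe), set(universe), labels=("bound", "KD")
    )


def set_enrichment(
    de_genes: Set[str], annotated_set: Set[str], universe: Set[str]
) -> OverlapResult:
    """Fisher enrichment of an annotated gene set among DE genes."""
    annotated = set(annotated_set) & set(universe)
    if not annotated:
        raise ValueError("annotated set does not intersect the universe")
    table = build_overlap_table(
        set(de_genes) & set(universe), annotated, set(universe), labels=("DE", "set")
    )
    return OverlapResult(table)
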