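"""Pairwise transcript structure comparison and splice-event taxonomy.

Two isoforms of the same gene are compared base-by-base (5'UTR / CDS /
3'UTR labels, strand-aware) and junction-by-junction.  Localized structural
differences are called as exon skipping, intron retention, alternative
donor, alternative acceptor, alternative first exon (distinct TSS) or
alternative last exon (distinct 3' end); bubbles matching no single taxon
are emitted as ``complex`` rather than silently misclassified.

Donor/acceptor orientation is strand-aware: on '+' the donor is the intron
start boundary and the acceptor the intron end; on '-' the roles reverse.
Consequently flipping the strand while keeping coordinates fixed swaps
donor<->acceptor (and first<->last exon), while mirroring the coordinates
AND flipping the strand preserves every event type.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .models_io import IntervalTrack, TranscriptModel

__all__ = [
    "StructuralDiff",
    "SpliceEvent",
    "compare_pair",
    "call_splice_events",
    "summarize_pairs",
    "PairSummary",
    "events_to_bed",
]

EVENT_TYPES = (
    "exon_skipping",
    "intron_retention",
    "alt_donor",
    "alt_acceptor",
    "alt_first_exon",
    "alt_last_exon",
    "complex",
)
INTERNAL_EVENT_TYPES = ("exon_skipping", "intron_retention", "alt_donor", "alt_acceptor")


@dataclass(frozen=True)
class SpliceEvent:
    type: str
    chrom: str
    strand: str
    interval: Tuple[int, int]
    inclusion_isoform: Optional[str] = None

    def __post_init__(self):
        if self.type not in EVENT_TYPES:
            raise ValueError(f"unknown event type {self.type!r}")


@dataclass(frozen=True)
class StructuralDiff:
    differs_5utr: bool
    differs_exons: bool
    differs_3utr: bool
    coding_change: bool
    primary_category: Optional[str]  # alt_splicing | alt_promoter | alt_3utr
    no_cds: bool = False


# ---------------------------------------------------------------------------
# interval algebra (0-based half-open, inputs sorted non-overlapping)


def _subtract(a: Sequence[Tuple[int, int]], b: Sequence[Tuple[int, int]]):
    """Bases in intervals ``a`` not covered by ``b``."""
    out = []
    for s, e in a:
        cur = s
        for bs, be in b:
            if be <= cur or bs >= e:
                continue
            if bs > cur:
                out.append((cur, bs))
            cur = max(cur, be)
            if cur >= e:
                break
        if cur < e:
            out.append((cur, e))
    return out


def _intersect(a, b):
    out = []
    for s, e in a:
        for bs, be in b:
            lo, hi = max(s, bs), min(e, be)
            if lo < hi:
                out.append((lo, hi))
    return sorted(out)


def _merge(intervals):
    out = []
    for s, e in sorted(intervals):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def _total_length(intervals):
    return sum(e - s for s, e in intervals)


def _region_intervals(tx: TranscriptModel):
    """Split a transcript's exonic bases into 5'UTR / CDS / 3'UTR intervals."""
    if tx.cds is None:
        return {"5utr": [], "cds": list(tx.exons), "3utr": []}
    cs, ce = tx.cds
    span = tx.span
    left = _intersect(tx.exons, [(span[0], cs)])
    mid = _intersect(tx.exons, [(cs, ce)])
    right = _intersect(tx.exons, [(ce, span[1])])
    if tx.strand == "+":
        return {"5utr": left, "cds": mid, "3utr": right}
    return {"5utr": right, "cds": mid, "3utr": left}


def _check_comparable(tx_a: TranscriptModel, tx_b: TranscriptModel):
    if tx_a.chrom != tx_b.chrom or tx_a.strand != tx_b.strand:
        raise ValueError(
            f"{tx_a.transcript_id} and {tx_b.transcript_id} lie on different "
            "chromosomes or strands"
        )


# ---------------------------------------------------------------------------
# event calling


def _first_last_exons(tx: TranscriptModel):
    """(first, last) exon in transcription direction."""
    if tx.strand == "+":
        return tx.exons[0], tx.exons[-1]
    return tx.exons[-1], tx.exons[0]


def call_splice_events(
    tx_a: TranscriptModel, tx_b: TranscriptModel
) -> List[SpliceEvent]:
    """Call localized splice events distinguishing two isoforms.

    Terminal differences with disjoint first (last) exons in transcription
    direction become alt_first_exon (alt_last_exon).  Internally, introns
    private to one isoform are explained greedily as exon skipping (an
    internal exon of one isoform spanned by a single intron of the other
    with shared outer splice sites), intron retention (an intron strictly
    inside an exon of the other isoform; the exon carrier is the inclusion
    isoform), or alternative donor/acceptor (a private intron pair sharing
    exactly one boundary).  Private introns left unexplained are merged
    into ``complex`` events.
    """
    _check_comparable(tx_a, tx_b)
    strand = tx_a.strand
    events: List[SpliceEvent] = []

    introns = {t.transcript_id: list(t.introns) for t in (tx_a, tx_b)}
    shared = set(introns[tx_a.transcript_id]) & set(introns[tx_b.transcript_id])
    unexplained = {
        t.transcript_id: set(introns[t.transcript_id]) - shared
        for t in (tx_a, tx_b)
    }

    # terminal events: disjoint first / last exons in transcription direction
    first_a, last_a = _first_last_exons(tx_a)
    first_b, last_b = _first_last_exons(tx_b)

    def _disjoint(x, y):
        return x[1] <= y[0] or y[1] <= x[0]

    def _terminal_intron(tx, which):
        ints = list(tx.introns)
        if not ints:
            return None
        genomic_first = (tx.strand == "+") == (which == "first")
        return ints[0] if genomic_first else ints[-1]

    if _disjoint(first_a, first_b):
        lo = min(first_a[0], first_b[0])
        hi = max(first_a[1], first_b[1])
        events.append(SpliceEvent("alt_first_exon", tx_a.chrom, strand, (lo, hi)))
        for tx in (tx_a, tx_b):
            ti = _terminal_intron(tx, "first")
            unexplained[tx.transcript_id].discard(ti)
    if _disjoint(last_a, last_b):
        lo = min(last_a[0], last_b[0])
        hi = max(last_a[1], last_b[1])
        events.append(SpliceEvent("alt_last_exon", tx_a.chrom, strand, (lo, hi)))
        for tx in (tx_a, tx_b):
            ti = _terminal_intron(tx, "last")
            unexplained[tx.transcript_id].discard(ti)

    # exon skipping: internal exon of X whose flanking introns fuse into a
    # single private intron of Y (outer splice sites shared)
    for X, Y in ((tx_a, tx_b), (tx_b, tx_a)):
        ux, uy = unexplained[X.transcript_id], unexplained[Y.transcript_id]
        for i in range(1, len(X.exons) - 1):
            exon = X.exons[i]
            prev_intron = (X.exons[i - 1][1], exon[0])
            next_intron = (exon[1], X.exons[i + 1][0])
            fused = (prev_intron[0], next_intron[1])
            if (
                fused in uy
                and prev_intron in ux
                and next_intron in ux
            ):
                events.append(
                    SpliceEvent(
                        "exon_skipping",
                        X.chrom,
                        strand,
                        exon,
                        inclusion_isoform=X.transcript_id,
                    )
                )
                uy.discard(fused)
                ux.discard(prev_intron)
                ux.discard(next_intron)

    # intron retention: private intron of X strictly inside an exon of Y
    for X, Y in ((tx_a, tx_b), (tx_b, tx_a)):
        ux = unexplained[X.transcript_id]
        for intron in sorted(ux):
            if any(s < intron[0] and e > intron[1] for s, e in Y.exons):
                events.append(
                    SpliceEvent(
                        "intron_retention",
                        X.chrom,
                        strand,
                        intron,
                        inclusion_isoform=Y.transcript_id,
                    )
                )
                ux.discard(intron)

    # alternative donor / acceptor: private intron pair sharing one boundary
    ua = sorted(unexplained[tx_a.transcript_id])
    ub = sorted(unexplained[tx_b.transcript_id])
    for ia in list(ua):
        match = None
        for ib in ub:
            share_start = ia[0] == ib[0]
            share_end = ia[1] == ib[1]
            if share_start != share_end:  # exactly one boundary shared
                match = (ib, share_start)
                break
        if match is None:
            continue
        ib, share_start = match
        if share_start:
            variable = (min(ia[1], ib[1]), max(ia[1], ib[1]))
            varying_boundary = "end"
        else:
            variable = (min(ia[0], ib[0]), max(ia[0], ib[0]))
            varying_boundary = "start"
        # donor is the intron start on '+', the intron end on '-'
        donor_varies = (varying_boundary == "start") == (strand == "+")
        etype = "alt_donor" if donor_varies else "alt_acceptor"
        shorter = (
            tx_a.transcript_id
            if (ia[1] - ia[0]) < (ib[1] - ib[0])
            else tx_b.transcript_id
        )
        events.append(
            SpliceEvent(etype, tx_a.chrom, strand, variable, inclusion_isoform=shorter)
        )
        unexplained[tx_a.transcript_id].discard(ia)
        unexplained[tx_b.transcript_id].discard(ib)
        ub.remove(ib)

    # leftovers: merge into complex bubbles
    leftovers = sorted(
        unexplained[tx_a.transcript_id] | unexplained[tx_b.transcript_id]
    )
    for cluster in _merge(leftovers):
        events.append(SpliceEvent("complex", tx_a.chrom, strand, cluster))

    return sorted(events, key=lambda ev: (ev.interval, ev.type))


def compare_pair(tx_a: TranscriptModel, tx_b: TranscriptModel) -> StructuralDiff:
    """Partition the structural difference of an isoform pair into regions.

    Each isoform's exonic bases are labeled 5'UTR / CDS / 3'UTR using its
    own CDS (strand-aware); the symmetric difference of exonic base sets
    sets ``differs_X`` for every region that contains a differing base in
    the isoform that carries it.  ``differs_exons`` is true for a coding
    base difference or any internal splice-structure difference;
    ``primary_category`` applies the priority alt_splicing > alt_promoter >
    alt_3utr.  Pairs where either isoform lacks a CDS are classified by
    splice structure only and flagged ``no_cds``.
    """
    _check_comparable(tx_a, tx_b)
    no_cds = tx_a.cds is None or tx_b.cds is None

    diff_in_a = _subtract(tx_a.exons, tx_b.exons)
    diff_in_b = _subtract(tx_b.exons, tx_a.exons)

    differs_5utr = differs_3utr = coding_change = False
    for tx, diff in ((tx_a, diff_in_a), (tx_b, diff_in_b)):
        regions = _region_intervals(tx)
        if _total_length(_intersect(diff, regions["cds"])) > 0:
            coding_change = True
        if not no_cds:
            if _total_length(_intersect(diff, regions["5utr"])) > 0:
                differs_5utr = True
            if _total_length(_intersect(diff, regions["3utr"])) > 0:
                differs_3utr = True

    events = call_splice_events(tx_a, tx_b)
    internal_splice = any(
        ev.type in INTERNAL_EVENT_TYPES or ev.type == "complex" for ev in events
    )
    differs_exons = coding_change or internal_splice

    if differs_exons:
        primary = "alt_splicing"
    elif differs_5utr:
        primary = "alt_promoter"
    elif differs_3utr:
        primary = "alt_3utr"
    elif no_cds and (diff_in_a or diff_in_b):
        primary = "alt_splicing"
    else:
        primary = None

    return StructuralDiff(
        differs_5utr=differs_5utr,
        differs_exons=differs_exons,
        differs_3utr=differs_3utr,
        coding_change=coding_change,
        primary_category=primary,
        no_cds=no_cds,
    )


# ---------------------------------------------------------------------------
# summaries


@dataclass
class PairSummary:
    """Category and event-type composition of differential isoform pairs."""

    n_pairs: int
    category_fractions: Dict[str, float]
    event_type_fractions: Dict[str, float]
    complex_count: int
    inclusion_counts: Dict[str, Dict[str, int]]  # event type -> subtype -> n


def summarize_pairs(
    pair_results: Sequence,
    events_by_pair: Dict[Tuple[str, str], List[SpliceEvent]],
    dedupe_events: bool = False,
) -> PairSummary:
    """Aggregate differential pairs into the three-way category split and
    the four-way splice-event split, plus inclusion counts by subtype.

    ``pair_results`` are IsoformPairResult objects with ``structural_diff``
    attached; ``events_by_pair`` maps (iso_a, iso_b) to called events.  For
    each skipping/retention event the subtype favoring the inclusion
    isoform is read from the sign of the pair's interaction beta.  With
    ``dedupe_events`` each unique (type, interval) genomic event counts
    once; the default counts per pair-event occurrence.
    """
    cat_counts: Dict[str, int] = {}
    n_with_cat = 0
    type_counts: Dict[str, int] = {t: 0 for t in INTERNAL_EVENT_TYPES}
    complex_count = 0
    inclusion: Dict[str, Dict[str, int]] = {
        "exon_skipping": {"ERpos": 0, "TN": 0},
        "intron_retention": {"ERpos": 0, "TN": 0},
    }
    seen = set()
    for pr in pair_results:
        sd = pr.structural_diff
        if sd is not None and sd.primary_category is not None:
            cat_counts[sd.primary_category] = (
                cat_counts.get(sd.primary_category, 0) + 1
            )
            n_with_cat += 1
        for ev in events_by_pair.get((pr.iso_a, pr.iso_b), []):
            if dedupe_events:
                key = (ev.type, ev.chrom, ev.interval)
                if key in seen:
                    continue
                seen.add(key)
            if ev.type == "complex":
                complex_count += 1
                continue
            if ev.type in type_counts:
                type_counts[ev.type] += 1
            if ev.type in inclusion and ev.inclusion_isoform is not None:
                favored = (
                    "TN"
                    if ev.inclusion_isoform == pr.tn_favored_isoform
                    else "ERpos"
                )
                inclusion[ev.type][favored] += 1

    total_events = sum(type_counts.values())
    return PairSummary(
        n_pairs=len(pair_results),
        category_fractions={
            k: v / n_with_cat for k, v in sorted(cat_counts.items())
        }
        if n_with_cat
        else {},
        event_type_fractions={
            k: (v / total_events if total_events else 0.0)
            for k, v in type_counts.items()
        },
        complex_count=complex_count,
        inclusion_counts=inclusion,
    )


def events_to_bed(
    events_with_genes: Sequence[Tuple[SpliceEvent, str]]
) -> IntervalTrack:
    """One BED interval per event, name = type:gene_id."""
    return IntervalTrack(
        tuple(
            (ev.chrom, ev.interval[0], ev.interval[1], f"{ev.type}:{gene}")
            for ev, gene in events_with_genes
        )
    )
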