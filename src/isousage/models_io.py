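"""Core genomic data types and flat-file I/O.

All coordinates are held internally as 0-based half-open intervals; the
1-based closed convention of GTF is converted at the I/O boundary only.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

__all__ = [
    "TranscriptModel",
    "SampleAnnotation",
    "ExpressionMatrix",
    "IntervalTrack",
    "GtfParseError",
    "read_gtf",
    "write_gtf",
    "read_expression_table",
    "write_expression_table",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_bed",
    "write_bed",
    "read_gene_list",
    "group_by_gene",
]

SUBTYPES = ("ERpos", "TN")
PLATFORMS = ("rnaseq", "nanostring")


class GtfParseError(ValueError):
    """Raised for malformed GTF input; carries the offending line number."""


@dataclass(frozen=True)
class TranscriptModel:
    """Exon/CDS structure of one transcript isoform on a genome.

    ``exons`` are 0-based half-open genomic intervals sorted by start and
    pairwise non-overlapping.  ``cds``, when present, is the genomic span
    from the first to the last coding base (also 0-based half-open); both
    endpoints must fall inside exons.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple
    cds: Optional[tuple] = None
    attributes: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        exons = tuple((int(s), int(e)) for s, e in self.exons)
        if not exons:
            raise ValueError(f"transcript {self.transcript_id}: zero exons")
        for s, e in exons:
            if s >= e:
                raise ValueError(
                    f"transcript {self.transcript_id}: empty exon ({s},{e})"
                )
        if list(exons) != sorted(exons):
            raise ValueError(f"transcript {self.transcript_id}: exons not sorted")
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if s2 < e1:
                raise ValueError(
                    f"transcript {self.transcript_id}: overlapping exons"
                )
        object.__setattr__(self, "exons", exons)
        if self.cds is not None:
            cs, ce = int(self.cds[0]), int(self.cds[1])
            if cs >= ce:
                raise ValueError(f"transcript {self.transcript_id}: empty CDS")
            if cs < exons[0][0] or ce > exons[-1][1]:
                raise ValueError(
                    f"transcript {self.transcript_id}: CDS outside transcript span"
                )
            if not self._covers(exons, cs) or not self._covers(exons, ce - 1):
                raise ValueError(
                    f"transcript {self.transcript_id}: CDS endpoint not exonic"
                )
            object.__setattr__(self, "cds", (cs, ce))
        object.__setattr__(self, "attributes", dict(self.attributes))

    @staticmethod
    def _covers(exons, pos):
        return any(s <= pos < e for s, e in exons)

    @property
    def span(self):
        return (self.exons[0][0], self.exons[-1][1])

    @property
    def introns(self):
        """Gaps between consecutive exons, 0-based half-open."""
        return tuple(
            (e1, s2) for (_, e1), (s2, _) in zip(self.exons, self.exons[1:])
        )

    @property
    def exonic_length(self):
        return sum(e - s for s, e in self.exons)


@dataclass(frozen=True)
class SampleAnnotation:
    sample_id: str
    subtype: str
    cohort: str = "default"
    platform: str = "rnaseq"

    def __post_init__(self):
        if self.subtype not in SUBTYPES:
            raise ValueError(
                f"unknown subtype {self.subtype!r}; accepted labels: {SUBTYPES}"
            )
        if self.platform not in PLATFORMS:
            raise ValueError(
                f"unknown platform {self.platform!r}; accepted: {PLATFORMS}"
            )


SCALE_TAGS = ("raw", "quantile_normalized", "log2p1", "centered", "residual")


@dataclass
class ExpressionMatrix:
    """Transcripts (rows) x samples (columns) abundance matrix.

    ``data`` is a pandas DataFrame with unique row and column labels.
    ``scale_tag`` records the measurement scale and may only change
    through the normalization operations.
    """

    data: pd.DataFrame
    scale_tag: str = "raw"

    def __post_init__(self):
        if self.scale_tag not in SCALE_TAGS:
            raise ValueError(f"unknown scale_tag {self.scale_tag!r}")
        if self.data.index.duplicated().any():
            dupes = self.data.index[self.data.index.duplicated()].unique()
            raise ValueError(f"duplicate row ids: {list(dupes)[:5]}")
        if self.data.columns.duplicated().any():
            raise ValueError("duplicate sample ids")
        if self.scale_tag == "raw" and (self.data.values < 0).any():
            r, c = divmod(int((self.data.values < 0).argmax()), self.data.shape[1])
            raise ValueError(
                f"negative value at row {self.data.index[r]!r}, "
                f"column {self.data.columns[c]!r} on raw scale"
            )

    @property
    def row_ids(self):
        return list(self.data.index)

    @property
    def col_ids(self):
        return list(self.data.columns)

    @property
    def shape(self):
        return self.data.shape

    def subset_rows(self, ids: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.loc[list(ids)], self.scale_tag)

    def subset_cols(self, ids: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data[list(ids)], self.scale_tag)


@dataclass(frozen=True)
class IntervalTrack:
    """Named genomic intervals (BED-like, 0-based half-open)."""

    intervals: tuple

    def __post_init__(self):
        ivs = tuple(
            (str(c), int(s), int(e), str(n)) for c, s, e, n in self.intervals
        )
        for c, s, e, n in ivs:
            if s >= e:
                raise ValueError(f"interval {n}: start {s} >= end {e}")
        object.__setattr__(self, "intervals", ivs)

    def __len__(self):
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    def overlapping(self, chrom: str, start: int, end: int):
        return [
            iv for iv in self.intervals
            if iv[0] == chrom and iv[1] < end and iv[2] > start
        ]


# ---------------------------------------------------------------------------
# GTF


def _parse_gtf_attributes(text: str) -> dict:
    attrs = {}
    for chunk in text.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        key, _, value = chunk.partition(" ")
        attrs[key] = value.strip().strip('"')
    return attrs


def read_gtf(path) -> list:
    """Read exon/CDS features from a GTF file into TranscriptModel objects.

    GTF coordinates (1-based closed) are converted to 0-based half-open.
    Exons are sorted; the CDS span is min(CDS starts)..max(CDS ends).
    """
    exons: dict = {}
    cds: dict = {}
    meta: dict = {}
    order: list = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GtfParseError(
                    f"{path}: line {lineno}: expected 9 tab-separated fields, "
                    f"got {len(fields)}"
                )
            chrom, _source, feature, start, end, _score, strand, _frame, attr = fields
            if feature not in ("exon", "CDS"):
                continue
            try:
                start0, end0 = int(start) - 1, int(end)
            except ValueError:
                raise GtfParseError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from None
            attrs = _parse_gtf_attributes(attr)
            try:
                tid, gid = attrs["transcript_id"], attrs["gene_id"]
            except KeyError as exc:
                raise GtfParseError(
                    f"{path}: line {lineno}: missing attribute {exc}"
                ) from None
            if tid not in meta:
                meta[tid] = (gid, chrom, strand, attrs)
                order.append(tid)
            if feature == "exon":
                exons.setdefault(tid, []).append((start0, end0))
            else:
                cds.setdefault(tid, []).append((start0, end0))
    models = []
    for tid in order:
        gid, chrom, strand, attrs = meta[tid]
        if tid not in exons:
            raise GtfParseError(f"transcript {tid}: zero exon features")
        ex = sorted(exons[tid])
        cds_span = None
        if tid in cds:
            cds_span = (min(s for s, _ in cds[tid]), max(e for _, e in cds[tid]))
        extra = {
            k: v for k, v in attrs.items()
            if k not in ("gene_id", "transcript_id")
        }
        models.append(
            TranscriptModel(tid, gid, chrom, strand, tuple(ex), cds_span, extra)
        )
    return models


def write_gtf(models: Iterable[TranscriptModel], path) -> None:
    """Write transcripts as exon (and CDS) GTF features, 1-based closed."""
    with open(path, "w") as fh:
        for tx in models:
            attr = f'gene_id "{tx.gene_id}"; transcript_id "{tx.transcript_id}";'
            for s, e in tx.exons:
                fh.write(
                    f"{tx.chrom}\tisousage\texon\t{s + 1}\t{e}\t.\t{tx.strand}\t.\t{attr}\n"
                )
            if tx.cds is not None:
                cs, ce = tx.cds
                # emit CDS clipped to exons so the span round-trips
                for s, e in tx.exons:
                    lo, hi = max(s, cs), min(e, ce)
                    if lo < hi:
                        fh.write(
                            f"{tx.chrom}\tisousage\tCDS\t{lo + 1}\t{hi}\t.\t{tx.strand}\t0\t{attr}\n"
                        )


# ---------------------------------------------------------------------------
# Expression tables / sample sheets / BED / gene lists


def read_expression_table(path) -> ExpressionMatrix:
    """Read a TSV abundance table (first column = transcript ids) as raw scale."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.isna().any().any():
        bad = df.index[df.isna().any(axis=1)][0]
        raise ValueError(f"missing/ragged value in row {bad!r}")
    df = df.astype(float)
    return ExpressionMatrix(df, scale_tag="raw")


def write_expression_table(matrix: ExpressionMatrix, path) -> None:
    matrix.data.to_csv(path, sep="\t", index_label="transcript_id")


def read_sample_sheet(path) -> list:
    """Read a TSV sample sheet (sample_id, subtype, cohort, platform)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "subtype"}
    if not required.issubset(df.columns):
        raise ValueError(f"sample sheet must have columns {sorted(required)}")
    if df["sample_id"].duplicated().any():
        raise ValueError("duplicate sample_id in sheet")
    out = []
    for _, row in df.iterrows():
        out.append(
            SampleAnnotation(
                sample_id=row["sample_id"],
                subtype=row["subtype"],
                cohort=row.get("cohort", "default") or "default",
                platform=row.get("platform", "rnaseq") or "rnaseq",
            )
        )
    return out


def write_sample_sheet(annotations: Iterable[SampleAnnotation], path) -> None:
    pd.DataFrame(
        [
            {
                "sample_id": a.sample_id,
                "subtype": a.subtype,
                "cohort": a.cohort,
                "platform": a.platform,
            }
            for a in annotations
        ]
    ).to_csv(path, sep="\t", index=False)


def read_bed(path) -> IntervalTrack:
    """Read BED4 (chrom, start, end, name); BED is already 0-based half-open."""
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise ValueError(f"{path}: line {lineno}: fewer than 3 BED fields")
            name = fields[3] if len(fields) > 3 else f"interval_{lineno}"
            intervals.append((fields[0], int(fields[1]), int(fields[2]), name))
    return IntervalTrack(tuple(intervals))


def write_bed(track: IntervalTrack, path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, name in track:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\n")


def read_gene_list(path) -> set:
    """Read a plain-text list of identifiers, one per line."""
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}


def group_by_gene(models: Iterable[TranscriptModel]) -> dict:
    """Group transcripts into genes by exact gene_id string match."""
    genes: dict = {}
    for tx in models:
        genes.setdefault(tx.gene_id, []).append(tx)
    return genes
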