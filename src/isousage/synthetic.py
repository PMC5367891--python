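"""Synthetic two-subtype cohort generator with known ground truth.

Emulates the statistical structure of a bulk RNA-seq breast-cancer cohort:
multi-isoform gene models on a synthetic chromosome, log-normal FPKM-like
abundances with gene-level subtype effects and planted subtype x isoform
interactions ("isoform switches"), NanoString-like overdispersed probe
counts with assay/well/library effects, knockdown expression profiles whose
direction of response is tunably concordant with the subtype signature, and
binding-site tracks with a planted odds-ratio enrichment near
knockdown-responsive genes.

Determinism: every generator draws from per-gene substreams derived from
``SeedSequence(config.seed, spawn_key=(stream, gene_index))``, so changing
one configuration field never re-randomizes unrelated genes.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .models_io import (
    ExpressionMatrix,
    IntervalTrack,
    SampleAnnotation,
    TranscriptModel,
    group_by_gene,
)

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "NanoStringData",
    "simulate_gene_models",
    "simulate_cohort",
    "simulate_nanostring",
    "simulate_knockdown",
    "simulate_binding_sites",
]

VARIANT_TYPES = (
    "skip",
    "retention",
    "alt_donor",
    "alt_acceptor",
    "alt_first_exon",
    "alt_last_exon",
)

# substream namespace: one id per generator
(
    _S_MODELS,
    _S_COHORT,
    _S_NSFACTORS,
    _S_NSCOUNTS,
    _S_KD,
    _S_BINDING,
    _S_COHORT_NOISE,
) = range(7)


def _rng(seed: int, stream: int, index: int = 0) -> np.random.Generator:
    return np.random.Generator(
        np.random.PCG64(np.random.SeedSequence(seed, spawn_key=(stream, index)))
    )


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic cohort.

    Defaults emulate the discovery-cohort conditions: 11 ER+ and 14 TN
    samples, a two-unit log2 usage shift for switched isoform pairs, and
    residual noise of 0.5 on the log2 scale.  ``isoform_count_distribution``
    defaults to roughly three quarters single-isoform genes, matching the
    RefSeq-wide proportion of multi-isoform gene models.
    """

    n_genes: int = 200
    isoform_count_distribution: Dict[int, float] = field(
        default_factory=lambda: {1: 0.765, 2: 0.14, 3: 0.06, 4: 0.035}
    )
    n_samples_ERpos: int = 11
    n_samples_TN: int = 14
    switch_fraction: float = 0.1
    switch_effect: float = 2.0
    gene_de_fraction: float = 0.1
    gene_de_effect: float = 2.0
    noise_sd: float = 0.5
    nb_dispersion: float = 10.0
    kd_concordance: float = 0.75
    kd_effect: float = 2.0
    kd_background_rate: float = 0.05
    binding_enrichment: float = 3.0
    binding_base_rate: float = 0.2
    variant_types: Tuple[str, ...] = VARIANT_TYPES
    # RefSeq-like composition: splice-structure variants dominated by exon
    # skipping, with alternative first exons (promoter switches) the next
    # largest class and 3' end switches the smallest
    variant_weights: Dict[str, float] = field(
        default_factory=lambda: {
            "skip": 0.390,
            "retention": 0.072,
            "alt_donor": 0.048,
            "alt_acceptor": 0.125,
            "alt_first_exon": 0.243,
            "alt_last_exon": 0.122,
        }
    )
    seed: int = 0

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        probs = self.isoform_count_distribution
        if not probs:
            raise ValueError("isoform_count_distribution is empty")
        if any(p < 0 for p in probs.values()) or not math.isclose(
            sum(probs.values()), 1.0, abs_tol=1e-9
        ):
            raise ValueError("isoform counts must carry probabilities summing to 1")
        for name in (
            "switch_fraction",
            "gene_de_fraction",
            "kd_concordance",
            "kd_background_rate",
            "binding_base_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        for name in ("switch_effect", "gene_de_effect", "noise_sd", "kd_effect"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if self.binding_enrichment <= 0:
            raise ValueError("binding_enrichment must be positive")
        unknown = set(self.variant_types) - set(VARIANT_TYPES)
        if unknown:
            raise ValueError(f"unknown variant types: {sorted(unknown)}")
        if any(w < 0 for w in self.variant_weights.values()):
            raise ValueError("variant weights must be non-negative")

    def replace(self, **kwargs) -> "SimulationConfig":
        return dataclasses.replace(self, **kwargs)

    @classmethod
    def from_file(cls, path) -> "SimulationConfig":
        """Read a flat ``key = value`` configuration file."""
        kwargs: dict = {}
        with open(path) as fh:
            for line in fh:
                line = line.split("#")[0].strip()
                if not line:
                    continue
                key, _, value = line.partition("=")
                key, value = key.strip(), value.strip()
                if key == "isoform_count_distribution":
                    dist = {}
                    for item in value.split(","):
                        k, _, p = item.partition(":")
                        dist[int(k)] = float(p)
                    kwargs[key] = dist
                elif key == "variant_types":
                    kwargs[key] = tuple(v.strip() for v in value.split(","))
                elif key in ("n_genes", "n_samples_ERpos", "n_samples_TN", "seed"):
                    kwargs[key] = int(value)
                else:
                    kwargs[key] = float(value)
        return cls(**kwargs)


@dataclass
class GroundTruth:
    """Planted effects, recorded per gene and per isoform at generation time."""

    gene_de: Dict[str, int] = field(default_factory=dict)  # gene -> sign or 0
    switch_pair: Dict[str, Tuple[str, str]] = field(default_factory=dict)
    isoform_direction: Dict[str, int] = field(default_factory=dict)  # TN sign
    kd_direction: Dict[str, int] = field(default_factory=dict)
    gene_bound: Dict[str, bool] = field(default_factory=dict)

    @property
    def switched_genes(self) -> set:
        return set(self.switch_pair)

    @property
    def de_genes(self) -> set:
        return {g for g, s in self.gene_de.items() if s != 0}

    @property
    def switched_isoforms(self) -> set:
        return {t for t, d in self.isoform_direction.items() if d != 0}

    @property
    def kd_responsive_isoforms(self) -> set:
        return {t for t, d in self.kd_direction.items() if d != 0}

    def write_tsv(self, path) -> None:
        rows = []
        for tx, d in sorted(self.isoform_direction.items()):
            rows.append(
                {
                    "transcript_id": tx,
                    "subtype_direction": d,
                    "kd_direction": self.kd_direction.get(tx, 0),
                }
            )
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# gene models


def _snap_cds(exons: Sequence[Tuple[int, int]], cs: int, ce: int):
    """Clamp a tentative CDS span so both endpoints are exonic bases."""
    starts = [s for s, _ in exons]
    # first exonic base >= cs
    snapped_start = None
    for s, e in exons:
        if e > cs:
            snapped_start = max(s, cs)
            break
    # last exonic base < ce
    snapped_end = None
    for s, e in reversed(exons):
        if s < ce:
            snapped_end = min(e, ce)
            break
    if snapped_start is None or snapped_end is None or snapped_start >= snapped_end:
        return None
    return (snapped_start, snapped_end)


def _apply_variant(
    exons: List[Tuple[int, int]], variant: str, strand: str, rng: np.random.Generator
) -> List[Tuple[int, int]]:
    """Apply one structural variant to a base exon chain; returns new exons."""
    exons = list(exons)
    n = len(exons)
    if variant == "skip" and n >= 3:
        k = int(rng.integers(1, n - 1))
        del exons[k]
    elif variant == "retention" and n >= 2:
        k = int(rng.integers(0, n - 1))
        merged = (exons[k][0], exons[k + 1][1])
        exons[k : k + 2] = [merged]
    elif variant in ("alt_donor", "alt_acceptor") and n >= 2:
        k = int(rng.integers(0, n - 1))  # intron index
        delta = int(rng.integers(20, 61))
        # donor is the intron boundary at the 5' side in transcription
        # direction: intron start on '+', intron end on '-'
        shift_start = (variant == "alt_donor") == (strand == "+")
        if shift_start:
            s, e = exons[k]
            if e - s > delta + 20:
                exons[k] = (s, e - delta)
        else:
            s, e = exons[k + 1]
            if e - s > delta + 20:
                exons[k + 1] = (s + delta, e)
    elif variant == "alt_first_exon" and n >= 2:
        length = int(rng.integers(100, 201))
        gap = int(rng.integers(300, 601))
        if strand == "+":
            s0 = exons[0][0]
            exons[0:1] = []
            exons.insert(0, (s0 - gap - length, s0 - gap))
        else:
            e0 = exons[-1][1]
            exons[-1:] = []
            exons.append((e0 + gap, e0 + gap + length))
    elif variant == "alt_last_exon" and n >= 2:
        length = int(rng.integers(100, 201))
        gap = int(rng.integers(300, 601))
        if strand == "+":
            e0 = exons[-1][1]
            exons[-1:] = []
            exons.append((e0 + gap, e0 + gap + length))
        else:
            s0 = exons[0][0]
            exons[0:1] = []
            exons.insert(0, (s0 - gap - length, s0 - gap))
    return exons


def simulate_gene_models(config: SimulationConfig) -> List[TranscriptModel]:
    """Lay out non-overlapping multi-isoform genes on a synthetic chromosome.

    Each extra isoform of a gene is derived from the gene's base transcript
    by exactly one structural variant drawn from ``config.variant_types``:
    an internal exon skip, an intron retention, a donor or acceptor shift,
    or an alternative first/last exon (distinct TSS / 3' end).  A CDS span
    is assigned so that variants fall in coding or untranslated regions in
    different genes.
    """
    counts = sorted(config.isoform_count_distribution.items())
    count_vals = np.array([k for k, _ in counts])
    count_probs = np.array([p for _, p in counts], dtype=float)

    models: List[TranscriptModel] = []
    cursor = 10_000  # leave headroom for upstream alternative first exons
    chrom = "chrS"
    for i in range(config.n_genes):
        rng = _rng(config.seed, _S_MODELS, i)
        gene_id = f"SIMG{i:05d}"
        strand = "+" if rng.random() < 0.5 else "-"
        n_exons = int(rng.integers(4, 9))
        exon_lens = rng.integers(120, 301, n_exons)
        intron_lens = rng.integers(300, 1001, n_exons - 1)
        exons = []
        pos = cursor
        for j in range(n_exons):
            exons.append((pos, pos + int(exon_lens[j])))
            pos += int(exon_lens[j])
            if j < n_exons - 1:
                pos += int(intron_lens[j])
        # CDS endpoints inside first-or-second / last-or-penultimate exon,
        # so terminal variants hit pure-UTR and coding cases across genes
        cs_exon = exons[int(rng.integers(0, 2))]
        ce_exon = exons[n_exons - 1 - int(rng.integers(0, 2))]
        cs = int(rng.integers(cs_exon[0] + 10, cs_exon[1] - 10))
        ce = int(rng.integers(ce_exon[0] + 10, ce_exon[1] - 10))
        if cs >= ce:
            cs, ce = exons[0][0] + 10, exons[-1][1] - 10

        n_iso = int(rng.choice(count_vals, p=count_probs))
        weights = np.array(
            [config.variant_weights.get(v, 0.0) for v in config.variant_types]
        )
        probs = (
            weights / weights.sum()
            if weights.sum() > 0
            else np.full(len(config.variant_types), 1.0 / len(config.variant_types))
        )
        iso_exons = [list(exons)]
        for _ in range(1, n_iso):
            variant = str(rng.choice(list(config.variant_types), p=probs))
            iso_exons.append(_apply_variant(exons, variant, strand, rng))

        for j, ex in enumerate(iso_exons):
            ex = sorted(ex)
            cds = _snap_cds(ex, cs, ce)
            models.append(
                TranscriptModel(
                    transcript_id=f"{gene_id}.{j + 1}",
                    gene_id=gene_id,
                    chrom=chrom,
                    strand=strand,
                    exons=tuple(ex),
                    cds=cds,
                )
            )
        gene_end = max(e for tx in iso_exons for _, e in tx)
        # realistic intergenic spacing; also keeps a +-25 kb binding-site
        # window from straddling neighboring genes
        cursor = gene_end + 60_000
    return models


# ---------------------------------------------------------------------------
# expression cohort


def simulate_cohort(
    models: Sequence[TranscriptModel],
    config: SimulationConfig,
    cohort_seed: Optional[int] = None,
    sample_prefix: str = "",
):
    """Draw an FPKM-like cohort with planted gene DE and isoform switches.

    Per-transcript log2 abundance = baseline + gene subtype effect (DE
    genes, TN samples) + isoform offset + subtype x isoform interaction
    (switched pairs, magnitude ``switch_effect``) + Normal(0, noise_sd).
    The emitted matrix is on the raw scale (2**x).

    The planted effects are keyed by ``config.seed``; the residual noise by
    ``cohort_seed`` (default: same as the config seed).  Passing a
    different ``cohort_seed`` therefore draws an independent replication
    cohort with the same underlying biology, as when profiling a second
    patient series.
    """
    if config.n_samples_ERpos < 1 or config.n_samples_TN < 1:
        raise ValueError("each subtype needs at least one sample")
    if cohort_seed is None:
        cohort_seed = config.seed
    annotations = [
        SampleAnnotation(f"{sample_prefix}ER{k + 1:02d}", "ERpos", cohort="sim")
        for k in range(config.n_samples_ERpos)
    ] + [
        SampleAnnotation(f"{sample_prefix}TN{k + 1:02d}", "TN", cohort="sim")
        for k in range(config.n_samples_TN)
    ]
    sample_ids = [a.sample_id for a in annotations]
    is_tn = np.array([a.subtype == "TN" for a in annotations], dtype=float)
    n = len(sample_ids)

    genes = group_by_gene(models)
    truth = GroundTruth()
    rows = []
    row_ids = []
    for i, (gene_id, txs) in enumerate(sorted(genes.items())):
        rng = _rng(config.seed, _S_COHORT, i)
        noise_rng = _rng(cohort_seed, _S_COHORT_NOISE, i)
        baseline = rng.normal(5.0, 1.5)
        de_sign = 0
        if rng.random() < config.gene_de_fraction:
            de_sign = 1 if rng.random() < 0.5 else -1
        truth.gene_de[gene_id] = de_sign

        tx_ids = sorted(tx.transcript_id for tx in txs)
        offsets = rng.normal(0.0, 1.0, len(tx_ids))
        interaction = {t: 0.0 for t in tx_ids}
        for t in tx_ids:
            truth.isoform_direction[t] = 0
        if len(tx_ids) >= 2 and rng.random() < config.switch_fraction:
            a, b = (
                tx_ids[int(k)]
                for k in rng.choice(len(tx_ids), size=2, replace=False)
            )
            a, b = min(a, b), max(a, b)
            sign = 1 if rng.random() < 0.5 else -1
            interaction[a] = sign * config.switch_effect / 2.0
            interaction[b] = -sign * config.switch_effect / 2.0
            truth.switch_pair[gene_id] = (a, b)
            truth.isoform_direction[a] = sign
            truth.isoform_direction[b] = -sign

        for t, off in zip(tx_ids, offsets):
            x = (
                baseline
                + off
                + is_tn * (de_sign * config.gene_de_effect)
                + is_tn * interaction[t]
                + (
                    noise_rng.normal(0.0, config.noise_sd, n)
                    if config.noise_sd > 0
                    else 0.0
                )
            )
            rows.append(np.exp2(x))
            row_ids.append(t)

    matrix = ExpressionMatrix(
        pd.DataFrame(rows, index=row_ids, columns=sample_ids), scale_tag="raw"
    )
    return matrix, annotations, truth


# ---------------------------------------------------------------------------
# NanoString


@dataclass
class NanoStringData:
    """Probe count table plus probe classes and per-sample assay/well info."""

    counts: pd.DataFrame  # probes x samples, integer
    probe_class: pd.Series  # endogenous / negative / housekeeping
    sample_info: pd.DataFrame  # sample_id, assay, well

    def write_tsv(self, counts_path, info_path) -> None:
        out = self.counts.copy()
        out.insert(0, "probe_class", self.probe_class)
        out.to_csv(counts_path, sep="\t", index_label="probe_id")
        self.sample_info.to_csv(info_path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, counts_path, info_path) -> "NanoStringData":
        df = pd.read_csv(counts_path, sep="\t", index_col=0)
        probe_class = df.pop("probe_class")
        return cls(df, probe_class, pd.read_csv(info_path, sep="\t"))


def _nb_draw(rng, mean, theta):
    mean = np.maximum(np.asarray(mean, dtype=float), 1e-8)
    if not np.isfinite(theta):
        return rng.poisson(mean)
    p = theta / (theta + mean)
    return rng.negative_binomial(theta, p)


def simulate_nanostring(
    matrix: ExpressionMatrix,
    pairs: Sequence[Tuple[str, str]],
    config: SimulationConfig,
    n_negative: int = 8,
    n_housekeeping: int = 10,
    samples_per_assay: int = 12,
    assay_sd: float = 0.15,
    well_sd: float = 0.10,
    library_sd: float = 0.20,
) -> NanoStringData:
    """Draw NanoString-like probe counts for the isoforms in ``pairs``.

    Counts are NegativeBinomial with mean = expression x assay factor x
    well factor x library factor and dispersion ``config.nb_dispersion``
    (infinite dispersion gives the Poisson limit).  Negative-control and
    housekeeping probes are included; each sample carries assay (cartridge)
    and well annotations.
    """
    probe_ids = sorted({t for pair in pairs for t in pair})
    missing = [t for t in probe_ids if t not in matrix.data.index]
    if missing:
        raise ValueError(f"pair isoforms absent from matrix: {missing[:5]}")
    samples = matrix.col_ids
    assays = [f"A{k // samples_per_assay + 1}" for k in range(len(samples))]
    wells = [f"W{k % samples_per_assay + 1:02d}" for k in range(len(samples))]

    frng = _rng(config.seed, _S_NSFACTORS, 0)
    assay_factor = {
        a: (frng.lognormal(0.0, assay_sd) if assay_sd > 0 else 1.0)
        for a in sorted(set(assays))
    }
    well_factor = {
        w: (frng.lognormal(0.0, well_sd) if well_sd > 0 else 1.0)
        for w in sorted(set(wells))
    }
    lib_factor = (
        frng.lognormal(0.0, library_sd, len(samples))
        if library_sd > 0
        else np.ones(len(samples))
    )
    sample_factor = np.array(
        [
            assay_factor[a] * well_factor[w] * lf
            for a, w, lf in zip(assays, wells, lib_factor)
        ]
    )

    hk_base = frng.lognormal(np.log(2000.0), 0.3, n_housekeeping)
    theta = config.nb_dispersion
    count_rows = []
    classes = []
    all_ids = []
    for j, pid in enumerate(probe_ids):
        rng = _rng(config.seed, _S_NSCOUNTS, j)
        mean = 20.0 * matrix.data.loc[pid].to_numpy() * sample_factor
        count_rows.append(_nb_draw(rng, mean, theta))
        classes.append("endogenous")
        all_ids.append(pid)
    for j in range(n_housekeeping):
        rng = _rng(config.seed, _S_NSCOUNTS, len(probe_ids) + j)
        count_rows.append(_nb_draw(rng, hk_base[j] * sample_factor, theta))
        classes.append("housekeeping")
        all_ids.append(f"HK{j + 1:02d}")
    for j in range(n_negative):
        rng = _rng(
            config.seed, _S_NSCOUNTS, len(probe_ids) + n_housekeeping + j
        )
        count_rows.append(_nb_draw(rng, 4.0 * np.ones(len(samples)), theta))
        classes.append("negative")
        all_ids.append(f"NEG{j + 1:02d}")

    counts = pd.DataFrame(
        np.vstack(count_rows).astype(int), index=all_ids, columns=samples
    )
    info = pd.DataFrame(
        {"sample_id": samples, "assay": assays, "well": wells}
    )
    return NanoStringData(counts, pd.Series(classes, index=all_ids), info)


# ---------------------------------------------------------------------------
# knockdown and binding sites


def simulate_knockdown(
    models: Sequence[TranscriptModel],
    truth: GroundTruth,
    config: SimulationConfig,
    n_replicates: int = 2,
) -> ExpressionMatrix:
    """Control + knockdown expression profiles (biological replicates).

    Subtype-switched isoforms always respond to the knockdown; with
    probability ``kd_concordance`` the response direction is the expected
    one — opposing the isoform's TN-vs-ER+ sign, as when an ER+-associated
    factor is depleted in an ER+ background and isoforms shift toward their
    TN state — otherwise it is flipped.  Non-switched isoforms respond at
    ``kd_background_rate`` with a random direction.  Response directions
    are recorded in ``truth.kd_direction``.
    """
    genes = group_by_gene(models)
    cols = [f"ctrl_rep{r + 1}" for r in range(n_replicates)] + [
        f"kd_rep{r + 1}" for r in range(n_replicates)
    ]
    is_kd = np.array([c.startswith("kd") for c in cols], dtype=float)
    rows, row_ids = [], []
    for i, (gene_id, txs) in enumerate(sorted(genes.items())):
        rng = _rng(config.seed, _S_KD, i)
        baseline = rng.normal(5.0, 1.5)
        for tx in sorted(txs, key=lambda t: t.transcript_id):
            t = tx.transcript_id
            offset = rng.normal(0.0, 1.0)
            sub_dir = truth.isoform_direction.get(t, 0)
            if sub_dir != 0:
                concordant = rng.random() < config.kd_concordance
                kd_dir = -sub_dir if concordant else sub_dir
            elif rng.random() < config.kd_background_rate:
                kd_dir = 1 if rng.random() < 0.5 else -1
            else:
                kd_dir = 0
            truth.kd_direction[t] = kd_dir
            x = (
                baseline
                + offset
                + is_kd * (kd_dir * config.kd_effect)
                + (
                    rng.normal(0.0, config.noise_sd, len(cols))
                    if config.noise_sd > 0
                    else 0.0
                )
            )
            rows.append(np.exp2(x))
            row_ids.append(t)
    return ExpressionMatrix(
        pd.DataFrame(rows, index=row_ids, columns=cols), scale_tag="raw"
    )


def simulate_binding_sites(
    models: Sequence[TranscriptModel],
    truth: GroundTruth,
    config: SimulationConfig,
    site_length: int = 200,
    placement_window: int = 5_000,
) -> IntervalTrack:
    """Place binding sites near genes, enriched at knockdown-responsive ones.

    A gene is bound with base odds ``binding_base_rate / (1 - rate)``,
    multiplied by ``binding_enrichment`` when any of its isoforms is
    knockdown-responsive, so the planted odds ratio equals the enrichment
    parameter.  Bound status is recorded in ``truth.gene_bound``.
    """
    genes = group_by_gene(models)
    base_odds = config.binding_base_rate / (1.0 - config.binding_base_rate)
    intervals = []
    for i, (gene_id, txs) in enumerate(sorted(genes.items())):
        rng = _rng(config.seed, _S_BINDING, i)
        responsive = any(
            truth.kd_direction.get(tx.transcript_id, 0) != 0 for tx in txs
        )
        odds = base_odds * (config.binding_enrichment if responsive else 1.0)
        p = odds / (1.0 + odds)
        bound = rng.random() < p
        truth.gene_bound[gene_id] = bound
        if bound:
            span_start = min(tx.span[0] for tx in txs)
            span_end = max(tx.span[1] for tx in txs)
            lo = max(0, span_start - placement_window)
            hi = span_end + placement_window - site_length
            start = int(rng.integers(lo, max(lo + 1, hi)))
            intervals.append(
                (txs[0].chrom, start, start + site_length, f"site_{gene_id}")
            )
    return IntervalTrack(tuple(intervals))
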