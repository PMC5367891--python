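# Methods

This note documents the models, the synthetic-data generator, the numerical
choices and the known limitations of the package. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Differential isoform usage model

Subtype-specific isoform usage is tested per gene with the fixed-effects
linear model

    y ~ m0 + subtype + isoform + subtype*isoform + E,   E ~ N(0, s^2)

on log2(FPKM+1) responses, observations stacked as (sample, isoform) rows.
The interaction is tested by the extra-sum-of-squares F statistic (full vs
no-interaction model) with degrees of freedom ((L-1), N-2L) for L isoforms
and N = samples x L stacked observations. For isoform pairs (L = 2) the
single interaction coefficient, in treatment coding with ER+ and the
lexicographically first isoform as references, equals the TN-minus-ER+
difference of per-sample isoform log-ratio means; its sign assigns the
TN-favored isoform.

Assumptions and caveats:

- **Within-sample correlation between isoforms is ignored.** The stacked
  OLS fit treats the L observations from one sample as independent. This
  is exactly what the model formula above implies, and it is why the F
  statistic only *approximates* the squared two-sample t statistic on
  per-sample log-ratios (the estimates coincide exactly; the residual
  variance estimators differ). The test's type-I error is nevertheless
  calibrated under the generator's independent-noise model (measured
  0.052 at alpha=0.05 on 5,000 null genes; KS test against uniform not
  rejected).
- **Response scale.** All model fitting uses log2(x+1). The pseudocount
  attenuates effects for low-abundance transcripts (visible in the
  parameter-recovery tests, which check estimates on the exact log2 scale);
  variance stabilization is worth this bias for rank/significance purposes.
- **Expression filter.** A transcript enters testing when detected
  (abundance > 0) in at least 2 samples.
- Gene-level differential expression is available as a Wilcoxon rank-sum
  test (exact when combined n <= 25 and tie-free, otherwise normal
  approximation with midranks, tie and continuity corrections) and as the
  OLS model `y ~ m0 + subtype` (equivalent to the equal-variance t-test).

### Storey q-values

pi0 is estimated as #{p > lambda} / (m (1 - lambda)) over the grid
lambda = 0.05 ... 0.95 (step 0.05), smoothed by a cubic polynomial in
lambda, evaluated at lambda = 0.95 and clamped to [1/m, 1]. Then
q(p_(i)) = min_{j >= i} pi0 * m * p_(j) / j, so q-values are monotone in p,
tied p-values share a q, and pi0 = 1 reduces exactly to
Benjamini-Hochberg. With fewer than 20 p-values the estimator falls back
to pi0 = 1 with a warning. The cubic smoother is reliable for large m
(pi0 in [0.9, 1] on 10,000 uniform p-values) but can collapse toward the
1/m floor below m ~ 100, making small-panel q-values anti-conservative;
for small analyses pass `pi0=1.0` explicitly.

## Splice-event classification

Each isoform's exonic bases are labeled 5'UTR / CDS / 3'UTR from its own
CDS span, strand-aware; region flags come from the symmetric difference of
exonic base sets. Junction-level events are called from intron chains:

- *exon skipping*: an internal exon of one isoform whose two flanking
  introns fuse into a single intron of the other, outer splice sites
  shared (the exon carrier is the inclusion isoform);
- *intron retention*: an intron of one isoform strictly contained in an
  exon of the other (the exon carrier is the inclusion isoform);
- *alternative donor / acceptor*: a private intron pair sharing exactly
  one boundary; on '+' the donor is the intron start, on '-' the intron
  end, so flipping the strand annotation alone swaps donor and acceptor
  (and first/last exon), while mirroring coordinates *and* flipping strand
  preserves every event type;
- *alternative first / last exon*: disjoint terminal exons in
  transcription direction (distinct TSS / 3' end);
- anything left unexplained is emitted as `complex` rather than silently
  forced into the four-way taxonomy, and excluded from the four-way
  fractions (its count is reported).

The primary category per pair applies the priority alt_splicing (coding
base difference or internal splice event) > alt_promoter (5'UTR) >
alt_3utr. The priority is a documented choice: published three-way
fractions are mutually exclusive without a stated rule, and splicing is
the dominant class. Terminal-exon *length* differences in UTRs are UTR
categories, not splice events. Pairs lacking a CDS are classified by
splice structure only and flagged `no_cds`. Event summaries count per
pair-event occurrence by default; `dedupe_events` counts each unique
genomic event once.

## Synthetic-data generator

The generator emulates the statistical structure of a two-subtype bulk
cohort; its defaults are the reference study conditions used throughout
the tests.

- **Gene models**: genes laid out without overlap on one synthetic
  chromosome, 60 kb intergenic spacing, 4-8 exons of 120-300 bp with
  introns of 0.3-1 kb; isoform count per gene drawn from
  {1: 0.765, 2: 0.14, 3: 0.06, 4: 0.035} (roughly the RefSeq share of
  multi-isoform gene models). Each extra isoform applies one structural
  variant drawn with RefSeq-like weights (skipping 0.39, retention 0.07,
  donor 0.05, acceptor 0.13, alternative first exon 0.24, alternative
  last exon 0.12). CDS endpoints fall in the first-or-second and
  last-or-penultimate exon so both UTR-only and coding consequences occur.
- **Cohort**: 11 ER+ / 14 TN samples. Per-transcript log2 abundance =
  baseline N(5, 1.5) + isoform offset N(0, 1) + gene DE effect
  (fraction 0.1, magnitude 2, random sign, TN samples) + subtype x isoform
  interaction for switched genes (fraction 0.1 of multi-isoform genes,
  pair magnitude 2 split +-1 between the two isoforms) + N(0, 0.5) noise;
  emitted as 2^x on the raw scale. Planted effects are keyed by the config
  seed and residual noise by an optional cohort seed, so a replication
  cohort with the same biology but fresh sampling is one argument away.
- **NanoString**: counts ~ NegativeBinomial(mean = 20 x expression x assay
  x well x library factor, theta = 10), factors log-normal (sd 0.15 /
  0.10 / 0.20), 12-sample cartridges, 8 negative-control (mean 4) and 10
  housekeeping probes (mean ~2000). theta -> infinity gives the Poisson
  limit.
- **Knockdown**: two control + two knockdown replicates; switched isoforms
  always respond (magnitude 2), in the expected direction (opposite their
  TN-vs-ER+ sign, as when an ER+-associated factor is depleted in an ER+
  background) with probability `kd_concordance` = 0.75; background
  responders at rate 0.05 with random direction. The implied
  direction-concordance odds ratio is (0.75/0.25)^2 = 9.
- **Binding sites**: a gene is bound with base rate 0.2, its odds
  multiplied by `binding_enrichment` = 3 when knockdown-responsive, so the
  planted odds ratio equals the enrichment parameter; sites (200 bp) are
  placed within +-5 kb of the gene span.
- **Determinism**: every quantity is drawn from a per-gene substream
  keyed by (seed, stream id, gene index); changing one configuration field
  never re-randomizes unrelated genes, and fixed seeds give byte-identical
  output files.

What the generator does **not** model: read-level sampling (no FPKM
estimation noise structure, no length bias), correlated noise between
isoforms of a gene, batch effects in RNA-seq, heavy-tailed outliers, or
zero inflation. Passing tests therefore demonstrate correctness of the
estimators under the stated model, not robustness to every artifact of
real tumor data.

## NanoString normalization

Endogenous counts are fitted with a negative-binomial log-link GLM with
terms for assay, well, per-sample log(median negative-control + 1) and
log(median housekeeping + 1) (free slopes, not fixed offsets), and
transcript identity. The IRLS fit alternates with maximum-likelihood
updates of theta (bounded search on log theta) until the relative
deviance change is below 1e-8 (at most 100 outer iterations;
non-convergence raises). The normalized matrix holds Pearson residuals
(y - mu) / sqrt(mu + mu^2/theta); deviance residuals are available via
`residual_type`. Dispersion recovery is only guaranteed when the model is
correctly specified: biological variation across samples (noise, subtype
effects) is not in the model and inflates apparent overdispersion, which
is why the recovery experiment simulates probe-constant expression
(theta_hat within [8, 12] at theta = 10 with ~10k observations).

## Cross-platform concordance and classifier transfer

Per pair and sample, the RNA-seq side is log2((a+1)/(b+1)) (the
pseudocount is configurable) and the NanoString side the residual
difference; concordance is sign agreement among pairs with both values
nonzero. Because the transcript term centers residuals per probe, only
pairs whose ratio actually crosses zero across samples are informative —
which is also a probe-design reality. `select_probe_panel` therefore
emulates panel design by keeping switched pairs with cohort-mean
|log2 ratio| < 1.5 (up to 106 pairs / 212 probes). Under the replication
conditions (probe dispersion 30) per-sample concordance averages in the
0.80-0.85 band; this calibration was chosen once for the replication
experiment and is a smoke test of the simulator, not a validated property
of any real platform pair.

The subtype classifier is L2-penalized logistic regression (strength 1.0
on standardized features, intercept unpenalized, deterministic lbfgs from
zero start). Ridge is not optional here: with ~212 features and ~26
samples the classes are typically linearly separable and the unpenalized
likelihood diverges. ROC curves sweep all distinct scores; trapezoidal
AUC equals the Mann-Whitney rank AUC (asserted over random score sets with
ties).

## Overlap statistics

Two-sided Fisher p-values use the probability-mass rule — the sum of
hypergeometric probabilities of all margin-preserving tables no more
probable than the observed one (1e-7 relative log tolerance for ties) —
computed with log-gamma arithmetic so that p-values below 1e-30 do not
underflow. The odds ratio is the sample cross-product (a d)/(b c)
(reported as 0/inf/NaN in degenerate cases) with a Woolf logit 95%
interval; any zero cell triggers the Haldane-Anscombe 0.5 correction for
the interval only. The binding-overlap window defaults to 25 kb on each
side of the gene span. Universes for all overlap tests must be supplied
explicitly — the d cell (and hence the odds ratio) depends on it, and a
silently defaulted union universe would overstate enrichment.

## Problem sizes used in the acceptance script

Type-I error: 5,000 two-isoform null genes, 25 samples. Switch recall:
800 genes, switch fraction 0.25 (=200 planted pairs). Dispersion
recovery: 104 probes x 96 samples (~10k observations). Binding/direction
recovery: 2,000 genes. pi0: 10,000 uniform p-values. Replication: 2,200
genes, panel of up to 106 pairs, a second cohort drawn with a shifted
noise seed. These sizes give stable Monte-Carlo estimates while keeping
the full run around half a minute.

## Known limitations

- The stacked-OLS interaction test is anti-conservative if isoform
  abundances within a sample are positively correlated (shared library
  size); quantile normalization mitigates but does not remove this.
- The pi0 smoother is unstable for small numbers of tests (see above).
- Event classification operates on annotated models only; it cannot
  discover unannotated junctions, and mutually exclusive exons land in
  the `complex` bucket rather than a dedicated taxon.
- CDS handling treats the coding region as a single genomic span per
  transcript; stop-codon inclusion conventions do not change region
  labels at event granularity but would matter for codon-level analyses.
- The classifier transfer experiment shares gene models between cohorts;
  real cross-cohort transfer additionally faces annotation and
  quantification drift that is not simulated.
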