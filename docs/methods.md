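# Methods

## Problem setting and model

The unit of prediction is the exon. An exon is characterized by its
chromosome (1..24, with 23 = X and 24 = Y), its 0-based half-open
coordinates, and a normalized read-depth vector: per-base aligned-read
counts divided by the sample's mean per-base depth (pooled over all
retained exons), right-padded with zeros to a fixed window of 1000
positions. Exons longer than the window are discarded at catalog load.
Dividing by the sample mean makes the diploid baseline ≈ 1 regardless of
coverage, so a heterozygous deletion sits near 0.5 and a single-copy gain
near 1.5; this is what lets one model operate across a 10×–0.05× coverage
range. The normalization denominator is a design choice of this package
(a global autosomal-style mean rather than per-chromosome or median); it
is the simplest statistic that is finite and stable at very low coverage.

The classifier embeds the window with two length-preserving 1-D
convolutions (1 → 32 → 64 channels, kernel 3, stride 1, symmetric zero
padding, batch-norm + ReLU after each), appends a trainable per-chromosome
classification token (one 64-vector per chromosome, selected by the exon's
chromosome), adds a fixed sinusoidal positional encoding over the 1001
positions, and passes the sequence through three transformer encoder
blocks (pre-norm; 4 heads, feed-forward width 128 and dropout 0.1 by
default — all exposed in `ModelConfig`). The transformed token position is
read out through a two-layer fully connected head with softmax over
{NO-CALL, DEL, DUP}. Exact probability ties resolve to NO-CALL
(conservative no-call). The padded tail is fed to the model unmasked; the
positional encoding lets the network learn where padding lives.

Choices made where the design was genuinely open:

- **Positional encoding**: fixed sinusoidal, because it is parameter-free
  and adds no training burden at the data sizes we target.
- **Token placement**: appended at the *end* of the sequence; the read-out
  slices the last position.
- **Loss**: multiclass cross-entropy with optional inverse-frequency class
  weights. Weighting defaults to on for fine-tuning, where NO-CALL exons
  outnumber events by orders of magnitude.

## Training

Two stages, both Adam with a cosine-annealed learning rate and all layers
trainable (no freezing):

1. **Pretraining** on windows labeled by a conventional caller run on
   high-coverage data (or by planted synthetic truth).
2. **Fine-tuning** on pairs of coverage-thinned windows and the
   *full-coverage* labels of the same exons. Labels are never recomputed
   on thinned data.

Full-scale defaults follow the regime the method was designed for
(initial learning rate 5e-5, one pretraining epoch over a large corpus,
three fine-tuning epochs); they are exposed in `TrainConfig`. The
desk-scale benchmarks in `exocnv.benchmark` use a smaller model
(window 128, 16→32 channels, one encoder block), a larger rate (1e-3)
and more epochs (25 pretrain / 12 fine-tune), because the toy corpus is
four orders of magnitude smaller than a real exome panel. These sizes are
the package's own benchmark design, chosen so a full cycle runs in about
a minute per seed on one CPU core.

Training is seed-deterministic on a single device: initialization, batch
shuffling, dropout masks and every synthetic draw flow from explicit
`numpy` Generators.

## Coverage thinning

Down-sampling a sample to a fraction p of its coverage is modeled as
per-base binomial thinning: each base's count c is replaced by
Binomial(c, p). This preserves the marginal depth distribution the model
consumes, composes correctly (thinning by p then q equals thinning by pq
in distribution), and is exact for the read-count statistics that matter
at exon scale. When a BAM is available, read-level subsampling is an
acceptable alternative backend; the depth-level route is the default
because the package also accepts plain depth tracks.

## Post-processing

Roughly 5% of exonic regions in degraded samples have no aligned reads;
the model cannot call them. Each such exon receives the majority label of
its three nearest *called* exons on the same chromosome (midpoint
distance; distance ties break toward the smaller start coordinate; fewer
than three candidates → vote over what exists; none → NO-CALL).
Cross-chromosome neighbors are never used. Imputation votes over hard
labels; probability averaging exists behind a flag.

Gene calls aggregate exon labels by majority vote. Two modes ship because
the natural-language rule is ambiguous for event-minority genes:
`all-class` (default) lets NO-CALL exons vote; `event-only` votes only
among DEL/DUP exons and calls a gene NO-CALL only when no exon carries an
event. Ties resolve to NO-CALL in both modes, and per-gene vote counts
are always reported so mixed DEL+DUP genes are measurable.

## Synthetic data generator

The generator emulates, at desk scale, the conditions the method is built
for: a multi-chromosome toy exome (non-overlapping exons laid down gene by
gene); exactly `n_del`/`n_dup` uniformly placed, non-overlapping events
(defaults keep the 10× base coverage and the 500 bp event floor of a
realistic simulation design, with the event-span ceiling reduced to
15 kbp so events fit a toy chromosome); per-base depth drawn negative
binomial with mean `coverage × copy factor` (0.5 / 1.0 / 1.5; dispersion
r = 10, i.e. variance μ + μ²/10 — moderate overdispersion) plus Poisson
contamination at 2% of base coverage, mimicking mismapped contaminant
reads that are independent of the host copy number; binomial coverage
ladders; and a 5% exon dropout reproducing depth-less regions.

What it deliberately does **not** model: read-level degradation
(fragment-length spectra, deamination), GC-bias curves, reference-genome
sequence context, and population linkage structure. The classifier
consumes depth only, so the generator is faithful at the depth level; a
passing benchmark therefore demonstrates that the architecture and
training strategy recover depth-encoded copy-number signal under
thinning, dropout and contamination noise — not that they overcome every
bias of real ancient libraries.

The frequency-structured cohort mode assigns each planted deletion a
population frequency and draws carrier samples per population, with all
events private to one of two populations. Two parameterizations are used:
a *structure* cohort with common variants (frequencies 0.25–0.8), the
regime in which population structure is identifiable from a few dozen
sites, and a *frequency* cohort in which 80% of events sit below 20%
frequency, emulating the rare-variant excess expected under negative
selection. Cohort call sets carry confident probabilities (0.99) so the
deletion-matrix filters behave as they would on confident real calls.

## Population-genetic statistics

The deletion matrix keeps entry (s, e) = 1 iff sample s calls DEL at exon
e with P(DEL) strictly above the probability threshold (default 0.9).
Sites are retained iff the cross-sample variance of the indicator is
strictly above the variance threshold. The variance convention is
divide-by-n (population variance), under which a binary site's variance
is capped at 0.25 — so the historical 0.25 default is attainable only in
the limit and desk-scale analyses pass 0.09 (the variance of a site at
10% or 90% carrier frequency); `ddof=1` selects the R-style sample
variance for which 0.25 is a meaningful cutoff.

PCA operates on centered, unit-variance-scaled columns (constant columns
dropped); component signs are fixed by making each loading's
largest-magnitude entry positive, so embeddings are reproducible. The
silhouette is computed on the first two components with Euclidean
distance (full-matrix Manhattan silhouette available via the `metric`
argument). Hierarchical clustering uses Manhattan distances with Ward-D2
linkage — `scipy`'s Ward update on an unsquared dissimilarity matrix,
verified in the tests against a brute-force Lance–Williams agglomeration —
and clustering accuracy is the best matching fraction over all
cluster-to-group assignments (Hungarian matching), evaluated at k = number
of true groups.

Consecutive DEL-labeled exons on one chromosome merge into segmental
deletions; by default any genomic gap between consecutive catalog exons is
bridged (`max_gap=inf`), since "segmental" has no canonical gap bound —
the parameter is exposed, and an autosome-only filter is available. The
site frequency spectrum histograms per-site carrier frequencies and
reports the fraction below a threshold (default 20%); the size spectrum
reports per-size-bin segment counts and the Spearman correlation between
bin midpoint and count, flagging (not zeroing) the degenerate
constant-count case.

## Numerical notes and limitations

- The network and its training run on a small reverse-mode autodiff
  engine written on `numpy` arrays (float64), with gradients verified
  against central finite differences for every layer. Single-threaded
  determinism is exact; bit-identity across BLAS implementations is not
  guaranteed.
- Softmax uses max-shifting; cross-entropy clamps probabilities at 1e-12.
- Checkpoints are single-file NPZ archives (config JSON + arrays) and
  round-trip bit-exactly.
- Batch normalization uses batch statistics in training and running
  statistics (momentum 0.1) at inference; inference is therefore
  batch-size independent.
- At 0.05×-equivalent coverage a ~100 bp exon holds ~5 reads; the
  information ceiling is low and fine-tuned macro-F1 around 0.3 on the
  desk-scale fixture should be read against that ceiling (a naive
  depth-threshold rule reaches ~0.27), not against the ~0.9 attainable
  at 1×.
- Diploid integer genotyping, breakpoint refinement, GC correction and
  duplicate marking are out of scope; inputs are trusted as aligned.
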