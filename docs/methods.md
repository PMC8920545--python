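# Methods

`osteoscreen` implements a screening pipeline for osteogenic-
differentiation-relevant genes in bulk expression time courses of bone
marrow mesenchymal stem cells (BMSCs): several public-style datasets
(batches), each containing uninduced controls (day 0) and osteogenically
induced samples at later stages, are merged, mined for differential and
network evidence, and distilled into a ranked list of novel candidate
regulators. Because the pipeline's value lies in *recovering* such a
regulator, the package ships a synthetic-data generator with a fully known
ground truth; every stage is validated against that truth or against an
independent brute-force oracle.

## Batch integration

Datasets measured on different platforms are merged by a parametric
empirical-Bayes location/scale adjustment. Per gene the data are
standardized under a linear model with batch indicators and the biological
group (control/induced) as a protected covariate; per-batch gene-wise
location effects (gamma) and scale effects (delta²) are estimated and
shrunk toward a normal and an inverse-gamma prior fitted across genes
(method-of-moments hyperpriors, iterative joint solver, convergence when
the largest parameter change falls below 1e-4 or after 100 iterations).

Shrinkage deliberately leaves a small residual offset per gene — the part
of the apparent batch effect the prior attributes to noise. Since the rest
of the pipeline treats the merged matrix as batch-free, the adjustment
finishes with exact equalization passes in the same standardized space:
remaining per-batch location offsets are removed outright and the scale
factors are divided by their sample-size-weighted cross-batch mean
(equalizing batch variances without touching a gene's overall scale),
iterated until the matrix changes by less than 1e-8. This makes the
operation a projection — adjusting an already-merged matrix is the
identity to numerical tolerance — which is the property the test suite
verifies. The group covariate can be disabled (`covariate=None`); with it
enabled, planted induction signal is preserved through merging (checked on
synthetic data).

Degenerate inputs are hard errors: a single batch, a batch with one
sample, or a zero-variance gene (named in the message).

## Differential expression

Per gene, a two-group linear model on the log2 matrix gives the log2 fold
change (difference of group means), the pooled residual variance s_g² with
d_g = n - 2 degrees of freedom. Gene-wise variances are moderated toward a
scaled inverse-chi-square prior (d0, s0²) fitted by moment matching on
log s_g² (digamma/trigamma moments; the trigamma inverse is solved by
Newton iteration). The moderated statistic

    t_g = logFC_g / (s~_g sqrt(1/n1 + 1/n2)),
    s~_g² = (d0 s0² + d_g s_g²) / (d0 + d_g)

is referred to t with d0 + d_g degrees of freedom. If the gene-wise
variances are *under*dispersed relative to a chi-square (the moment system
has no solution), the estimator falls back to full shrinkage (d0 = inf,
normal reference distribution) with a logged warning. With `shrink=False`
the statistic equals the classical pooled-variance two-sample t exactly,
which the tests assert at 1e-10.

DEG classification uses asymmetric gates: **up** if BH-adjusted p < 0.05
and logFC > 1; **down** if BH-adjusted p < 0.05 and logFC < -0.8. The
lenient downward gate reflects that strong silencing is rarer than strong
induction in osteogenic time courses; both gates are exposed as flags.
The high/low comparison after a median split uses BH < 0.05 with no
fold-change gate. Median-split ties go to "low" (deterministic, documented;
with continuous expression the strict-inequality rule keeps splits
balanced). Benjamini-Hochberg adjustment is the standard step-up procedure
with cumulative-minimum enforcement, validated against a brute-force
implementation of the definition on random p-vectors.

## Pathway activity (ssGSEA)

Per sample, genes are ranked by expression (average ranks on ties; the
highest-expressed gene has rank N). For a set with K members present, the
enrichment score is the *integrated* difference between the weighted
in-set CDF (gene weights rank^alpha, normalized to sum 1; alpha = 0.25)
and the unweighted out-of-set ECDF over the full ranked list — the
running-sum total, not its supremum. The score therefore depends on ranks
only and is invariant under monotone transforms of a sample's values.
Optionally (default) the score matrix is normalized by its overall
(max - min), keeping cross-sample comparability for clustering and
stage-median summaries. Sets with fewer than `min_overlap = 3` usable
members are dropped with a warning, as is a set covering every gene (its
out-of-set ECDF is undefined).

Note on calibration: with rank weighting (alpha > 0) the integrated score
of a *random* set is not mean-zero — the weights accelerate the in-set CDF
at the top of the list, producing a positive offset. The statistic is used
comparatively (across samples and stages), where the offset cancels; the
mean-zero symmetry property holds, and is tested, in the unweighted
alpha = 0 mode.

Stage summaries take the median score per (set, day), with controls
forming day 0.

## Association and networks

Gene-pathway association is the Pearson correlation between a DEG's
profile and a pathway's score vector, with a two-sided p from the exact t
transform r sqrt((n-2)/(1-r²)) and BH adjustment over the whole
gene x pathway table (the correction scope is a package choice; a raw-p
flag is provided). Constant vectors yield r = 0, p = 1 with a warning.

Co-expression networks are built separately for up- and down-regulated
genes (never mixed) from the gene-gene Pearson matrix at a sweep of
absolute-correlation thresholds (default 0.6, 0.7, 0.8, 0.9; edge sets are
nested by construction). Per network, hubs are the nodes with the top-k
largest degrees (k = 5 default, ties at the k-th degree included, isolated
nodes never hubs — the per-network hub rule and the consensus cutoff are
package choices exposed as flags, with per-threshold detail always
reported so any rule can be audited). A gene is a consensus hub when
flagged in at least half the networks. PPI evidence ranks degrees in the
interaction subgraph induced on the DEGs, top-k with tie inclusion
(k = 9 default).

## Enrichment

Over-representation uses the upper-tail hypergeometric probability
P(X >= k) for each term intersected with the universe, BH-adjusted across
terms; it is validated against exact integer-combinatorics enumeration on
all small universes.

Pre-ranked GSEA ranks all genes by the fold change between sample groups
and walks the list with the classic weighted Kolmogorov-Smirnov running
sum (hit increment |stat|^w / sum over the set with w = 1, miss decrement
1/(N-K)); the enrichment score is the signed maximum deviation. The null
is a *gene-label* permutation (random same-size sets; a pre-ranked list
precludes sample permutation), seeded and bit-reproducible, with
p = (1 + #{|ES_perm| >= |ES|}) / (nperm + 1). No normalized ES is
computed; the permutation p with BH adjustment across sets is the decision
statistic. Calibration (uniform p under a random ranking) is verified by a
Kolmogorov-Smirnov test in the acceptance suite.

## Candidate prioritization

Each DEG accumulates an evidence vector: DEG status, the fraction of
pathways with a significant positive association, the co-expression
consensus-hub flag and the PPI-hub flag, combined as

    score = w1 [DEG] + w2 (pos. assoc / n pathways) + w3 [co-exp hub] + w4 [PPI hub]

with default weights (1, 1, 1, 1). The integration is deliberately a
minimal determinized rule: the full evidence vector is always emitted so
users can re-rank by any policy. Genes that are members of the pathway
gene sets themselves, or that appear on the user-editable list of
previously studied osteogenesis genes, are moved to an excluded list with
the reason recorded — the novelty filter that leaves unstudied candidates.
Ties break by positive-association count, then gene symbol.

## qPCR arithmetic

Relative quantification uses 2^(-ddCt): dCt = Ct_target - Ct_reference per
well, ddCt = mean dCt(treated) - mean dCt(control). Group-mean ddCt is the
headline fold change; per-replicate folds (each treated well against the
control-group mean) with mean and SD are emitted for summary tables.
Swapping groups inverts the fold exactly; shifting all Ct values by a
constant leaves it unchanged.

## Synthetic data: what it emulates, and what it does not

The generator's defaults mirror the merged-compendium study design:
4 batches x stages day 0/1/3/7/14 x 4 samples (16 controls + 64 induced,
emulating a 14 + 63 cohort), 25 up- and 17 down-regulated genes, and 15
pathway modules of 20 genes tagged with the osteoblast category
composition (1 transcription factor / 9 differentiation / 1 development /
3 proliferation / 1 signaling).

* **Baselines and noise.** Gene baselines are U(6, 12) log2 units
  (up-DEG baselines U(6, 9), down-DEG baselines U(9, 12), so per-gene
  means stay within 5-13 after shifts); noise is Gaussian on the log2
  scale (microarray convention), sd 0.5, with per-DEG multipliers
  U(1.0, 1.6) so genes respond with heterogeneous fidelity.
* **Kinetics.** Planted DEGs shift by ±3 log2 units: half ("early
  response") reach the full shift at day 1 and hold; the rest ramp
  linearly to the final stage. The amplitude is strong-marker scale —
  ramping genes average roughly 0.45 of the final shift across the
  induced samples, and that average must clear the classification gates.
* **Pathway modules.** Each module has a latent activity per sample,
  zero in controls and (day/14)^0.3 plus N(0, 0.05) jitter in induced
  samples — a steep early rise that saturates, matching early-onset
  pathway engagement; the single development module decreases instead.
  Members add 0.8 x activity, deliberately below the DEG gates so module
  genes and planted DEGs remain distinct truth classes.
* **Regulator.** One up-DEG tracks its module's realized activity with
  reduced (0.3x) noise: it is genuinely correlated with pathway activity
  and, through that fidelity, the strongest co-expression hub. The PPI
  fixture wires the regulator to every other DEG (guaranteed maximal
  degree), makes DEG-DEG background edges dense among down-regulated
  genes (p = 0.4) and sparse elsewhere (p = 0.05) — real induction PPI
  hub sets split between up- and down-regulated genes — plus random
  background edges among non-DEG genes.
* **Batch effects.** Additive per-(batch, gene) shifts N(0, 0.8) and
  multiplicative inverse-gamma scale factors (shape 10, mean 1) applied to
  the noise after the biology, matching the location/scale model the
  merge step assumes.
* **Annotation fixture.** A term table with one planted
  "ossification-like" term (all true up-DEGs plus module genes; at least
  half the term is up-regulated truth) among >= 30 random background
  terms.

One seed drives everything through `numpy.random.SeedSequence`
sub-streams; a config plus seed fully determines every artifact.

What the generator does *not* emulate: count-based RNA-seq noise,
probe-level artifacts (probe collapse is tested on hand-built tables),
correlated gene-gene background structure beyond the planted modules,
missing values, platform-specific intensity saturation, or outlier
samples. Passing tests therefore demonstrate correctness of the
statistical machinery and recoverability of a planted signal under the
assumed noise model — not performance on any particular real dataset.

## Problem sizes in the test and acceptance runs

Unit tests run on reduced instances (200-500 genes, 2-3 samples per
batch/stage); the recovery and calibration checks use the full default
configuration (1,000 genes, 80 samples) across 20 seeds, 60 seeds for the
null error-rate check, and 200 replicates x 400 permutations for GSEA
calibration. These sizes give stable statistics while keeping the whole
suite fast.

## Known limitations

* The evidence-integration score is a package-defined determinization; no
  claim is made that its weights are optimal.
* The gene-permutation GSEA null ignores inter-gene correlation, as all
  pre-ranked GSEA nulls do; its p-values are calibrated for random
  rankings, not for correlated backgrounds.
* The exact-equalization finish of the batch adjustment assumes batches
  share the biology captured by the covariate model; unmodeled biological
  differences between batches would be removed with the batch effects.
* Only two-group contrasts are supported (no paired or multi-factor
  designs), and identifiers are plain case-sensitive symbols without an
  aliasing layer.
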