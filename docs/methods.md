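# Methods

This note documents the statistical models, defaults and design choices
behind `codonstats`, and what the synthetic study corpora do and do not
establish about real data.

## Codon counting and validation

Codons are read in frame 0 from the first base of each record; CDS are
assumed sense-strand, one per FASTA record. Codons containing any
non-ACGT character are skipped (never imputed) and tallied, so counts are
conservative and additive across records. Sequences whose length is not a
multiple of three are rejected by default (frame ambiguity corrupts every
downstream statistic); a `truncate` policy keeps them minus the trailing
bases. In-frame internal stop codons produce a warning but the sequence is
retained, since curated CDS collections do contain such records; a
`reject` policy is available. The default genetic code is the standard
(NCBI table 1) code, configurable via `GeneticCode.from_ncbi_id`; the
initiator ATG and the terminal stop are counted like any other frame-0
codon and drop out only at the RSCU/pair stage, where Met, Trp and stop
codons are excluded.

## RSCU vectors and species profiles

RSCU(c) = n_c k / n_a over each synonymous family; the 59 informative
codons are reported in a fixed canonical order (amino acids alphabetical
by three-letter name, codons alphabetical within family) so vectors and
matrix exports are reproducible. Two choices here were genuinely open:

* **Absent families** (common in short per-sequence vectors) are imputed
  at the neutral value 1.0 and flagged, so PCA and clustering see "no
  information" rather than extreme zeros. Vectors with more than 30% of
  their families imputed are excluded from classifier training by default
  — such vectors are mostly imputation, not signal.
* **Species-level "average RSCU"** is computed from pooled codon counts
  (count-weighted) rather than the unweighted mean of per-gene vectors;
  pooling is robust to very short genes. An `unweighted-mean` mode exists
  for sensitivity analysis; the two differ whenever gene lengths and
  compositions vary.

Hierarchical clustering of profiles defaults to Euclidean distance with
Ward linkage on raw (unscaled) RSCU values; metric and linkage are
configurable, and dendrograms export to Newick with GC/domain annotation
channels.

## Pair covariation

"Successive pairs" are successive occurrences of the same amino acid in
transcript order — other codons may intervene — matching the
autocorrelation phenomenon being measured; an `adjacent_only` mode
restricts to contiguous codons for sensitivity analysis. Pairs never span
sequence boundaries. Expected counts use corpus-level within-family codon
frequencies: expected = n_pairs · f(c1) · f(c2).

**Variance model.** The z statistic divides (observed − expected) by the
standard deviation under the independence model. The plain per-cell
binomial variance n p (1−p) ignores that consecutive pairs share an
occurrence: in an iid codon chain, neighbouring pair indicators covary by
δ₍c1=c2₎ f(c1)² f(c2) − p², and the number of such neighbour positions is
O = Σ_genes max(0, occurrences − 2). The implemented variance is

    var = n p (1−p) + 2 O (δ f³ − p²),

which agrees with a Monte-Carlo simulation of the independence null to
within estimation noise (< 0.015 z-units at 10⁵ replicates), whereas the
uncorrected binomial misstates z by up to ~0.4 on two-codon families.
`pair_zscores` without gene structure falls back to the plain binomial
form. Cells with zero variance (an unused or exclusive codon) are defined
as z = 0 and flagged degenerate.

**Choice of null.** `permutation_zscores` offers three nulls. The
`resample` scope (default) simulates the independence model itself — each
replicate redraws occurrences iid from corpus frequencies, gene sizes
preserved — and is the oracle used to validate the analytic z. The
`corpus` and `gene` shuffle scopes condition on (corpus- or gene-level)
codon composition; their null variance is 25–40% smaller than the
independence model's, so shuffle-based z values are systematically larger
in magnitude than analytic ones. This distinction matters: mechanisms
that plant covariation (stickiness, expression coupling) also skew
per-gene composition, which order shuffling cannot remove, so only the
composition-conditioned null is exactly centred on shuffled data.

Shading of pair tables follows the covariation convention: z > 3
"strong", 0 < z ≤ 3 "slight", z ≤ 0 "none". tRNA labels, when supplied,
are merged into exports as pass-through annotation only — no wobble-rule
computation is attempted.

**RSCPU** normalizes pair frequency by the product of individual codon
frequencies, making it independent of corpus size and GC content. Both
frequencies default to within-family normalization (pairs are defined
within synonymous families, so family normalization keeps numerator and
denominator on one scale); a `global` mode normalizes codon frequencies
over all sense codons instead. Pairs with zero expected frequency are
undefined: they are reported as missing in exports and imputed at the
neutral value 1.0 only for cross-species distance computation.

## Classification

Per-sequence RSCU matrices are reduced by mean-centred PCA. Component
signs are fixed (largest-magnitude loading positive) so scores are
reproducible. The Scree elbow is operationalized as the component
preceding the maximum second difference (acceleration) of the
explained-variance profile, minimum 1. Note a structural property of this
rule: whenever PC1 > 2·PC2 − PC3 — true of any corpus with a dominant GC
gradient — the acceleration is maximal at the second component and the
rule retains exactly 1 component. On GC-gradient corpora the domain
signal lives in the components after the GC axis, so the per-sequence
classification analyses in the acceptance tests retain 3 components
explicitly (the retention documented for this kind of per-sequence
analysis) rather than the Scree value; `fit_pca` accepts `k_retained` for
this purpose.

The classifier is an RBF-kernel SVM with class weights inversely
proportional to class frequency (imbalance is handled here, not by
stratified splitting). Hyperparameters are grid-searched over cost
{0.1, 1, 10, 100} and kernel width {0.001, 0.01, 0.1, 1} with an inner
3-fold CV; the selected model is validated by stratified 5-fold CV and
refit with probability estimates. Predictions take the probability argmax
with alphabetical tie-break. Evaluation reports one-vs-rest ROC/AUC per
class and accuracy in sequence-length bins (100–200, 200–500, 500–1000,
1000+ nt). The default 10% train / 90% test split follows the analysis
this package reimplements; the fraction is exposed because a 10% training
share is unusually small. Splits are at sequence level by default, with a
species-level mode for leakage-controlled evaluation.

## Optimality

Strata are the top and bottom abundance quintiles (n_bins = 5) — the
common "highly/lowly expressed" operationalization; genes are ranked by
abundance with ties broken by gene id, and bins are equal-size quantile
groups. Calls use binned RSCU, not the lowess smooth (the trend fit is
descriptive, for plots and exports), because binned values have exact
family-sum semantics and are directly testable. The neutrality band
δ = 0.1 around RSCU 1 defines "intermediate"; codons inside it, or moving
against the expression gradient, are not forced into either class.
Zero or missing abundances are excluded (log undefined) and counted. The
covariation–optimality overlap counts pairs with z ≥ 3 whose codons share
a class; pairs touching an intermediate codon are excluded from both
numerator and denominator by default and listed separately (an
`include` accounting keeps them in the denominator, since either
accounting of such pairs is defensible).

## Synthetic corpora

The generator emulates the statistical structure the analyses assume:

* **GC gradient**: per-species GC targets drawn from a range (default
  0.30–0.70) shared by all domains, so GC cannot separate domains. Family
  weights are exp-tilted by whole-codon GC with the tilt calibrated by
  root-finding so the expected corpus GC hits the target; with the fixed
  proteome-average amino-acid composition the reachable GC is roughly
  0.31–0.65, and targets outside saturate with a warning (best-effort).
  Within the feasible range achieved GC lands within ±0.05 of target.
* **Domain signatures**: arginine profiles per domain (Archaea AGA/AGG ≈
  0.75 of arginine mass, Bacteria CGC/CGT ≈ 0.72, Eukarya intermediate),
  exempt from the GC tilt so the signature survives the gradient, plus
  domain-consistent tilts (factors 1.5–1.8) on eight other families so
  the domain signal is not carried by a single amino acid. A small
  per-species log-normal weight jitter (σ = 0.08) gives every species an
  idiosyncratic, well-defined baseline preference per family.
* **Expression coupling**: per-gene abundance is log-normal (σ =
  `expression_spread`, default 1). The optimality mix m = clip(ln a /
  2σ, 0, 1) interpolates each planted family linearly (in log abundance)
  between the species baseline and a point mass on its optimal codon —
  the simplest mechanism that produces monotone RSCU–expression trends.
  Below-median genes are pure baseline, so low-stratum preferences equal
  baseline preferences. Optimal codons are drawn per species from the
  baseline distribution; arginine is exempt by default (its preferences
  stay constant across expression).
* **Stickiness**: with probability s an occurrence repeats the previous
  codon of the same amino acid, planting autocorrelation of tunable
  strength.

Ground truth (optimal sets, baseline preferences, switch sets,
stickiness) is recorded per species. Families whose top two baseline
probabilities differ by less than 0.02 (≈ 4 sampling sd of a quintile-bin
estimate at default sizes) have no identifiable preferred codon; they are
flagged and excluded from the switch truth. Regeneration from the same
spec and seed is byte-identical.

**What the generator does not emulate**: phylogenetic correlation among
species, amino-acid composition variation, gene-level selection strength
variation, indels/non-coding sequence, and real abundance distributions.
Passing recovery tests on these corpora shows the pipeline correctly
measures the structures it targets at realistic noise levels; it does not
by itself establish the classification accuracies or covariation–
optimality overlaps attainable on real multi-species CDS collections,
which depend on corpus scale and biology outside the model.

## Problem sizes

The default validation corpora are sized for quick, fully reproducible
runs: 10 species × 100 genes per domain (3,000 sequences) for domain
recovery; 1,000 genes per species for optimality recovery; 500 genes for
the RSCPU null; 30 genes for the 10⁵-replicate Monte-Carlo oracle. Genes
are 300–1,500 nt. These sizes put every recovery target several sampling
standard deviations from its threshold while keeping the whole suite in
the minutes range.

## Known limitations

* Cross-amino-acid codon pairs are out of scope; covariation and RSCPU
  are defined within synonymous families only.
* The Scree acceleration rule is unreliable in the presence of one
  dominant component (see above); users analysing GC-spread corpora
  should set `k_retained` deliberately.
* SVM probability estimates use the underlying library's internal
  calibration; any monotone score would serve for ROC, but probabilities
  across classes should not be over-interpreted.
* `filter_species` uses a strict > threshold (a species with exactly
  1,000 genes is removed at min_genes = 1000), mirroring the filtering
  convention of the analysis this package reimplements.
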