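# Methods

This note documents the models implemented in `methylssl`, the choices
made where the design was genuinely open, and what the packaged synthetic
experiments do and do not demonstrate about real methylation data.

## Setting

The input is a beta-value matrix: per sample and CpG probe, the fraction
of methylated signal, bounded in [0, 1] and typically bimodal (probes sit
near fully unmethylated ~0.1 or fully methylated ~0.9). Labels come at
two nested levels — a methylation subclass (MC) nested inside a coarser
methylation class family (MCF) — and are severely imbalanced: some tumor
classes hold fewer than 10 reference samples. The semi-supervised problem
is transductive (label the unlabeled pool seen during training) and
inductive (label held-out samples).

## Preprocessing

Probes are removed on any of four standard annotation flags (sex
chromosomes, common SNP within 5 bp of the CpG, multi-mapping on hg19,
cross-reactive); the reading is disjunctive. Features are then selected
unsupervised: probes whose sample standard deviation (n−1 denominator)
across the *entire* cohort strictly exceeds a cutoff. The default cutoff
is 0.3, appropriate for genome-wide 450K cohorts. Computing the SD on all
samples before any split deliberately reproduces the reference design; it
leaks unlabeled-data variance into feature selection, which is part of
the transductive protocol rather than an oversight.

On the synthetic desk-scale cohorts the same statistic needs a different
cutoff: with a few hundred samples and ~10 classes, an informative
probe's between-class SD is ≈0.2–0.35 while the beta-noise floor of
uninformative probes is ≈0.07–0.17 (it scales as
√(m(1−m)/(1+concentration))). Desk pipelines therefore select at 0.2 —
above the noise floor, below the informative spread. A further property
matters for rare classes: a probe informative for a class holding ~1% of
samples has between-class variance below the noise floor, so *any* SD
cutoff that rejects noise also rejects rare-class-specific probes. The
augmentation experiment (below) consequently runs on the full probe set;
on real cohorts this bias is mitigated by the much larger class count.

## Base learners

* **1-NN** (Euclidean). Per-class confidence is distance-softened:
  score_c ∝ 1/(1 + d_c) with d_c the distance to the nearest training
  point of class c; the argmax equals the 1-NN label.
* **Decision tree**: an entropy-criterion (information-gain) tree with
  leaf class proportions as confidences. It stands in for C5.0, whose
  exact internals are proprietary; no boosting or winnowing.
* **RBF-SVM**: soft-margin C-classification, C = 1,
  γ = 1/n_features. Confidences are a softmax over the
  one-vs-rest–aggregated pairwise decision values. Platt-style
  probability estimates were rejected deliberately: their internal
  cross-validation is undefined for classes with fewer than ~5 samples —
  routine here — and their argmax can contradict the SVM's own label
  prediction, which destabilizes self-training. The softmax-of-decision
  values construction is deterministic and always argmax-consistent with
  `predict`.

All learners expose per-class scores in [0, 1] summing to 1; ties in any
argmax break toward the smallest class index.

## The five self-labeled schemes

**SELFT** iterates: fit the learner on the labeled pool, score the
unlabeled pool, and move the most confident predictions into the labeled
pool, with per-iteration per-class quotas proportional to the original
labeled class distribution (largest-remainder rounding, minimum 1 per
class so rare classes are never frozen out). It stops after `max_iter`
(50) iterations or once `perc_full` (0.7) of the unlabeled pool is
consumed.

**SETRED** is SELFT plus data editing. Each candidate batch is screened
on the relative neighborhood graph (RNG) built over the current labeled
pool plus the candidates; edge weights are w = 1/(1+d), bounded in
(0, 1]. For a candidate with assigned label y, the observed cut-edge
weight J sums the weights of incident edges whose far endpoint carries a
different label. Under the null that neighbor labels are i.i.d. draws
with the labeled-pool frequency p_y,

    μ₀ = (1 − p_y) Σ w_e,   σ₀² = p_y (1 − p_y) Σ w_e².

A correctly labeled point should have *fewer* cut edges than chance, so
the candidate is accepted only when (J − μ₀)/σ₀ ≤ Φ⁻¹(θ), i.e. J below
the quantile with upper tail mass 1−θ; θ defaults to 0.1. θ = 1 pushes
the critical value to +∞ and reduces SETRED exactly to SELFT. Isolated
candidates (no incident edge) are accepted unedited: the statistic is
undefined there, and rejecting would starve rare classes. This left-tail
acceptance matters in the multiclass regime: with K classes the priors
p_y are small, μ₀ sits close to the all-cut value, and an upper-tail test
has almost no power, while the left-tail form rejects essentially all
mislabeled candidates (measured rejection ≈ 1.0 on noisy vs ≈ 0.1 on
clean candidates under 20% injected noise).

**SNNRCE** (fixed 1-NN learner) runs three phases on the RNG over all
points: (1) unlabeled vertices whose *entire* neighborhood is labeled and
unanimous take that label — requiring the whole neighborhood labeled,
not just the labeled part of it, prevents single cross-cluster edges
from planting wrong labels; (2) plain 1-NN self-training consumes the
remainder; (3) initially-unlabeled vertices whose cut-edge z-score
exceeds Φ⁻¹(1−α) (α = 0.1) are relabeled to their neighborhood majority.
At α = 1 every vertex with a cut edge is relabeled to its neighborhood
majority, the documented degenerate case.

**TRITRAIN** trains three copies of the base learner on independent
bootstrap resamples (each bootstrap is patched to retain at least one
sample of every class). Per round, learner i may retrain on the unlabeled
points its two peers agree on, but only while the peers' joint error e_i
keeps the product e_i·|L_i| below its previous value, subsampling L_i
when necessary — the standard stability condition. The final label is
the majority vote; scores average the three confidence rows.

**DEMO** (democratic co-learning) fits the three heterogeneous learners
jointly. Per round each unlabeled point receives a confidence-weighted
majority label (weights are the midpoints of 95% normal-approximation
confidence intervals on labeled-set accuracy); a dissenting learner
adopts the point only when the agreeing group's summed CI lower bounds
exceed the dissenters'. Training sets are recomputed each round and the
loop stops when they stabilize. The final vote weighs learners by mean CI
accuracy and excludes any learner whose lower bound is ≤ 0.5.

Every scheme is deterministic given its seed: bootstraps, candidate
ordering, and tie-breaks all flow from one generator.

## Calibration and thresholding

Raw per-class SSL scores are not comparable across classes. They are
mapped to probabilities by multinomial logistic regression with an L2
penalty on standardized score features (intercepts unpenalized): minimize
(1/n)·NLL + (λ/2)·‖W‖². λ is selected from a log-spaced grid of 100
values spanning [10⁻⁴·λ_max, λ_max] (λ_max from the max absolute score
gradient) by mean deviance over 10-fold cross-validation; folds are
stratified by class — unstratified folds would drop rare classes
entirely — and seeded. A class absent from the calibration response
keeps probability exactly 0, with a warning. The calibration response is
the *true* label of the transductive pool; using the SSL pseudo-labels
instead is a documented alternative the implementation does not take.

For a single confidence threshold shared by all classes, the multiclass
problem is binarized: a sample is *classifiable* when the argmax
calibrated class equals its true class, and its score is the row-maximal
calibrated probability. ROC analysis over all distinct scores (predict
positive iff score ≥ τ) yields AUC via the Mann–Whitney pair count (ties
½) and the Youden-optimal τ maximizing sensitivity + specificity − 1
(smallest τ on ties). Samples with maximal calibrated probability ≥ τ
(default 0.8, boundary inclusive) are high-confidence (HC), the rest
low-confidence (LC). If every sample is classifiable the ROC is
degenerate; the report then carries AUC 1 and a flag rather than an
error.

## Partitions, metrics, benchmark

Each bootstrap draws, stratified per class with largest-remainder
rounding: 30% into the inductive test set, then half of the remainder
into the labeled pool (minimum one labeled sample per class) and half
into the unlabeled/transductive pool. Metrics are one-vs-all: per-class
recall, precision (classes never predicted are excluded from the macro
mean), specificity; balanced accuracy is the unweighted mean of per-class
recall and is the model-selection criterion, since plain accuracy
rewards majority-class behavior under imbalance. MCF-level results come
from refitting on family labels, not collapsing MC predictions.

## Augmentation experiment

The packaged experiment draws a reference cohort and an external cohort
as two same-structure sample sets from one generator call (the external
set plays the prospective-cohort role, so it must share archetypes and
informative-probe structure with the reference — new samples, same
classes). The reference cohort is split 30% hold-out population / 35%
labeled / 35% unlabeled; SETRED-SVM is fit on the labeled+unlabeled
pools, its transductive scores are calibrated, tiers are assigned at
τ = 0.8, and the external cohort is pseudo-labeled inductively with the
same calibration. Four training variants — BASELINE (seed labels only),
PLUS_HC, PLUS_LC, PLUS_ALL — are evaluated by a 500-tree random forest
and a dense net (He-uniform init, ReLU, softmax, Adam 10⁻³, batch 6, 20
epochs; hidden sizes 1000→500 in full-replication mode, 64→32 at desk
scale), both with balanced sample weights w_c = n/(K·n_c). Metrics: 5×
stratified 3-fold CV (balanced accuracy and weighted recall) and seven
stratified 70–30 hold-out resamples of the seed-labeled population only —
pseudo-labeled samples never enter a hold-out set, asserted on every
resample. The seven hold-out balanced accuracies are compared across
variants with Tukey HSD at α = 0.05. The NN is implemented directly in
numpy so that sample weights enter the loss and training is
bit-reproducible single-threaded.

Desk-scale cohort: 12 common classes of 45 samples in four
three-subclass families plus three rare classes (8, 7, 6 samples) that
form their own singleton families, 1,000 probes, 16 informative probes
per subclass with 70% family sharing, beta concentration 8. Rare tumor
entities are typically molecularly distinct rather than minor variants
of a common type, hence the singleton families; embedding a 7-sample
class inside a 45-sample sibling's family makes its pseudo-labels
systematically collapse onto the sibling — a real failure mode of
pseudo-labeling rare classes, observable with the generator, but one
that would make the experiment measure only that collapse.

## What the synthetic experiments show — and what they do not

The generator produces unimodal beta-distributed blobs around class
archetypes with independent probes. Real methylation classes have
correlated probes, batch and purity effects, multimodal substructure and
out-of-distribution samples; none of that is modeled. Consequently:

* On these cohorts the eleven SSL models recover a high-separation
  cohort perfectly, SETRED-SVM at 20% labeling matches or beats a
  supervised SVM on the labeled subset, and calibration lifts the
  classifiable-vs-non-classifiable AUC (typically ~0.8 → 1.0 at desk
  scale). These are directional checks of the machinery, not estimates
  of real-data accuracy.
* The downstream classifiers saturate: a random forest with ~25 seed
  samples per common class is already at balanced accuracy 1.0, so the
  augmentation experiment demonstrates *no degradation* from HC
  pseudo-labels (and PLUS_ALL ≥ PLUS_LC), not the absolute gain
  achievable when the baseline is label-starved across ~90 classes. The
  NN, more sensitive to label noise, does show reduced hold-out accuracy
  when low-confidence labels are added — the qualitative pattern the
  tier split is designed to prevent.

## Numerical conventions and degenerate inputs

* Beta values clipped to [10⁻⁶, 1−10⁻⁶]; concentration = ∞ is the exact
  noiseless limit.
* Duplicate points are always RNG-connected (zero distance cannot be
  blocked); the blocking test uses a strict inequality.
* σ₀ = 0 (prior 0 or 1) maps the z-score to ±∞ by the sign of J − μ₀.
* All argmax ties break toward the smallest class index and are logged.
* Tukey HSD on groups with zero spread yields an undefined studentized
  range; the acceptance script reports p = 1 there (no evidence of a
  difference).
* Stratified fold counts are reduced (with a warning) when the smallest
  class cannot populate every fold.

## Problem sizes

Packaged study sizes were chosen so the full suite and the acceptance
script each run in minutes on a single CPU: noiseless recovery uses 240
samples × 2,000 probes × 3 bootstraps × 11 models × 2 label levels;
editing power and the gain comparisons use 120–180-sample cohorts over 5
seeds; the augmentation experiment uses 561 reference + 561 external
samples. The same code paths accept full-size cohorts unchanged.
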