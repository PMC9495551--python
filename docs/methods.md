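# Methods

## Overview

`cernamod` identifies per-miRNA regulatory modules from paired tumor/normal
expression data in five stages: stability-selected differential expression,
confidence- and co-expression-filtered interaction networking with Maximal
Clique Centrality, neural tumor/normal classification with additive feature
attribution, sign-constrained ceRNA triplet screening over validated target
pairs, and direction-consistent module grouping. This note records the
models, the parameters that matter, and the design choices made where the
design was genuinely open.

## Differential expression

Counts are assumed to be non-negative integers over matched case/control
pairs. Between-sample normalization is the trimmed mean of M-values: the
reference library is the one whose 0.75 quantile of count rates (counts /
library size) is closest to the mean of those quantiles; per-feature
log-ratios `M = log2((x/N)/(x_ref/N_ref))` are trimmed 30% on each side by
`M` and 5% by average abundance `A`, and averaged with
inverse-asymptotic-variance weights (`weighted=False` disables the weights;
only then are factors exactly invariant to rescaling a single library,
because the weights depend on absolute depth). Factors are rescaled to
geometric mean 1. The implementation reproduces edgeR's `calcNormFactors`
to ~1e-10 on a fixed test matrix.

Normalized abundance is `log2(CPM + 0.5)` on effective library sizes
(library size × TMM factor). Putting the half-count pseudocount on the CPM
scale keeps zeros finite and makes the values exactly invariant to global
count scaling.

The per-feature statistic is a paired Wilcoxon signed-rank test on per-pair
log-CPM differences (zero differences split, normal approximation with
continuity correction). This is a deliberate choice of a distribution-free
test over a negative-binomial exact test: the downstream pipeline consumes
only (log2FC, p, FDR), the effect estimate is the mean paired log-CPM
difference, and at the intended scale (≥ 80 pairs) the signed-rank test has
essentially full power at |log2FC| = 2. The statistic is pluggable — any
engine mapping a feature × pair difference matrix to p-values can be
substituted. Significance requires |log2FC| > 1 (strict) and
Benjamini–Hochberg FDR < 0.05 (statsmodels' step-up, validated against the
brute-force definition).

Stability selection re-runs the full test (including TMM renormalization) on
⌈0.8 · n_pairs⌉ pairs drawn without replacement, 50 times, and keeps the
intersection of the per-round significant sets. The subsampling unit is the
*pair* — both members always travel together, keeping the paired test valid.
The fold-change/FDR gate is applied within each round before intersecting.
Child round seeds are spawned from one master seed. miRNA, being a small
sparse class, is tested in a single pass.

A quality-control helper drops features with more than 1/3 of samples
missing (RNA-seq) or more than 2 missing (miRNA); "missing" means NA in the
input, never zero.

## Interaction network and centrality

Edges enter the mRNA graph when the protein-level confidence score is
strictly greater than 700 (STRING convention, 0–1000) and the transcripts
are significantly co-expressed (two-sided Pearson p < 0.05 with n−2 df
t-distribution p-values) on normalized log abundance over all samples,
tumor and normal pooled. Duplicate rows and self-loops collapse; endpoints
absent from the expression matrix are dropped and logged; zero-variance
profiles are flagged non-significant (r undefined, p = 1).

Maximal cliques are enumerated with Bron–Kerbosch with pivoting (validated
against both exhaustive subset enumeration and networkx on all test
graphs); a guard refuses graphs over 5000 nodes unless overridden, since
enumeration is worst-case exponential. Maximal Clique Centrality is
`MCC(v) = Σ (|C|−1)!` over maximal cliques `C ∋ v` with `|C| ≥ 2`. The
size-≥2 restriction makes isolated nodes score 0 rather than the 0! = 1 a
literal reading would give; a node lying only in 2-cliques scores its
degree with no special case.

## Classifier

The tumor/normal classifier is a fully connected network — hidden layers of
400 and 100 units for the mRNA model, 400/100/40 for the ceRNA model — with
ReLU activations, a per-feature normalization (batch norm, ε = 10⁻³,
running-stat momentum 0.99) after each hidden layer of the mRNA model, and a
single sigmoid output. Training uses Adam (β₁ = 0.9, β₂ = 0.999, ε = 10⁻⁷),
learning rate 10⁻⁴, batch size 16, binary cross-entropy, on a stratified
70/30 train/validation split; the split/batch randomness derives from
(seed, repeat) so any repeat is reproducible and the protocol can be
repeated (default 50×) to gauge split sensitivity. The default epoch count
is 200 — on the synthetic data the loss plateaus well before that — with the
full ≥1000-epoch regime available by configuration. The implementation is
plain numpy, bit-deterministic under a fixed seed on one thread, and exposes
its layer structure to the attribution engine. Features are log2(abundance
+ 1); an L2 weight penalty is available as an alternative regularizer.
ReLU was chosen as the hidden nonlinearity (the standard default for
fully-connected classifiers); weight init is He-normal.

ROC/AUC uses scikit-learn's `roc_curve` (trapezoid AUC, verified equal to
pairwise Mann–Whitney concordance), and six classical baselines (KNN, SVC,
decision tree, Gaussian naive Bayes, logistic regression, random forest)
run with library defaults under the same split protocol.

## Attribution

Per-sample additive attributions are computed against a reference
("background") set — by default up to 100 training-set rows drawn with a
fixed seed. Two methods:

* **rescale** (default): backpropagates finite-difference multipliers per
  (sample, reference) pair — a nonlinearity contributes Δout/Δin between
  sample and reference (its derivative where |Δin| < 10⁻⁹), affine layers
  contribute their weights, inference-mode batch norm is a per-unit affine
  map. Attributions `φᵢ = mᵢ(xᵢ − bᵢ)` sum *exactly* to f(x) − f(b) per
  reference, hence to f(x) minus the mean reference output after averaging.
  The method is exact for (log-)linear models but only approximates Shapley
  values under feature interactions — on small trained networks we observe
  per-feature deviations of tens of percent from exact Shapley, which is
  inherent to single-pass backpropagation attribution, not an
  implementation artifact.
* **permutation**: a Monte Carlo Shapley estimator — marginal contributions
  averaged over random feature orderings, references cycled across
  permutations. Also exactly locally accurate (telescoping), and converges
  to the Shapley values; 3000 permutations bring an 8-feature network
  within a few percent of exact coalition enumeration. Cost is
  n_permutations × n_features forward passes.

The published-workflow summary score ("SHAP value") is the arithmetic mean
over samples of the absolute per-sample attribution, computed on the
probability (post-sigmoid) scale. An exact Shapley oracle by coalition
enumeration (≤ 12 features, absent features imputed by background means)
exists for testing only. Pruning removes features whose summary score is
exactly zero after rounding at 10⁻¹²: the intent is removing features the
model never uses, not small-contribution features.

## Triplet screening and modules

Candidate mRNAs satisfy MCC > 8 and contribution > 10⁻⁴, both strict.
Triplets are enumerated from the validated target tables only — a pair
absent from the tables is never considered, however correlated — with
miRNAs/lncRNAs restricted to significant (stable) DE features and mRNAs to
candidates. The ceRNA gate requires r(miR, mRNA) < 0, r(miR, lncRNA) < 0,
r(mRNA, lncRNA) > 0, each with two-sided p < 0.05 and the sign checked
separately.

Screening correlations are computed on *condition-centered* abundance: the
pipeline subtracts per-condition means before correlating. Across pooled
tumor+normal samples, any two differential features whose directions align
correlate through the shared disease shift alone, so a pooled screen would
accept every direction-aligned validated pair regardless of co-regulation;
centering demands covariation beyond the group difference. (Edge
co-expression filtering stays pooled — there the group shift is part of the
biology being captured.) Passing `samples=None` reproduces the pooled
behavior.

The ceRNA network joins triplet pairings with interaction edges among
included mRNAs; the potential-ceRNA subnetwork keeps nodes whose
ceRNA-model contribution exceeds 10⁻⁴ and drops isolates. Modules group
each miRNA's validated-target neighbors by DE direction: one module per
(miRNA, direction) group containing at least one mRNA; when both directions
qualify, both are emitted and the larger is marked primary (the grouping
rule itself gives no reason to discard the minority group). The miRNA's own
direction is not constrained relative to its members — biologically the
miRNA typically moves opposite to the targets it represses, and the
generator plants it that way, but the extraction rule does not require it.
Modules without a lncRNA are allowed but logged. Modules are ordered by the
miRNA's contribution, descending.

## Synthetic data

The generator emulates the statistical shape the pipeline assumes. Counts
are negative binomial (dispersion 0.1) around per-feature baseline means
drawn log-uniformly from 20–500, with feature lengths 0.5–5 kb and
lognormal library-size variation (σ = 0.3, ~±30%) — mRNA and lncRNA share
one sequencing library per sample, miRNA has its own. Abundance is
FPKM-like: counts per million library counts per kb. Defaults: 100
tumor/normal pairs; 1200 mRNAs, 400 lncRNAs, 150 miRNAs; 60 planted DE
features per class at |log2FC| = 2 (case mean = control mean × 2^±2,
half-shift applied symmetrically to both groups); 50 planted triplets at
strength 0.7.

Planted ceRNA structure: each planted miRNA carries one standard-normal
per-sample latent factor, loading negatively on the miRNA and positively on
its partner mRNAs (5 per miRNA) and its single partner lncRNA; partners
share one DE direction, opposite the miRNA's. The loading is
`s·√(ρ/(1−ρ))` with `s` the delta-method log2-scale residual SD at the
feature's baseline mean, targeting within-condition correlation ρ =
`triplet_strength`. One lncRNA per miRNA mirrors the one-sponge structure
of reported modules and makes the planted triplet list exactly the induced
(mRNA × lncRNA) cross product — with several lncRNAs per factor, the extra
genuinely-coupled combinations would be mislabeled false positives. A
correlation of 0.7 with five mutually-coupled partners is also near the
ceiling a single shared factor permits.

The planted interaction graph partitions same-direction DE mRNAs into
cliques of ≥5 (short remainders merge into the previous clique, so every
planted hub clears MCC = 4! = 24 > 8) with confidence scores drawn 701–999;
background edges arrive with probability 0.002 and confidence 150–999.
Target tables contain the planted pairs plus, per DE miRNA, 10 decoy
targets drawn uniformly over *all* features of the class — target databases
are DE-agnostic, and this is what makes screen precision a meaningful
quantity.

What the generator does **not** emulate: sequencing reads, isoform
structure, batch effects, covariates (stage, race), miRNA-specific
RPM→RPKM conversion, zero inflation, or realistic correlation among
non-planted features. Passing tests therefore demonstrate correctness of
the machinery and recoverability of planted structure under clean
conditions — they do not certify performance on real tissue data, where
effect sizes, library artifacts and confounding are all less favorable.

## Numerical choices and degenerate inputs

* Wilcoxon on an all-zero difference row returns p = 1 (constant feature).
* Zero-variance vectors in any correlation return (r = NaN, p = 1).
* BH adjustment validates p ∈ [0, 1] and clips at 1.
* All-zero libraries, single-class labels, empty backgrounds, feature
  mismatches, and subsamples of fewer than 3 pairs raise errors naming the
  offending input; empty candidate sets, empty target tables, and empty
  subnetworks warn and return empty results.
* Attribution ratio fallback threshold 10⁻⁹; pruning zero-threshold 10⁻¹²;
  BCE clipping 10⁻⁷.
* Pipeline stage seeds are spawned from the one config seed via
  `SeedSequence`; reruns of the same config write byte-identical artifacts
  (single-threaded).

## Problem sizes

The default simulated study (100 pairs; 1200/400/150 features; 50 rounds of
stability selection; 200 training epochs) runs the full pipeline in well
under a minute on one CPU, and the complete test suite — including oracle
comparisons and two full pipeline executions — in a few minutes. These
sizes were chosen so planted effects sit in the high-power regime the
published workflow operates in, while keeping iteration fast.

## Known limitations

* The per-feature DE statistic is rank-based, not a count model; with few
  pairs (< 10) it is conservative, and no dispersion shrinkage is done.
* Rescale attributions are not Shapley values under interactions (see
  above); use `method="permutation"` when fidelity to Shapley matters.
* Clique enumeration does not scale to dense graphs with tens of thousands
  of nodes; MCC is intended for filtered networks of moderate size.
* Screening treats the validated target tables as ground truth; errors in
  them propagate directly.
* The potential-ceRNA contribution threshold (10⁻⁴) is an absolute number
  on the probability-output scale and inherits that scale's arbitrariness;
  it is configurable.
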