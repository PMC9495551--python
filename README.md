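# cernamod

Discovery of miRNA–lncRNA–mRNA regulatory modules from paired tumor/normal
expression data.

Competing endogenous RNAs (ceRNAs) are transcripts — protein-coding mRNAs and
long non-coding RNAs — that regulate each other indirectly by competing for a
shared pool of microRNA binding. A lncRNA acting as a miRNA "sponge"
de-represses that miRNA's mRNA targets, so a functioning ceRNA axis leaves a
characteristic correlation signature in expression data: the miRNA is
negatively correlated with both the mRNA and the lncRNA, while mRNA and
lncRNA are positively correlated with each other. `cernamod` implements a
complete pipeline that finds such axes in a paired case/control RNA-seq +
miRNA-seq study and groups them into per-miRNA regulatory modules. It is
aimed at computational biologists who want the full workflow — or any of its
stages — as reusable, tested library code, exercised end-to-end on synthetic
data with planted ground truth.

## The method

Given count and abundance matrices for three RNA classes over matched
tumor/normal pairs, a protein-level interaction edge list with confidence
scores, and validated miRNA→target tables, the pipeline runs:

1. **Differential expression with stability selection.** Counts are
   normalized by the trimmed mean of M-values (TMM; 30% two-sided trim on
   log-ratios *M*, 5% on average abundance *A*, precision-weighted, factors
   rescaled to geometric mean 1). Per feature, the paired statistic is a
   Wilcoxon signed-rank test on per-pair differences of log₂CPM, with
   Benjamini–Hochberg FDR control and the joint gate |log₂FC| > 1 ∧
   FDR < 0.05. For the large classes (mRNA, lncRNA) the call set is the
   intersection over 50 rounds of re-testing on random 4/5 subsamples of the
   pairs; miRNA is called in a single pass.
2. **Interaction network.** Edges are kept when confidence > 700 (STRING
   score convention) *and* the endpoints are significantly co-expressed
   (Pearson p < 0.05); nodes are restricted to stable DE mRNAs. Hubness is
   scored by Maximal Clique Centrality,
   MCC(v) = Σ_{C ∋ v} (|C| − 1)! over maximal cliques C (Bron–Kerbosch
   enumeration with pivoting).
3. **Classifier and attribution.** A fully connected network (hidden layers
   400/100, batch normalization, ReLU, sigmoid output; Adam, learning rate
   10⁻⁴, batch 16, binary cross-entropy, stratified 70/30 split) is trained
   to separate tumor from normal on the network mRNAs. Per-feature SHAP-style
   contributions are the mean over samples of |additive attribution|
   (rescale-rule backpropagation; a Monte Carlo Shapley estimator is also
   provided). Zero-contribution features are pruned and the model relearned.
4. **Candidate and triplet screening.** Candidate mRNAs satisfy MCC > 8 and
   contribution > 10⁻⁴. All validated (miRNA, mRNA) × (miRNA, lncRNA) pairs
   over DE miRNAs/lncRNAs and candidate mRNAs are assembled into triplets and
   kept when r(miR, mRNA) < 0, r(miR, lncRNA) < 0, r(mRNA, lncRNA) > 0, all
   at p < 0.05 (computed on condition-centered abundance).
5. **Modules.** A second classifier over all ceRNA-network nodes (hidden
   layers 400/100/40) yields contributions; nodes above 10⁻⁴ form the
   potential-ceRNA subnetwork, and each miRNA's validated targets are grouped
   by shared up/down regulation direction into regulatory modules.

The synthetic-data generator plants every structure the pipeline looks for —
negative-binomial counts with lognormal baselines and library sizes, DE
features at |log₂FC| = 2, interaction cliques, and latent-factor-driven
ceRNA triplets at correlation strength 0.7 — so each stage can be scored
against known truth.

## Worked example

```python
from cernamod import (
    PipelineConfig, SimulationConfig, generate_dataset, run_pipeline,
    score_modules, score_triplets,
)

dataset, truth = generate_dataset(SimulationConfig(seed=42))
result = run_pipeline(dataset, PipelineConfig(seed=42, epochs=200))

m = result.manifest
print(f"stable DE features: {m['n_stable_de_mrna']} mRNA, "
      f"{m['n_stable_de_lncrna']} lncRNA, {m['n_stable_de_mirna']} miRNA")
print(f"interaction network: {m['n_network_nodes']} nodes, {m['n_network_edges']} edges")
print(f"candidate mRNAs (MCC > 8, SHAP > 1e-4): {m['n_candidate_mrnas']}")
print(f"screened ceRNA triplets: {m['n_triplets']}")
print(f"potential ceRNAs: {m['n_potential_cernas']}; modules: {m['n_modules']}")
trip = score_triplets(result.triplets, truth)
mods = score_modules(result.modules, truth)
print(f"planted-triplet recall {trip['recall']:.2f}, precision {trip['precision']:.2f}")
top = result.modules[0]
print(f"top module: {top.mirna_id} ({top.direction}-regulated members), "
      f"{len(top.mrna_ids)} mRNAs + {len(top.lncrna_ids)} lncRNA")
```

prints

```
stable DE features: 60 mRNA, 60 lncRNA, 60 miRNA
interaction network: 60 nodes, 141 edges
candidate mRNAs (MCC > 8, SHAP > 1e-4): 60
screened ceRNA triplets: 50
potential ceRNAs: 70; modules: 10
planted-triplet recall 1.00, precision 1.00
top module: MIR00099 (down-regulated members), 5 mRNAs + 1 lncRNA
```

All 60 planted DE features per class are recovered as stable; the planted
interaction cliques survive both edge filters (141 retained edges vs 139
planted, the surplus being confidence-passing background edges between
co-regulated DE mRNAs);
the 50 planted triplets are screened with neither false negatives nor false
positives at this seed; and the ten planted miRNA modules are reconstructed
exactly, each with its mRNAs and single sponge lncRNA. The classifiers
separate tumor from normal perfectly on this cleanly separable synthetic
signal — real tissue data is noisier on every one of these axes.

A command-line interface mirrors the library
(`cernamod simulate|de|network|run|evaluate …`; `cernamod --help`).

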