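# retarget

Gene prioritization and network-proximity drug repositioning for
two-group transcriptomic studies (built around the lung-adenocarcinoma
use case: tumor vs normal FPKM, a weighted gene–gene interaction
network, functional-annotation features, and drug→target-gene sets).

**Who it is for**: computational biologists who have a case/control
expression matrix and want to (1) partition genes into
disease-associated ("positive"), unrelated ("negative") and ambiguous
sets by differential expression, (2) score the ambiguous genes with a
graph attention network (GAT) that combines annotation features with
interaction-network topology, and (3) rank candidate drugs by how close
their target networks sit to the disease network.

## The models

**Labeling.** Fold change is the ratio of raw group means; significance
is a limma-style moderated t-test on log2(FPKM + 1) with
empirical-Bayes variance shrinkage and Benjamini–Hochberg FDR. Genes
with FDR ≥ 0.05 are excluded; log2FC > 2 / < −2 are positives,
−0.3 < log2FC < 0.3 negatives, the rest ambiguous.

**Classifier.** A two-layer multi-head GAT over the interaction graph:
per head, message logits e_ij = LeakyReLU(a_srcᵀWh_j + a_dstᵀWh_i) +
log w_ij are softmax-normalized over the neighbourhood (self-loops
included) and the α-weighted neighbour features are aggregated. Trained
full-batch with Adam, class-weighted cross-entropy, early stopping on
validation AUROC, and a random-then-grid hyperparameter search scored
by 3-fold CV AUROC. The operating point is the Youden threshold; genes
scoring > 0.9 become predicted disease genes. Implemented on a small
numpy reverse-mode autodiff engine (no GPU framework needed); gradients
and the attention forward pass are verified against independent oracles
in the test suite.

**Repositioning.** For disease network N_g (positives ∪ predicted
genes, plus first neighbours) and each drug network N_di (targets plus
first neighbours):

* Jaccard overlap J(N_g, N_di) = |N_g ∩ N_di| / |N_g ∪ N_di|,
* closest network distance d = mean over g ∈ N_di of the hop distance
  to the nearest disease gene,
* z = (d − μ)/σ against 1,000 random degree-matched pseudo-target sets.

Drugs pass the summary filter when J exceeds the all-drug mean, z < −2
and at least half of N_di overlaps N_g; drug–target pairs with median
IC50 < 10,000 nM count as physical interactions.

A seeded synthetic-data module (`retarget.simulate`) generates all
inputs with planted ground truth — differential genes, informative
annotation features, a homophilous scale-free interaction graph, and
proximal planted drugs — so every stage is testable end to end.

## Worked example

```python
import retarget as rt
from retarget.netgraph import impute_unweighted_edges

cfg = rt.SimulationConfig(seed=1)          # 2,000 genes, 60+60 samples
expr, feats, graph, drugs, ic50, truth = rt.simulate_all(cfg)
graph = impute_unweighted_edges(graph)

de = rt.differential_expression(expr)
labels = rt.assign_labels(de)
split = rt.stratified_split(labels, seed=1)
filtered, counts, _ = rt.filter_pipeline(
    feats, labels, seed=1, train_genes=split.index[split == "train"])

clf = rt.GeneClassifier(filtered, labels, graph, split, rt.GATConfig(seed=1))
res = clf.fit(n_random=4, grid_refine=True, seed=1)
print(res.summary())

disease = set(labels.index[labels.isin(("positive_up", "positive_down"))])
disease |= res.predicted_genes()
repo = rt.DrugProximityModel(graph, disease, drugs).fit(n_perm=1000, seed=1)
print(repo.summary())
```

prints:

```
Gene classifier (graph attention network)
=============================================
genes: 2000  train/val/test: 357/45/45
config: hidden_dim=32 heads=8 dropout=0.5 lr=2.10e-04
Youden threshold (validation): 0.579
test AUROC:     0.893
test precision: 0.909
test recall:    0.667
test F1:        0.769

Network-proximity drug repositioning
=============================================
drugs scored: 200 / 200   permutations: 1000
disease network size |N_g|: 602
mean Jaccard: 0.0406
drugs with z < -2: 8
summary-filter passers: 8

          jaccard      z  overlap_fraction
drug
drug_076    0.149 -3.669             0.989
drug_127    0.141 -3.557             0.977
drug_077    0.139 -3.492             0.977
drug_118    0.133 -2.825             0.910
drug_169    0.116 -3.038             0.888
drug_041    0.085 -2.797             0.812
drug_088    0.060 -2.381             0.740
drug_116    0.058 -2.205             0.720
```

Reading the numbers: the classifier separates held-out positive from
negative genes with AUROC 0.89; precision/recall/F1 are reported at the
validation-set Youden threshold (0.579). The repositioning stage then
keeps the drugs whose target networks are significantly closer to the
disease network than size-matched chance (z < −2) with above-average
Jaccard overlap — in this simulation the top five passers
(`drug_076`, `drug_127`, `drug_077`, `drug_118`, `drug_169`) are
exactly the five drugs whose targets were planted inside the disease
neighbourhood (`truth.planted_drugs`).

The same pipeline is scriptable from the shell:

```bash
retarget simulate --out study/ --seed 1
retarget label --expr study/expression.tsv --groups study/groups.tsv --out labels.tsv
retarget features --features study/features.tsv --labels labels.tsv --seed 1 --out feat/
retarget train --features feat/features_filtered.tsv --labels labels.tsv \
    --split feat/split.tsv --network study/network.tsv --seed 1 --out model/
retarget reposition --graph study/network.tsv --disease-genes disease.txt \
    --drugs study/drugs.gmt --nperm 1000 --seed 1 --out repo/
```

## Layout

```
src/retarget/
  simulate.py    synthetic study generator (+ planted ground truth)
  de.py          moderated differential expression and labeling
  featsel.py     feature filters, stratified split, normalization
  netgraph.py    graph merging, weight imputation, subgraphs
  autodiff.py    minimal reverse-mode autodiff on numpy
  gat.py         graph-attention layers and training loop
  classifier.py  GeneClassifier / ClassifierResults (search, Youden, metrics)
  cluster.py     embedding K-means with silhouette-selected K
  reposition.py  DrugProximityModel / RepositioningResults (J, d, z, filters)
  examples.py    bundled published worked-example tables
  io.py, cli.py  TSV/GMT/GraphML I/O and the click CLI
docs/methods.md  model details, numerical choices, limitations
```
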