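# damgcn

Cross-domain node classification on patient-similarity graphs with an
adversarial domain-adaptive multichannel graph convolutional network
(DAMGCN).

## The problem

Clinical cohorts for outcomes such as all-cause death, cardiac-function
risk or MACE occurrence are small, imbalanced and distributed differently
from hospital to hospital and from year to year, so a node classifier
trained on one cohort graph rarely transfers to a related one. `damgcn`
addresses this by training **one** model jointly on a labeled *source*
cohort graph and a related *target* cohort graph that share label
semantics but differ in feature distribution, transferring knowledge
through shared encoder weights and an adversarial domain objective. It is
aimed at researchers working with tabular patient cohorts (one row of
numeric features per patient) who want graph-based risk classification
that survives a domain change.

## The model

Each domain is an attributed graph G = (V, E, X, Y). When no edge list is
supplied, edges come from k-nearest-neighbour similarity in feature space
(k = 6 by default, union-symmetrized, undirected). Two propagation
operators drive a shared two-layer graph convolutional encoder
σ(S X W), with hidden widths 128 → 16:

* **Local consistency** — S = D̃⁻¹ᐟ² (A + I) D̃⁻¹ᐟ², the symmetric
  self-loop-normalized adjacency.
* **Global consistency** — S = D⁻¹ᐟ² P D⁻¹ᐟ², where P is the positive
  pointwise mutual information matrix of node co-occurrences harvested
  from random walks (walks are sentences, nodes are words;
  PPMI_ij = max{log(p_ij / (p_i· p_·j)), 0}).

The two channel embeddings Z_A and Z_P are fused per node by a learned
two-way attention, Z = att_A ⊙ Z_A + att_P ⊙ Z_P with
att_A + att_P = 1, keyed on a shared projection J X of the raw features.
Training minimizes

L = L_S + γ₁ · L_DA + γ₂ · L_T

where L_S and L_T are cross-entropy losses of source and target label
heads on stratified 60 % training splits, and L_DA is the binary
cross-entropy of a domain classifier fed through a **gradient-reversal
layer** (identity forward, gradient × −λ backward) so that the shared
encoder learns domain-invariant embeddings. λ ramps as
min(2/(1+e^(−10p)) − 1, 0.1) over training progress p; Adam, fixed
lr = 0.003, 300 full-batch epochs, seed 21, γ₁ = 1, γ₂ = 0.8.

Ablation variants are built in: `no_target` (drop L_T), `no_global`
(drop the PPMI channel and attention — a plain GCN), `no_domain` (drop
the adversary).

## Worked example

No clinical data is shipped; the synthetic generator produces paired
cohorts with the same statistical shape (25 features, binary imbalanced
outcome, covariate-shifted target). All numbers below are what the
commands print.

```bash
damgcn simulate --out demo/data --seed 7
# wrote source (300 nodes) and target (300 nodes) under demo/data

damgcn train --source demo/data/source --target demo/data/target \
             --out demo/run --seed 21
# final losses: L_S=0.0150 L_DA=0.6949 L_T=0.0132
# target test accuracy: 0.8917 (MCC 0.5850)
```

Both label losses are driven near zero while the domain loss stays near
log 2 ≈ 0.693 — the adversary cannot tell the domains apart, which is
exactly what domain-invariant embeddings look like. `demo/run/` contains
the checkpoint, the per-epoch loss trace
(`epoch, L_S, L_DA, L_T, total, lambda`) and a metrics table whose
columns are Accuracy, AUC, Precision, Recall, F1score, MCC, Balanced
accuracy (macro averaging; the target test split here scores
accuracy 0.892, AUC 0.916, MCC 0.585). The ablation grid

```bash
damgcn ablate --source demo/data/source --target demo/data/target \
              --out demo/ablate --epochs 200 --seed 21
```

trains all four variants on the pair. On any single pair and seed the
full/no_global/no_domain ordering can fluctuate by a point; averaged over
seeds the full model is at or above every ablation and `no_target` is
clearly weakest (the test suite checks exactly this, over 5 seeds).
`damgcn export-embeddings --layer fused ...` writes the 16-dimensional
fused embeddings with aligned labels for external 2-D projection (e.g.
t-SNE).

Real cohorts flow through the same paths: give `--source`/`--target`
directories containing `features.csv` (one patient per row, optional
header and `node_id` column), `labels.csv`, and optionally `edges.tsv`
(0-based undirected pairs; otherwise the KNN graph is built for you).

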