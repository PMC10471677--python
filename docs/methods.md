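# Methods

## Model

One DAMGCN instance holds a single set of weights used by both domains.
The encoder is a two-layer graph convolution per channel,
Z⁽ⁱ⁾ = σ(S Z⁽ⁱ⁻¹⁾ W⁽ⁱ⁾ + b⁽ⁱ⁾), σ = ReLU, widths d → 128 → 16, with
dropout (rate 0.5) applied after each hidden activation during training
only. The local channel uses S = D̃⁻¹ᐟ²(A+I)D̃⁻¹ᐟ²; the global channel
uses the degree-normalized PPMI matrix S = D⁻¹ᐟ² P D⁻¹ᐟ². Both
normalizations are symmetric: the symmetric form is the graph-convolution
standard, keeps the operator's spectrum in [−1, 1], and makes the
operator a similarity transform of the row-stochastic random-walk
operator. Note that row sums of the symmetric form are *not* bounded by
1 (a hub row can exceed it); the invariant that holds, and that the tests
check, is spectral radius ≤ 1.

Channel weights are separate (local vs global) but shared across domains;
sharing across domains is the transfer mechanism. The attention scorer is
s = vᵀ tanh(W_att [z ∥ (JX)ᵢ] + b) with J a shared d × 16 projection of
the raw features; the per-node softmax over the two channel scores gives
convex weights, so the fused embedding is always a per-node convex
combination of Z_A and Z_P. The scorer is shared across channels and (by
default) across domains — the encoder is shared, so sharing the scorer
maximizes what transfers; `ModelConfig(share_attention=False)` unshares
it. Any per-node scalar scorer would satisfy the fusion contract; the
tanh form is the minimal learned choice. The domain classifier is one
ReLU hidden layer of width 16 onto a single sigmoid logit; label heads
are linear-plus-softmax.

## PPMI channel

Walks restart from every non-isolated node (isolated nodes get zero PPMI
rows and rely on the local channel alone); each step samples the
row-normalized adjacency. Defaults: 10 walks per node, 40 steps, window 5
— conventional skip-gram-scale values, exposed in `WalkConfig`. The
frequency matrix counts ordered (center, context) pairs within the
window, so a corpus closed under reversal yields a symmetric F. PPMI uses
the natural logarithm; any other base rescales P uniformly and is
absorbed by the learned weights. PMI values below 1e-12 nats are snapped
to exactly zero: for count matrices whose joint factorizes into its
marginals the true PMI is identically zero, and the snap removes the
~1e-16 floating-point residue without affecting any genuinely dependent
pair.

## Objective and schedule

L = L_S + γ₁ L_DA + γ₂ L_T, with γ₁ = 1 and γ₂ = 0.8 by default. γ₂ is
an optional second balance parameter on the target term; `strict_total`
forces γ₂ = 1, recovering the plain unweighted sum. L_S and L_T are mean
cross-entropies over the *training* split of each domain (the supervised
setting implies the split, not all target nodes); true-class
probabilities are clamped at 1e-12 before the log and the clamp is
logged. L_DA is mean binary cross-entropy over all N_S + N_T nodes,
source labeled 0 and target 1 (the loss is symmetric in that choice),
reached through the gradient-reversal layer Q_λ (forward identity,
backward −λ·gradient).

The ramp λ(p) = min(2/(1+e^(−10p)) − 1, 0.1) with p = epoch/(epochs−1)
starts at 0 and saturates at the 0.1 cap early in training. A second
mode, `as_printed`, evaluates min(1/(1+e^(−10p)) − 1, 0.1); that
expression is ≤ 0 for every p (it starts at −0.5), which flips the
adversary into cooperation, so it exists only for exact replication of a
published form and is not the default.

Optimization is full-batch Adam (β = 0.9/0.999, ε = 1e-8) at fixed
lr = 0.003 for 300 epochs. Full-batch is deliberate: the graphs are small
and the domain loss averages over all nodes. Splits are stratified by
class (60/40) to guarantee both classes in every split of small
imbalanced cohorts. Weight initialization is seeded Glorot-uniform. All
randomness — initialization, dropout masks, walk sampling, splits —
derives from one `TrainConfig.seed` through a `SeedSequence`, so a
configuration reproduces its loss trace bit for bit.

## Numerical engine

The model trains on a compact vectorized reverse-mode autodiff engine
(`damgcn.autodiff`): a tape of numpy arrays with broadcast-aware
gradients for the dozen operations the architecture needs, plus Adam.
Gradient correctness is tested against central finite differences, and
the gradient-reversal layer against both the engine and the
finite-difference gradient of the explicitly negated branch.

## Graph construction

KNN graphs connect each node to its k = 6 nearest neighbours by Euclidean
distance on raw features (an optional z-score flag standardizes first;
upstream preprocessing of real cohorts is assumed, not restated).
Distances are computed densely and neighbours chosen with a stable
argsort, so ties break toward the lower node index and the graph is a
deterministic function of the features. Symmetrization is by union. All
node indexing is 0-based.

## Synthetic generator

`SyntheticSpec` emulates the statistical shape of small clinical cohorts:
two domains, d = 25 features, binary outcome with positive fraction 0.15,
class-conditional Gaussian features with centroids `class_sep` = 3 noise
standard deviations apart along a seed-fixed direction, n = 300 nodes per
domain. The target domain applies a rigid rotation (Givens angle
0.15·`shift` rad on successive coordinate pairs) plus a translation of
norm `shift` (default 1.0, a moderate shift) to the whole cloud —
covariate shift that preserves label geometry. Defaults were chosen once
as a realistic desk-scale regime: separable enough that training
converges in 300 epochs, shifted enough that a source-only classifier
measurably degrades.

What the generator does **not** emulate: real clinical covariate
semantics, missingness, heavy-tailed or categorical features, and label
noise. Passing tests therefore demonstrate the mechanics and the
direction of the transfer effects, not clinical performance; on real
cohorts the magnitudes will differ.

## Problem sizes in the test suite

The default test run trains full 300-epoch models at the default
synthetic scale (300 + 300 nodes) for the loss-decomposition and
determinism checks, and a 5-seed × 4-variant ablation grid at 200 epochs
for the transfer-direction check; unit tests use 6- to 60-node instances.
These sizes keep the whole suite in the low minutes on one CPU while
exercising every code path at the same hyperparameters used for full
runs.

## Known limitations

* Binary outcomes only in the generator; the model and metrics accept
  C > 2 (multiclass MCC uses the standard generalization) but the AUC
  convention is positive-class, binary.
* Dense N × N operators throughout — appropriate for cohort graphs of
  10²–10⁴ nodes, not for web-scale graphs.
* The sampled-walk PPMI estimator is the only global-channel estimator;
  no closed-form expected-frequency variant.
* Single-head attention and a fixed two-layer encoder; deeper or
  alternative GNN operators are out of scope.
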