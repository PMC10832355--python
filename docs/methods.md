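# Methods

## Problem and overall design

Spatial omics assays measure an expression vector (genes or proteins) and a
2-D position for every spot (cell, bead, or pixel). Spatial-domain
identification asks for a partition of spots into contiguous tissue regions
with coherent expression — cortical layers, hippocampal fields, and so on.
`spatialgdl` frames this as unsupervised graph representation learning: a
spot–spot neighbor graph built from coordinates carries messages between
neighboring spots' expression profiles, a graph deep-learning (GDL) module
trains node embeddings without labels, and ordinary clustering of the
embeddings yields the domains. Because neither the best GDL objective nor
the best GNN architecture is settled, both are interchangeable here: two
modules (deep graph infomax and a variational graph autoencoder) times six
encoder families, benchmarked per dataset by adjusted Rand index (ARI)
against ground truth and by training cost.

## Preprocessing

Counts are library-size normalized to the median total per spot, log1p
transformed, and optionally z-scored per feature (default on; constant
features are guarded by clamping the sd to 1, which zeroes their columns).
Highly variable genes are ranked by normalized dispersion — variance/mean
of the log-normalized matrix — with ties broken by ascending column index;
the default budget is 3000 genes. Panels of at most 50 features (protein
imaging panels) skip selection and keep every feature, as do datasets with
fewer features than the budget. Spots with zero total count produce a
warning and an all-zero row, not an error; no spot filtering is applied by
default. The exact normalization recipe is a design choice — "normalized
variance of highly variable genes" admits several readings — and this one
was fixed because it is the standard single-cell recipe and fully
deterministic.

## Spatial graph

Adjacency comes from either the k-nearest-neighbor model (default k=6,
matching hexagonal Visium-like neighborhoods) or the fixed-radius model
(for imaging data). kNN edges are symmetrized by union rather than
mutuality so that no spot is isolated by one-sided selection; exact
distance ties break by ascending spot index. The trained operators consume
the symmetric normalization Ã = D^(−1/2)(A + I)D^(−1/2); self loops are on
by default (the usual GCN convention, and it keeps zero-degree rows
finite — such rows normalize to zero). The spectral radius of Ã is ≤ 1,
which keeps repeated propagation (SGC powers, Chebyshev recurrences)
numerically bounded.

## Encoders

Six message-passing families are implemented from their published update
rules behind one forward contract, `(X, graph) -> n x d`:

- **GCN** — two layers of H ← act(Ã H W), final layer linear.
- **SGC** — Ã^K X W, no nonlinearity (K=2 default).
- **TAG** — per layer Σ_{k=0..K} Ã^k X W_k, two layers.
- **Chebyshev** — polynomial filter on the scaled Laplacian; λ_max is fixed
  at 2 (the upper bound for the normalized Laplacian) rather than
  eigensolved per graph, which makes the scaled operator exactly −Ã and
  the recurrence deterministic.
- **SAGE** — W_self x_i + W_neigh·mean of neighbors; isolated spots use a
  zero neighbor mean.
- **GATv2** — per-edge scores aᵀLeakyReLU(W_l x_i + W_r x_j), softmax over
  each in-neighborhood including the self loop, heads concatenated.

Hidden activation is PReLU inside the infomax module (its original
convention) and ReLU inside the autoencoder. Weights are Glorot-uniform,
seeded; no biases or edge weights (the spatial graph is binary). Defaults
of one hidden layer, hidden width 128 and latent width 32 are package
choices — layer counts and widths are hyperparameters with no canonical
value — and every benchmark in this repository states the widths it used.

All gradient training runs on a small reverse-mode autodiff tape over
NumPy arrays (`_autodiff.py`) supporting the dense/sparse products,
reductions and segment-softmax these models need, with Adam as the
optimizer. Gradients are verified against central finite differences in
the test suite.

## Deep graph infomax module

Negative samples corrupt the data by permuting feature rows while reusing
the topology. The readout is sigmoid∘column-mean; the discriminator is the
bilinear form sigmoid(hᵀWS). These concrete forms follow the original
infomax design, which the objective here adopts; the loss is the standard
BCE, −mean log D(h,S) − mean log(1−D(h̄,S)) — the negation of the printed
mutual-information lower bound, minimized. One fresh corruption is drawn
per epoch (flag-exposed). Final embeddings are the positive-branch encoder
outputs. Training internally uses the logit-space softplus form of the
BCE for stability; the probability-space `dgi_loss` function clamps scores
at 1e-12 before the log.

## Variational graph autoencoder module

The first layer is a single message-passing layer of the chosen family
(ReLU output); the second propagates once more and applies the head weight
W1 to give the posterior mean μ and log-variance log σ². **By default the
two heads share the one weight matrix W1, so μ and log σ² are element-wise
identical.** This coupling is unusual — the classical VGAE uses separate
head weights — but it is implemented as stated in the formulation this
package follows; the separate-head variant sits behind
`share_heads=False` and neither is asserted as "correct". Latents are
sampled once per epoch via Z = μ + σ⊙ε; the inner-product decoder
sigmoid(ZZᵀ) reconstructs the adjacency with self loops counted as
positive edges. The loss is class-weighted reconstruction BCE (positive
weight (n²−‖A‖)/‖A‖; degenerate all-edge or no-edge targets fall back to
an unweighted mean) plus the Gaussian KL to the standard-normal prior
averaged per spot. The KL enters with scale 1.0 on that per-spot average,
which reproduces the classical VGAE objective's 1/n weighting exactly
once. The clustering embedding is μ, not a sample, so downstream
clustering is deterministic.

## Clustering, metrics, ranking

When the number of domains is known (labels present), embeddings are
clustered by a seeded full-covariance Gaussian mixture with that k —
mirroring how spatial clustering methods are usually benchmarked with the
annotated domain count; otherwise Leiden on a kNN graph of the embeddings.
ARI is the chance-corrected pair-counting agreement; NMI uses
arithmetic-mean normalization. Both are computed through scikit-learn and
are cross-checked in the tests against hand-coded pair-counting and
entropy oracles, exhaustively over every partition pair of up to six
elements. ARI alone drives ranking; ranks are per dataset (1 = best, ties
share the mean rank) and averaged across datasets. The trade-off set per
module is the intersection of the top-n most accurate and top-n fastest
encoders (n=10 by default). Wall time is measured around training only —
preprocessing and I/O are shared across combinations and excluded. When a
dataset carries partial annotation, ARI should be computed on annotated
spots only; the synthetic benchmark is fully labeled so this never
triggers here.

## Synthetic benchmark

The generator emulates two geometries. `layers`: spots on a jittered grid
(jitter sd = 0.25 × spacing, avoiding degenerate kNN ties) in the unit
square, domains as contiguous horizontal bands balanced to within one
spot — a layered-cortex caricature. `blobs`: Gaussian clouds around
uniform random centers, labels by nearest center — an imaging-data
caricature. Expression is lognormal: per-gene baseline ~ N(1, 0.3) on the
log scale, each domain elevating its disjoint 20-gene program by
signal_strength × noise_sd (defaults 3 and 1), Gaussian log-noise, and
10% multiplicative Bernoulli dropout. The default shape is 800 spots ×
200 genes × 5 domains. `expected_separability` scores difficulty as
signal/√(1 + p/(1−p)) for dropout rate p.

The generator deliberately omits count overdispersion, platform noise and
real gene identities: the framework consumes normalized features, so the
tests probe recovery of mean-shift domain structure, not robustness to raw
sequencing noise. Passing them shows the machinery is correct, not that
any particular ARI will be reached on real tissue.

One subtlety of null (zero-signal) data is worth knowing: an embedding
trained on the spatial graph is never at exact chance against spatially
contiguous null labels, because message passing smooths even pure-noise
features along the graph — any clustering of such embeddings is spatially
contiguous and therefore weakly aligned with contiguous bands (measured
mean ARI ≈ +0.06 on the default preset). The label–expression
independence of the generator is checked on expression-only (PCA)
embeddings, which sit at chance (mean ARI ≈ 0.000). The ~0.06 offset is
the footprint of the graph prior, and it is exactly why spatial methods
outperform expression-only clustering when real signal is present.

## Problem sizes and numerical choices

Benchmark sweeps in the tests and the reproduction script run the 800-spot
preset at hidden width 64, latent 32, 60 epochs, Adam at 1e-3 (DGI) /
1e-2 (VGAE) — desk-scale settings chosen so a full 2×6 sweep runs in about
a minute on one CPU while still separating the well- from the
poorly-suited combinations. Probabilities are clamped at 1e-12 before
logs; softplus-based BCE is used wherever logits are available; sigmoid
inputs are clipped at ±500. A non-finite loss aborts training with the
epoch in the diagnostic rather than continuing silently.

## Known limitations

No mini-batching: graphs are held in memory and the VGAE decoder is dense
n×n, so very large slides need subsampling. No histology/image features,
no batch correction or imputation, 2-D coordinates only, and the encoder
registry covers six families — the contract (spec → forward) admits more
without touching the training modules.
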