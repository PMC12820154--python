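# Methods

## Model and objective

The classifier is a DeiT-tiny Vision Transformer: patch size 16, embed dim
192, 12 pre-norm blocks, 3 heads, MLP ratio 4, a single CLS token and a
linear 2-class head. No distillation token is used — the published
parameter accounting (147,456 trainable; 5,672,258 total) is consistent
only with the single-CLS, 2-class architecture, so that variant is adopted.
Blocks are pre-norm (LN before attention/MLP), the DeiT convention;
parameter counts are unaffected by that choice. Patch flattening order is
row-major over the patch grid and row-major by pixel then channel within a
patch; the embedding formula leaves this open, so it is fixed and tested
against a per-patch loop.

LoRA adapters attach to the query and value slices of the fused QKV
projection — algebraically identical to adapting separate projections, and
it preserves the printed counts. A is initialized Gaussian with σ = 1/r,
B is zero, so the adapted model equals the base model at injection; the
suite asserts this bit-exactly. Two scaling conventions are implemented:
`alpha_over_r` (s = α/r = 2, the standard LoRA scaling, default) and
`alpha_literal` (s = α = 32, the formula read literally). Counts and
payloads are identical under both. The classification head is frozen by
default so the trainable set is exactly the 147,456 adapter floats that are
transmitted (0.56 MiB at 32 bits); a `train_head` flag includes it, which
any from-scratch or new-label-space use needs.

The FedProx proximal norm is taken over the trainable (exchanged) tensors
only, anchored at the weights received at round start — the only set both
parties share. AdamW's decoupled weight decay and the proximal term coexist
as configured, without de-duplication. The cosine schedule steps once per
local epoch with T_max = the local epoch count.

Aggregation weights are nᵢ/n (local sample counts); LoRA updates are
averaged entrywise over A and B. Note mean(A)·mean(B) ≠ mean(AB) in
general; entrywise averaging is the standard choice because it keeps the
aggregation rule linear in the transmitted tensors. Uplink and downlink
payloads are logged separately and are equal under full participation.

## Implementation

Everything numerical is NumPy. The forward pass has a single source of
truth (`autodiff.model_forward`), used by eval-mode inference, training and
attention extraction alike. The backward pass is hand-derived per layer
(layer norm, fused-QKV attention with LoRA branches and inverted dropout,
GELU via the exact erf form, softmax cross-entropy) and verified in the
test suite against central finite differences on every tensor of a small
configuration. AdamW is the standard decoupled form. All randomness flows
through explicitly seeded `numpy.random.Generator` instances, so runs are
bit-reproducible.

## Metrics

Accuracy, precision, recall and F1 come from the binary confusion matrix
with pneumonia as the positive class; the same formulas with roles swapped
give the normal-class figures (normal "precision" is TN/(TN+FN), matching
the published table's reading). Zero denominators return 0 with a
degeneracy flag. Percentages display at two decimals, round-half-up.

AUC uses the rank (Mann–Whitney) estimator with ties counting one half; AP
is the step-wise precision-weighted recall sum with tied scores processed
together. Both are cross-checked against scikit-learn and against
brute-force pair/threshold oracles. Youden's J scans the observed scores
with a ≥-threshold decision rule, ties broken toward the higher cutoff.

Communication cost supports two MB conventions: bytes/10⁶ (the formula as
printed) and bytes/2²⁰. The published payload pair (21.64 / 0.56 "MB") is
reproduced only by the binary convention, so that is the default and the
discrepancy is documented rather than hidden: 147,456 × 4 bytes is
0.56 MiB but 0.59 decimal MB.

## Synthetic data and the packaged benchmark

The generator emulates the gross appearance of a frontal radiograph at
small resolution: dark background, two bright elliptical lung fields
(smoothed), Gaussian pixel noise (σ = 0.05 by default), and — for pneumonia
— 2–4 Gaussian opacity blobs of amplitude ≈ `effect_size` planted inside
the lung fields. Labels are a stratified Bernoulli(prevalence) draw.
Defaults: 600 images, prevalence 0.5, effect 0.25 = 5× the noise σ, which
makes the class signal strong but spatially structured. It does **not**
model ribs, cardiac silhouettes, positioning or scanner physics, pediatric
anatomy, or label noise — so passing tests demonstrate the *mechanics* of
federated LoRA/FedProx training, not clinical performance.

Non-IID clients use Dirichlet(β) label skew (per class, client proportions
~ Dirichlet(β·1_K), largest-remainder integer allocation, bounded
resampling so every shard is non-empty) plus an optional per-client global
intensity offset as feature skew. β = 0.5 is the generic default; the
benchmark uses β = 0.3 with intensity shift σ = 0.08 to produce the
high-heterogeneity regime the method targets.

The packaged benchmark mirrors the fine-tuning setting LoRA presumes, in
two stages. First a tiny backbone (image 64, patch 16, embed 48, depth 4,
3 heads) is trained centrally on a synthetic *source* domain (weaker
effect 0.15, heavier noise 0.08, 300 images, 6 epochs, AdamW 1e-3) — the
stand-in for generic pretraining; from scratch, adapter-only training
cannot move a random backbone, which is a real property of LoRA, not an
artifact. Then 400 target-domain images are split across 10 clients and
each arm fine-tunes the shared backbone for 10 rounds, 2 local epochs,
batch 8, AdamW 1e-4 (the published fine-tuning rate), μ = 0.5, full client
participation. Problem sizes were chosen so a full four-arm comparison
completes in a couple of minutes on one CPU. Under these conditions the
full-model FedAvg arm visibly drifts while the LoRA arms (and especially
FedProx + LoRA) remain stable — the qualitative ordering the method
predicts; magnitudes are not comparable to full-scale results and are not
asserted.

## Explainability

Attention rollout follows the standard recipe: per block, head-averaged
attention is mixed 0.5/0.5 with the identity (residual path), row
re-normalized, and the mixed matrices are multiplied across blocks; the CLS
row over patch tokens is reshaped to the patch grid and bilinearly
upsampled. Head aggregation is mean (max available). RISE upsamples
Bernoulli(keep) cell grids with random sub-cell offsets, scores the masked
images for the predicted class, and averages masks weighted by score; by
default the per-pixel sum is divided by the per-pixel mask coverage (exact
correction), which makes a constant scorer yield an exactly constant map.
Both are labeled reconstructions of the named techniques; heatmaps are
min-max normalized for display.

The heterogeneity score embeds pooled per-client features to 2-D with
t-SNE (fixed seed; perplexity clamped to (n−1)/3) and returns the mean
pairwise Euclidean distance between client centroids. An identity-embedding
mode bypasses t-SNE so the centroid arithmetic is exactly testable; t-SNE
distances depend on embedding scale, so scores are comparable only within
one embedding run.

## Numerical choices and degenerate inputs

Layer norm uses ε = 1e-6. Softmax subtracts the row max. The split
redistribution draws round(fraction·pool) validation items allocated
across classes by largest remainder (stratified), so totals are conserved
exactly. Empty shards raise a skip signal at the client and an error only
if *all* clients skip. Merging adapters folds s·AB into the fused QKV
weights, deletes the adapter tensors, and is idempotent. Checkpoints and
adapter states are HDF5 files with a JSON metadata attribute (config,
trainable mask, LoRA header).

## Known limitations

Single-process simulation only (no RPC, stragglers, or secure
aggregation); binary classification; no DICOM ingestion; no pretrained
ImageNet weights shipped (loading a checkpoint is supported); t-SNE-based
heterogeneity is a visualization-derived score, not a calibrated
statistic; and synthetic-data results do not transfer to clinical claims.
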