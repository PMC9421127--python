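# Methods

## The model

`gednn` classifies a binary phenotype from SNP genotypes with a feedforward
network whose first two weight layers are constrained by biological graphs.
Let `X₀` be the n × p matrix of minor-allele dosages (0/1/2), `A` the binary
p × q SNP–gene adjacency derived from eQTL pairs (optionally augmented with
positional cis links), and `A′` the binary q × q gene–gene adjacency derived
from PPI edges, symmetrized and given a unit diagonal so each gene's unit is
wired to itself. The forward pass is

    X₁ = δ(X₀ (W₀ ⊙ A)  + b₀)        SNP → gene layer
    X₂ = δ(X₁ (W₁ ⊙ A′) + b₁)        gene → gene layer
    X₃ = δ(X₂ W₂ + b₂), …            dense hidden layers
    P(y|X₀) = softmax(Xₙ Wₙ + bₙ)    two-unit head

with `δ` = ReLU and `⊙` the Hadamard product. Masked entries of `W₀`, `W₁`
are exactly zero at initialization, in every forward pass, and after every
optimizer step (gradients are masked before the Adam update and the mask is
re-applied after it). Training minimizes mean binary cross-entropy on the
positive-class probability plus `α · Σᵢ ‖Wᵢ‖²` (L2 by default, L1
selectable); probabilities are clamped to `[1e-7, 1 − 1e-7]` inside the log.

Four modes share this architecture and differ only in masking, which is the
ablation contrast of interest: `dnn` (no gene layers, dense chain
p → 256 → 64 → 16 → 2), `e_dnn` (A only, gene→gene layer dense), `gedfn`
(A′ only, SNP→gene layer dense), and `gednn` (both). Gene-layer modes use
hidden widths [128, 16] after the two gene layers.

The network, dropout and the Adam optimizer are implemented directly on
numpy arrays. This keeps the masked-update semantics explicit (exact zeros,
not epsilon-small values), makes runs bit-reproducible from a single integer
seed, and lets the ablations share one code path so that masking is
provably the only difference between modes.

## Hyperparameters

| parameter | default | rationale |
|---|---|---|
| learning rate | 0.001 | best candidate with batch size 8 |
| batch size | 8 | small batches: more updates per epoch, better generalization |
| dropout keep | 0.9 | keep probability for hidden activations (the candidate grid 0.5–0.9 reads as keep rates — a 0.9 *drop* rate would ablate the network); output layer excluded |
| α (weight penalty) | 1e-4 | repository choice; no published value exists |
| max epochs / patience | 200 / 30 | masked layers have sparse fan-in and receive fewer effective updates per weight, so they converge 2–4× slower than dense layers; validation AUC on ~50 samples is noisy, so short patience triggers premature stops. Early stopping monitors validation AUC and restores the best weights |
| split | 0.8 / 0.1 / 0.1 stratified | validation drives early stopping and model choice; test AUC is held out |
| standardize | on | per-SNP z-scaling using training-split statistics |

### Initialization

Weights are He-uniform: `U(−1, 1)` scaled per output unit by
`sqrt(6 / fan_in)`. For a masked layer the fan-in of a unit is its mask
degree — the number of inputs actually wired to it (the column sum of the
adjacency in the x·W orientation) — since that is the variance that matters
for a sparse row of connections. Two ReLU dead-unit guards apply uniformly
to masked and dense layers: hidden biases start at +0.1 instead of 0, and
square hidden layers take the absolute value of their diagonal at
initialization (an identity-leaning start). Without these, a gene whose
self-connection weight in the A′-masked layer draws negative and that has no
PPI neighbors receives a pre-activation that is nonpositive for every sample
— ReLU then blocks every gradient and the gene is severed from the network
for the whole run. Because both guards apply identically to dense layers,
a masked network with all-ones adjacencies remains bit-for-bit identical to
the plain dense network under a shared seed (this equivalence is asserted in
the test suite).

## Pathway scores

For every wired SNP–gene pair, `PS(s, g) = |W₀ ⊙ A|[s, g] · D[g]`, where
`D[g]` is gene g's downstream influence on the disease output: the g-th
entry of `|W₁ ⊙ A′| · |W₂| · … · |Wₙ|` collapsed to the positive-class
column. Pairs without an eQTL edge have PS = 0 and are excluded. Scores are
deliberately not normalized — PS is a product of weights on the two sides of
the gene layer, and normalization would distort their relative
contributions — so PS is linear in `W₀` (scale covariance is tested).
Absolute values prevent sign cancellation along paths; a `signed` variant
and a `two_layer` variant (downstream factor truncated at the gene–gene
layer) are available flags. Biases are excluded: PS is defined on weights.
Ties are broken lexicographically by (SNP id, gene id). Scores are defined
for modes whose SNP→gene layer carries the eQTL mask (`gednn`, `e_dnn`);
for `dnn`/`gedfn` the support of A is undefined and the call is rejected.

## Preprocessing

Fixed order: (1) drop SNPs with a missing fraction strictly greater than
20%; (2) impute survivors per column — most frequent call (ties to the
smaller call) or the column mean rounded half-to-even to a legal call;
(3) drop SNPs with MAF not strictly greater than 0.05, with
MAF = min(f, 1 − f), f = dosage sum / 2n. Both inequalities are strict by
design, and MAF is computed after imputation so every SNP shares the
denominator 2n. Sample ids are harmonized by intersecting genotype and label
tables (genotype order wins); eQTL edges naming unknown SNPs are dropped
with a logged count.

## The synthetic generator

The generator's role is to produce the coupled genotype / eQTL / PPI /
phenotype layers that the real studies draw from public resources, with the
signal planted *through* the graph structure — the layers cannot be
simulated independently, because a phenotype that ignores the SNP–gene and
gene–gene relations would make the adjacency masks carry no information.

Defaults mirror the cohorts this class of study analyzes at desk scale:
n = 500 samples (the real cohorts are 501 and 508), p = 1000 SNPs and
q = 100 genes — a scaled-down version of the several-thousand-SNP,
n ≪ p regime that motivates sparse connectivity (the training split of 400
is well below p) — MAF uniform on (0.05, 0.5), ~1–2 eQTL genes per SNP
(bipartite density 0.01 plus a guaranteed edge per SNP), PPI density 0.05,
2% missing calls.

Phenotypes follow a liability-threshold model with 20 planted causal
SNP→gene paths (effect 1.0, gene-level Gaussian noise sd 0.5; the resulting
genetic signal supports an oracle AUC of ~0.97, a strongly genetic trait).
The causal genes are grown as a connected PPI module (breadth-first over the
gene graph, restarting on exhausted components) rather than scattered
uniformly: disease genes acting cumulatively through their network
neighborhood is precisely the modeling assumption the gene–gene layer
encodes, and uniform placement would leave that layer nothing to exploit.
Gene activity = effect × (summed dosages of the gene's causal SNPs), plus a
one-step propagation over PPI edges at half weight, plus noise; the
liability is the sum of causal-gene activities and the intercept is set to
minus the sample median, fixing prevalence at ~0.5 like the near-balanced
real cohorts. Everything is reproducible byte-for-byte from the seed.

What the generator does **not** emulate: linkage disequilibrium between
SNPs, population stratification, genotyping batch effects, weighted or
directional PPI evidence, and trans-eQTL distance structure. Passing tests
therefore demonstrate that the implementation behaves correctly under the
generative assumptions of the model itself, not that the method's reported
advantage transfers to any particular real cohort.

## Evaluation protocol

All modes are compared on identical preprocessing, splits and seeds, so
masking is the only difference. AUC is the trapezoidal area under the
threshold-swept ROC curve, which equals the Mann–Whitney probability that a
random case outscores a random control with ties counted one half (asserted
against a brute-force all-pairs oracle). The sample-size sweep draws
class-proportion-preserving subsamples (largest-remainder apportionment,
within one sample of the global class proportion) at N = 500…100 and
retrains per size and seed.

With n = 500 the held-out test set has 50 samples, so a single test AUC
carries a standard error of roughly 0.07; the qualitative comparisons
therefore use medians over 10 seeds, and single-run numbers should be read
with that noise floor in mind.

## Numerical and degenerate-input choices

* Probability clamp 1e-7 inside the loss; non-finite loss raises
  "training diverged" instead of propagating NaNs.
* Adam: β₁ = 0.9, β₂ = 0.999, ε = 1e-8, bias-corrected moments.
* Mode-imputation ties toward the smaller call; mean-imputation rounds
  half-to-even. Both keep calls in {0, 1, 2}.
* Gene order in masks is lexicographic; SNP order follows the genotype
  matrix. Pruning (SNPs without gene links, genes without SNP links) is a
  fixed point: rebuilding from pruned ids changes nothing.
* A strict mask-building mode additionally prunes genes with no
  off-diagonal PPI edge ("related to both a SNP and another gene" read
  literally); the default permissive mode accepts the self-loop, since the
  unit diagonal of A′ makes every retained gene self-connected.
* Position tables are 1-based closed internally; BED input is converted on
  read (start + 1). A SNP links positionally to a gene when it lies within
  `window_bp` (default 1 Mb, the usual cis convention) of the gene's
  interval on the same chromosome.
* All-zero adjacencies, empty sample intersections, all-missing SNP
  columns, single-class splits and undersized subsamples raise errors
  naming the offender rather than producing empty results.

## Known limitations

* Binary phenotypes only; the head is a fixed two-unit softmax.
* The pathway score has no null model; ranks are comparable within a run
  but carry no significance level.
* Training is single-threaded numpy; fine at desk scale (seconds per model
  at p = 1000), not meant for biobank-scale inputs.
* Real-cohort AUC levels depend on eQTL/PPI completeness and cohort
  structure that the generator does not model; only qualitative direction
  (masking helps in n ≪ p, AUC degrades with shrinking n) is asserted.
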