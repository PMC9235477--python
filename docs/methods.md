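# Methods

`hybridppi` implements three linked pieces of machinery for
protein–protein interaction (PPI) prediction: a graph-theoretic link
plausibility score computed on a known PPI network (GLIDE), a
sequence-only convolutional model with a contact-map bottleneck whose
training is *co-supervised* by that graph score, and a calibrated linear
fusion of the two for species where a partial network exists. This note
records the models, the parameter choices and their rationale, the
numerical decisions, and what the synthetic benchmarks do and do not
establish.

## Network link plausibility (GLIDE)

For a candidate pair (p, q) on an undirected, positively weighted
network the aggregate score is

    GLIDE(p, q) = exp( α·u / (u + β) ) · CWN(p, q) + u,
    u(p, q)     = 1 / DSD_γ(p, q),

with defaults α = 0.1, β = 1000. Because u is tiny relative to β on
typical networks, the exponential multiplier stays barely above 1: the
local CWN term dominates whenever the pair shares neighbours, and the
global diffusion term u orders pairs that do not (CWN = 0 there, so the
score degenerates to u exactly).

**Local term.** CWN (Common Weighted Normalized) sums, over the common
neighbours r of p and q, the two incident edge weights normalised by r's
weighted degree:

    CWN(p, q) = Σ_{r ∈ N(p) ∩ N(q)}  ( w(p,r) + w(r,q) ) / deg_w(r).

The normalisation makes promiscuous (hub) intermediaries count less. The
form is symmetric, zero exactly when no common neighbour exists, and
strictly increasing when a common neighbour is added.

**Global term.** The diffusion state of node i is row i of the
fundamental matrix of the network's weighted random walk: with
transition operator P = D⁻¹W and stationary distribution π,

    S = (I − P + 1πᵀ)⁻¹        (undamped, γ = 1; the default)
    S = (I − γP)⁻¹             (damped, 0 < γ < 1)

and DSD(p, q) = ‖S_p − S_q‖₁ (the diffusion state distance). Row
differences of the undamped form equal the converged limit of truncated
random-walk visit-count differences — the test suite verifies this
against a brute-force truncated-walk oracle (Cesàro-averaged so the
check also converges on periodic, i.e. bipartite, graphs) to 1e-6 in L1
on a fixture suite of connected graphs up to 8 nodes, and checks the
metric axioms (including the triangle inequality) on random graphs up to
10 nodes. All linear solves are double precision.

**Degenerate inputs.** Cross-component pairs have infinite diffusion
distance, so u := 0 and the multiplier takes its u→0 limit of 1; since
such pairs also share no neighbours the score is 0. Pairs with an
endpoint absent from the network cannot be scored by graph measures at
all: they receive score 0 and are *flagged*, and downstream consumers
treat them specially (see the loss below). Percentile thresholds on
score tables use linear interpolation between order statistics
(inclusive definition), which is deterministic and monotone in the
percentile.

## Sequence model

The bottom-up model follows the D-SCRIPT architecture family. Per-residue
embeddings (L × d₀) from a pluggable embedder are projected to d
dimensions (affine map, ReLU, dropout 0.5 at train time); the two
proteins' projected residue features are combined pairwise into
absolute-difference and product features (n × m × 2d); a 1×1 hidden
layer mixes them to h channels (ReLU); a single width-7 2D convolution
plus a sigmoid yields the n × m inter-protein contact map. The
probability head max-pools the map in 9×9 blocks, subtracts a learnable
threshold μ + γ·var over the pooled entries (γ clamped at 0), averages
the active excess, and maps it through a steep logistic (learnable slope,
initial value 20, centred at 0.5) to ŷ ∈ [0, 1]. Reference
hyperparameters: d = 100, h = 50, convolution width 7, pooling width 9.

The implementation is pure numpy with hand-derived gradients per block,
verified against central finite differences in the test suite; the
convolution and its adjoints are computed with FFT convolution. Weights
are initialised uniform ±1/√fan_in from a seeded generator, and a fixed
seed makes training and inference bit-stable in a single-threaded run.
At the clamp boundaries (γ, logistic slope at 0) the backward pass uses
the right-derivative. The contact map is emitted at full per-residue
resolution (pooling happens only inside the head); prediction metadata
records the 0-based index convention. Cost is O(n·m) in the two sequence
lengths.

**Embedders.** Production use assumes a pretrained protein language
model; its features enter through `PrecomputedEmbedder`, an adapter over
an HDF5 cache of per-protein matrices. For self-contained operation the
`HashWindowEmbedder` assigns each residue a pseudo-random vector that is
a deterministic function of the k-mer window centred on it (k = 5,
d₀ = 64, seeded through a cryptographic digest, so stable across
processes). It carries exact-match signal only — identical windows give
identical rows — which suffices for the motif-based benchmarks below but
does not model the fuzzy biochemical similarity a language model
provides.

## Multi-objective loss with network co-supervision

    L = λ · ( L_BCE + g_p · L_GLIDE ) + (1 − λ) · L_MAG

* `L_BCE`: binary cross-entropy of ŷ against the interaction label
  (predictions clamped to (1e-7, 1 − 1e-7)).
* `L_GLIDE`: binary cross-entropy of ŷ against the *binarized* network
  score 1[GLIDE(p,q) ≥ threshold(g_t)]. Binarizing rather than
  regressing the raw score keeps both classification terms on the same
  scale, so g_p alone calibrates their balance. Scores are computed on
  the network defined by the positive training examples; the threshold
  is the g_t-th percentile of the negatives' score distribution (a
  config switch allows the pooled distribution instead).
* `L_MAG`: mean of the predicted contact-map entries — a sparsity
  regulariser realised as the mean so it is scale-free in sequence
  length.

Defaults λ = 0.05, g_p = 0.2, g_t = 92.5. At g_p = 0 the objective is
bit-identical to the plain weighted BCE + magnitude loss (property-tested
as an exact floating-point identity). Training positives are edges of
the scoring network by construction, so their co-supervision target is
1 without scoring. Negatives whose endpoints are not both in the network
are *excluded* from `L_GLIDE` (contributing 0, counted and logged)
rather than given target 0 — penalising the model on absent evidence
would conflate "no network support" with "network says no". Per-batch
loss is the mean over pairs. Optimisation: Adam, learning rate 0.001,
batch 25, 10 epochs, always from seeded initialisation (never from
pretrained interaction weights). Validation AUPR is recorded per epoch
and the best epoch tracked.

Negative examples are sampled uniformly from unordered non-positive,
non-self pairs at a 10:1 negative:positive ratio — the conventional
PPI class imbalance; at that ratio a random ranking scores AUPR ≈ 0.091
and AUROC 0.5, which the evaluation module verifies empirically. An
alternative strategy that samples only low-GLIDE pairs as negatives is
provided (`sample_negatives_low_glide`) for ablation studies; it is
restricted to in-network pairs by construction.

## Hybrid fusion and calibration

Where the query species has a partial PPI network and both proteins
occur in it, the network and sequence scores are fused:

    hybrid(p, q) = GLIDE(p, q) + w · ŷ(p, q),

the GLIDE coefficient fixed at 1 since only the relative weight matters.
The weight is calibrated as the ratio of logistic-regression
coefficients c_seq / c_glide fitted on held-out labelled pairs
(unregularised maximum likelihood, Newton iterations, tolerance 1e-8;
shrinkage would bias the ratio, so none is applied, and scores enter on
their raw scales because the fused score is applied to raw scales). An
intercept is included; it does not enter the ratio. The shipped default
w = 0.3268 is the value calibrated on a large held-out human PPI set and
is the recommended fallback when no species-specific calibration data
exists. Calibration inputs must be disjoint from the network that
produced the GLIDE scores and from the sequence model's training pairs;
the API records a caller-supplied disjointness attestation rather than
trying to verify provenance it cannot see. A non-positive GLIDE
coefficient leaves w undefined (ratio over a non-positive denominator)
and raises with the fit diagnostics attached.

The fitted w obeys the exact reparameterisation law w → w/c when the
sequence scores are rescaled by c, and on simulated logistic data with
known coefficients (2, 1) at 10:1 imbalance the recovery lands within
±0.05 of the true ratio 0.5 at n = 20 000 (both are tested).

## Evaluation protocols

AUPR uses step-wise (non-interpolated) precision–recall summation —
interpolation conventions move the third decimal, so the convention is
fixed and tested against a brute-force threshold-sweep oracle. AUROC
equals the Mann–Whitney concordance probability (ties counted half),
checked against an exhaustive pair-counting oracle on small inputs. FPR
at a recall level is taken at the most permissive threshold group
achieving that recall, with tied scores entering together. The step-wise
AUPR estimator has a small positive O(1/n_pos) bias under random
scores; the baseline-law tests size their inputs so the bias is
negligible and tolerate it explicitly.

Stratified analyses group pairs by M = max of the endpoint degrees
(default bins 2–5, 6–10, 11–20, ≥21, plus an underflow stratum for
M < 2) or by unweighted shortest-path distance (unreachable pairs in an
"inf" stratum). Hub filtering removes pairs with either endpoint of
degree ≥ 21 — the boundary is strict: degree 20 is kept.

The sparsification benchmark keeps a fraction p of edges while
protecting connectivity: a spanning tree grown from a seeded random edge
order is always retained, and the remaining budget (round-half-up of
p·|E|, tree edges counted inside it) is drawn uniformly from non-tree
edges. Uniformity over spanning trees is not required, only seeded
randomness; the construction is recorded in the split metadata. Held-out
positives are exactly E ∖ E_p, and the builder's tests assert that set
identity and connectivity for every (p, seed).

## Synthetic benchmarks

The generator produces connected, degree-heterogeneous networks with
planted communities (Chung–Lu style edge probabilities modulated by a
within/between-community factor; hub nodes get degree propensities of
25–40 so the ≥21 stratum is populated at n ≈ 300; stray components are
stitched to the giant component). Sequences are uniform random amino
acid strings (default lengths 50–300) into which each community's motif
(length 12, 3 copies) is planted, so interacting — mostly
intra-community — pairs share detectable exact k-mers: signal the
hash-window embedder can represent and the convolutional model can
learn. A trivial motif co-occurrence classifier must already beat the
random baseline on the test split; this certifies learnability
independently of the model. Labels are network edges (positives) plus
uniformly sampled negatives at the configured ratio; splits are
pair-disjoint and stratified by label.

The label-noise mechanism models unassayed true interactions: a stated
fraction of the negative set is replaced by same-community non-edges
with the most common neighbours — pairs whose GLIDE scores are high by
construction (verified in the tests). These planted mislabels are
confined to the *training* split, because they represent corrupted
supervision; held-out labels stay truthful so validation AUPR measures
real ranking quality.

Desk-scale study conditions, chosen once for this package: the learning
smoke benchmark uses 60 nodes, mean degree 3, sequence lengths 40–80,
10:1 negatives, and a tiny model configuration (d = 20, h = 10) trained
for the standard 10 epochs — small enough for minutes-scale CPU runs,
large enough that validation AUPR clearly exceeds twice the random
baseline. The co-supervision comparison uses 60 nodes, mean degree 3,
sequence lengths 35–70, 10:1 negatives and a noise fraction of 0.10 —
enough corrupted supervision for the mitigation effect to be measurable
— over 5 seeds, comparing g_p = 0.2 against g_p = 0 by median best
validation AUPR.

**What the synthetic results do and do not show.** Passing tests
establish that the scores are computed exactly as specified, that the
loss and combiner have their intended algebraic structure, that the
architecture can extract planted sequence signal, and that the
co-supervision machinery behaves sensibly under controlled label noise.
They do not establish biological performance: real PPI networks have
richer topology than the block model, real interaction signal is not
exact motif matching, and the hash-window embedder is not a protein
language model. Conclusions about real corpora require the
`PrecomputedEmbedder` route with real embeddings and full-size training.

## Known limitations

* The numpy implementation is single-core; full-scale (d = 100, h = 50,
  sequences to thousands of residues) training is feasible but slow
  compared to a GPU tensor framework. The module boundaries keep the
  model contract independent of the execution engine.
* `glide_table` recomputes nothing across calls but holds dense
  diffusion-state matrices per connected component (O(N²) memory);
  networks beyond ~10⁴ nodes need a blocked solver.
* The negative sampler enumerates the candidate pool when the request
  exceeds half the pool; for very large protein sets with dense positive
  sets this is memory-heavy.
* Calibration assumes a logistic relationship between the two scores and
  the label; gross mis-specification shows up in the stored fit
  diagnostics, not automatically.
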