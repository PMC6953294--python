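# Methods

`coevonet` implements an end-to-end learning pipeline for protein
residue–residue contact prediction from a multiple sequence alignment
(MSA), together with the multi-task extension to 3-state secondary
structure (SS) and accessible surface area (ASA) prediction, CASP-style
evaluation, and a synthetic-data generator that makes the whole pipeline
testable on a desktop CPU.

## Model

### Input features

Columns are indexed by the query (first, gap-free) sequence.  Over the
21-letter alphabet (20 amino acids in alphabetical one-letter order,
code 20 = gap; non-standard letters B/Z/X/U/O/J collapse onto the gap
code to keep the alphabet closed), the model input is the pairwise
covariance tensor

    S[i, j, 21a + b] = f(a_i, b_j) − f(a_i) f(b_j),

an L×L image with 441 channels, where f are weighted relative
frequencies: each alignment row n carries a weight w_n > 0 and
frequencies are weighted sums normalized by Σw.  With unit weights this
reduces to plain counting.  No pseudocounts are applied; `S` is exactly
zero for an alignment of identical rows and every entry is bounded by
0.25 in absolute value.

The *feature-added* input appends, for a total of 527 channels:
query one-hot (20 channels, tiled row-wise, plus the transposed copy),
PSSM = the weighted 21-symbol column frequencies (21 × 2) — kept as
frequencies, not log-odds, because no background distribution enters
the model anywhere — column Shannon entropy in nats (1 × 2), mutual
information of column pairs in nats (1), and sequence separation
|i − j| / 100 clipped at 1 (1).  Entropy/MI use the natural log; any
fixed base is a per-channel rescaling absorbed by the first
convolution.  Zero-frequency MI terms are dropped (the 0·log 0 = 0
limit), implemented by clipping inside the log only, so exact zeros
contribute exactly zero.

### Sequence weighting

Weights come from a small MLP applied row-wise to seven per-sequence
features: alignment depth (fed as log10 N / 5 so it shares the unit
scale of the other features; the raw count would dominate), identity
with the query, identity with the consensus (column-wise most frequent
non-gap symbol, ties to the lowest code), gap ratio, and the alignment
means of the last three.  Identity counts the gap as an ordinary
symbol and normalizes by the full length.  The MLP is 7→7→7→1 with
ReLU hidden layers and a sigmoid output, so weights lie in (0, 1); the
sigmoid output (not named in the original description) is our reading
of reported weight distributions concentrated in [0, 1].  Because the
weights enter the covariance multiplicatively, gradients of the
contact loss flow back into the MLP — the pipeline is differentiable
end to end, which is the point: the network can learn to discount
noisy, non-homologous rows.  Drop-feature ablations (5-input variants)
are supported.

### Networks

All variants share the trunk: a 1×1 convolution reduces the input
channels to 128, followed by 30 residual blocks, each two
(BatchNorm–ReLU–3×3 conv) layers with an identity skip — 60 trunk
convolutions, 'same' padding so every layer is L×L.  Pre-activation
ordering is our choice; the source names the components but not their
order, and pre-activation trunks get the standard final BatchNorm–ReLU
before each output head (without it the raw residual stream feeds the
head un-normalized, which measurably hurts trainability).
A per-pixel linear map (1×1 convolution) and a sigmoid give
contact probabilities; a literal dense layer over L×L pixels would make
the parameter count depend on protein length, contradicting the
length-independence of the architecture.  Probabilities are
symmetrized as (p + pᵀ)/2.

The multi-task variant shares the first 20 blocks and gives each task
(contact, SS, ASA) a private 10-block head.  The SS/ASA heads reduce
the L×L×128 pair map to per-residue features by mean-pooling row i and
column i and concatenating (256 features per residue); pooling is our
resolution of how an L-length axis becomes a fixed-size input.  The SS
head ends in a 3-way softmax; the ASA head ends in a linear map passed
through softplus — the smooth way to honor the non-negativity of an
area (a raw linear output, the literal reading, can go negative).

Depth and width are configurable; tests and examples use micro-models
(e.g. 8 blocks × 32 channels) with the same structure.

### Losses and training

Total loss = contact + SS + ASA, unweighted (faithful but fragile: the
ASA term is in Å², the cross-entropies in nats; at full scale the
published recipe evidently tolerates this).  Contact loss is the
summed binary cross-entropy over unordered pairs i < j with separation
≥ 6 whose label is unmasked (pairs below the shortest evaluated range
carry no training signal; whether they were trained on is unstated —
`min_separation` is configurable).  SS loss is the summed 3-class
cross-entropy over unmasked residues; ASA loss is the RMSE over
unmasked residues with N = the unmasked count.  Probabilities are
clamped to [1e−7, 1 − 1e−7] inside the logs.  Losses are sums as
printed; a `normalize` option converts to per-protein means for
cross-length comparability.

Training uses ADAM (default lr 0.0005, standard moments) with one
protein per optimizer step.  MSAs deeper than 30,000 rows are
subsampled (query always kept — it defines the columns) and chains
longer than 200 residues are cropped to a uniformly-placed contiguous
window applied to the alignment and all labels, both re-drawn each
epoch and applied during training only; prediction always uses the
full alignment.  Validation loss is tracked per task and the best
epoch per task is kept, since contact and SS convergence differ.
Ensembling is the arithmetic mean of fold-model predictions (default
5 folds).

## Labels

Contacts: representative-atom (Cβ; Cα for glycine) distance strictly
below 8 Å; any pair involving a residue with a missing representative
atom is masked (NaN), and masked entries never contribute to losses or
metrics.  DSSP 8-state codes map H/G/I→helix, E/B→sheet, everything
else (T, S, blank) →coil — the CASP-literature convention; chain
breaks are masked.  Proteins with SS assigned for under 80% of
residues are rejected at dataset assembly.  ASA is regressed in
absolute Å²; only for three-state evaluation (B/M/E) is it divided by
the Tien et al. (2013) theoretical maximum per residue type, with
thresholds at 10% and 40% and boundary values assigned to M (closed
middle interval, fixed for determinism).

## Evaluation

Range bins on s = |i − j|: short 6–11, medium 12–23, long ≥ 24; s ≤ 5
is never evaluated.  Top-L/k precision (k = 10, 5, 2, 1) takes the
ceil(L/k) highest-probability unmasked pairs in the bin (ceil is our
choice; ties break to smaller separation then lexicographic pair, for
determinism) and reports TP/(TP+FP).  Metrics with an empty
denominator are reported as absent (None), not zero, to avoid biasing
averages; a bin with fewer candidates than the list size is scored on
all of them and flagged.  SS metrics are per-class recall/precision
and overall accuracy on argmax classes; ASA accuracy is computed after
three-state conversion of both sides.  Contact-type (HH/HS/SS) metrics
type each pair by the true SS of its residues (pairs touching coil are
untyped); the prediction set is the union of the per-bin top-L
selections (the original selection set is unstated; this is documented
and configurable).  The tertiary-structure hand-off mixes all ranges,
ranks by probability, truncates at 2L, and writes CASP RR lines
`i j 0 8 p` with 1-based i < j.

## Synthetic data

The generator emulates the co-evolution premise: spatially close
column pairs co-vary.  Per protein: (1) a compact self-avoiding 3-D
walk (bond 3.8 Å, clash radius 3.5 Å, a centripetal pull keeping the
chain globular; the chain alternates turny and extended segments of
4–8 residues) gives Cα positions; Cβ sits 1.5 Å off the local backbone
direction; the contact map is derived from this geometry *with the
same code used for real coordinates*, so labels and geometry cannot
disagree.  (2) From the contacting pairs with separation ≥ 6,
`n_contact_pairs` are planted: each gets a fixed random symbol
permutation σ, and every evolved homolog, with probability ρ
(`coupling`), redraws column i uniformly and sets column j = σ(i) —
exactly the pairwise frequency coupling that the covariance features
detect.  Elsewhere homologs mutate independently at `mutation_rate`
with a small (3%) gap-opening rate.  (3) A `noise_fraction` of the
depth is appended as uniform-random rows over all 21 symbols
(identity with the query ≈ 1/21) — the rows a weighting network
should learn to suppress.  (4) SS labels come from a geometric rule on
the realized walk — span |Cα(i+1) − Cα(i−1)| < 6.5 Å → helix-like,
> 7.0 Å with an extended nonlocal partner within 9 Å → sheet-like,
runs shorter than 3 → coil — with thresholds calibrated once to the
walk's own span distribution (on this geometry they yield roughly
13% helix, 17% sheet); ASA is a burial proxy (distance to centroid
scaled to [0, 200] Å²).  These proxies are meant to be *consistent and
learnable*, not physically accurate.

Defaults state the desk-scale world the package is exercised in: 200
proteins, L = 30, 50 evolved sequences, 12 planted pairs, ρ = 0.9,
noise fraction 0.5, mutation rate 0.3 (mid-range homolog divergence).
Everything is deterministic in the seed, per-protein seeds derive from
(suite seed, index), and suites regenerate bit-identically from their
manifest.

### What a green test does and does not establish

The synthetic world has a star phylogeny (all homologs are one
mutation step from the query), planted couplings that are *pair
permutations* rather than Potts-style energetics, geometric SS/ASA
proxies, and uniform noise.  Green tests establish that the machinery
is correct (features match counting oracles, gradients match finite
differences, metrics match hand arithmetic) and that the learning task
is solvable and graded in the coupling strength.  They do not
establish real-protein accuracy, robustness to realistic phylogenetic
correlation, or transfer of the weighting network to real
metagenomic noise.

## Numerical choices

* All computation is float32 for training, float64 where tests compare
  against central finite differences (step 1e−5/1e−6).
* The autodiff engine is a minimal tape over numpy (see
  `coevonet.nn.autodiff`); convolution is implemented as k² shifted
  matmuls, which is efficient for the 1×1 and 3×3 kernels used.
  Backward traversal is iterative — 60-layer graphs would overflow
  Python's recursion limit.
* BatchNorm with one protein per batch is instance normalization in
  effect; running statistics are tracked for evaluation mode.
* Micro-scale learning rate: the published 0.0005 is tuned to
  full-scale training (11k proteins, 128-channel trunks).  The desk-
  scale examples and acceptance runs use 0.002 for the micro-models
  (8 blocks, 32 channels, 200 proteins), selected as the largest rate
  that trains stably; 0.005 saturates the sigmoid head.  The default
  in `TrainConfig` remains 0.0005.
* Degenerate inputs: empty masked sums are 0; metrics on empty
  candidate sets are absent; an all-gap consensus column yields the
  gap code; sampling/cropping under the caps are no-ops.

### Desk-scale training behaves differently from full scale

Two effects, both measured by the test suite, separate the micro-models
from the full-scale recipe:

* **Uniform noise is benign shrinkage.**  Pure i.i.d. uniform noise
  rows have zero expected covariance; mixing them in shrinks the whole
  tensor smoothly and leaves the *ranking* of pairs by covariance
  essentially unchanged (top-L/5 precision of the raw statistic is flat
  in the noise-row weight).  The contact loss therefore gives the
  weighting MLP little or no incentive to suppress such rows at desk
  scale — for a trained micro-model the loss gradient actually prefers
  up-weighting them, a regularization effect.  Real non-homologous
  alignment hits carry structured correlations that *do* corrupt
  specific couplings; suppressing those is what full-scale weighting
  learns.  The synthetic world keeps the spec'd uniform-noise design
  and documents this divergence rather than engineering noise to make
  the test pass.
* **Isolated planted pairs fight the CNN's spatial prior.**  Planted
  couplings sit at single, scattered (i, j) pixels, while convolutions
  smooth over neighborhoods — a prior that pays off on real contact
  maps, where contacts cluster into helix ladders and sheet patterns.
  At desk scale the micro CNN reaches roughly 3× the no-skill density
  on held-out proteins within ten epochs, whereas the unsmoothed
  per-pixel covariance norm reaches ~10×: the residual trunk is
  optimization-bound here, not signal-bound.

## Known limitations

* One-hot encoding of a 30,000 × L alignment in memory is the
  covariance bottleneck (~500 MB float32 at L = 200); chunking over
  sequences would remove it but is not needed at desk scale.
* The multi-task heads pool pair maps to 256 features per residue;
  richer reductions (attention over the pair axis) are out of scope.
* The ASA loss shares the unweighted sum of the total loss; at micro
  scale it can dominate early training of the multitask variant.
* Uncertainty in the original description (PSSM "one-hot" remark, the
  weighting network's output activation, floor-vs-ceil in L/k) is
  resolved as documented above; each choice is localized and
  configurable where it matters.
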