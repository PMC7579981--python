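# Methods

`hetmda` predicts miRNA-disease associations from a three-layer
miRNA-protein-disease heterogeneous network. This note documents the model,
the numerical choices, the synthetic benchmark and the limits of what the
test suite demonstrates.

## The global heterogeneous network

The network is a symmetric block matrix over three typed node sets — miRNAs
(M), proteins (P) and diseases (D), in that global order:

    T = [[M,  B,  C ],
         [Bᵀ, P,  W ],
         [Cᵀ, Wᵀ, D ]]

`M`, `P` and `D` are intra-type similarity blocks with weights in [0, 1]
(Pearson correlation of expression profiles for miRNAs, interaction
confidence for proteins, phenotype similarity for diseases); `B` (miRNA
targets), `C` (miRNA-disease associations) and `W` (protein-disease
associations) are binary validated-association blocks. Intra-type diagonals
are forced to zero: the propagation model has no self-loops, and the
restart term of the random walk supplies self-mass. Similarity edges with
weight strictly below 0.5 are removed before feature extraction ("below" is
read strictly, so a weight of exactly 0.5 survives); the binary cross-type
blocks pass through the cut unchanged. Thresholding is recorded on the
network object and applying it twice is an error, which catches accidental
double processing; the cut itself is idempotent.

For miRNA similarity from expression, negative correlations are clipped to
zero (a negative co-expression edge has no meaning as a similarity weight)
and zero-variance profiles yield zero similarity with a warning rather than
NaNs.

## Diffusion features

Each node's diffusion profile is the stationary distribution of a random
walk with restart (RWR) seeded at that node. The adjacency is binarized
(any positive weight is an edge, so a step moves to a uniformly chosen
neighbour); a weighted variant is available behind a flag. The iteration is

    P ← (1 − α) · Tᵀ · P + α · P₀

with the transpose of the row-stochastic transition matrix, so that every
iterate is a probability distribution; on graphs with symmetric binary
adjacency this coincides with the untransposed form. Nodes without outgoing
edges (possible after thresholding) have their transition mass redirected
to the restart vector, which keeps the iterate stochastic and makes an
isolated seed a fixed point.

Parameters: restart probability `alpha = 0.5` (the conventional choice for
RWR-based association scoring), L1 convergence tolerance `1e-6`, at most
1000 iterations; non-convergence is reported on the profile object, never
silently ignored. The iterative solver agrees with a direct linear solve of
the fixed point, `P = α (I − (1−α) Tᵀ)⁻¹ P₀`, to well below 1e-6 on the
oracle suite; the iteration is kept because it scales to networks where the
dense solve does not.

The N×N profile matrix is compressed to k dimensions per node by truncated
SVD. The embedding is `U_k Σ_k` — left singular vectors scaled by singular
values — so inner products of embeddings converge to inner products of
profile rows as k grows; bare `U_k` would discard the relative importance
of components. Singular-vector signs are canonicalized (largest-magnitude
entry of each component made positive), making the embedding deterministic.
`k = 300` is the full-scale default; requesting more components than the
numerical rank returns rank columns with a warning. At synthetic-benchmark
scale (190 nodes) the package uses `k = 50`, comfortably below rank while
keeping the pair feature length proportionate to the sample size.

## HeteSim metapath features

A metapath is a node-type sequence from M to D; the canonical feature uses
all 39 sequences of two to four edges, ordered by length and then
lexicographically with M < P < D (MMD, MPD, MDD, MMMD, …, MDDDD). For a
concrete (miRNA, disease) pair and a metapath, HeteSim splits the path at
its middle, computes the reachable probability matrix (product of
row-normalized binarized per-step transition matrices) for the left half
from the miRNA and for the reversed right half from the disease, and scores
the pair as the cosine of the two midpoint-reachability vectors. Scores are
therefore in [0, 1]; a pair with no metapath instance has a zero midpoint
vector and scores 0 by convention.

Odd-length paths have two candidate midpoints. When both midpoint types
agree, the two half-path reachability matrices are averaged before the
cosine — the straightforward reading of the averaging step. When they
differ (e.g. M-M-P-D, with midpoints of type M and P) the matrices have
incompatible shapes, so the score is computed per decomposition and the two
scores are averaged. This keeps the measure defined on all 39 paths while
agreeing with the matrix-averaged form wherever that form is well defined.

The batch computation works block-wise with sparse matrix products and
row-normalized cosines; it is verified against both a per-pair evaluation
and an independent brute-force oracle that enumerates every node-level
instantiation of a metapath on networks of up to 12 nodes (agreement to
1e-8).

## Pair features and datasets

A pair's feature vector is `[miRNA embedding (k) | disease embedding (k) |
39 HeteSim scores]` — 639 values at the full-scale `k = 300`. The component
order is fixed and part of the on-disk format. Negative pairs are sampled
uniformly without replacement from all pairs that are not known
associations, `ratio` times the positive count, with the seed recorded in
the table's provenance; negatives are fixed once per dataset rather than
resampled per fold.

## Classifier and evaluation protocol

The classifier is gradient-boosted trees (XGBoost) with learning rate 0.15,
650 boosting rounds and maximum depth 4; all other hyperparameters stay at
library defaults, the seed is fixed and recorded. Random forest, RBF-SVM
and sklearn gradient boosting are available through the same hook for
comparison runs.

Cross-validation splits positives and negatives separately into k folds:
k−1 folds of ⌊n/k⌋ and a last fold holding the remainder (11824 positives
give nine folds of 1182 and a tenth of 1186). For each fold, the validation
positives' association edges are deleted from the C block, **all** features
(diffusion embeddings and HeteSim scores) are recomputed on the modified
network, the classifier is fitted on the remaining folds and scored on the
held-out fold. This prevents a validation pair's own label edge from
leaking into its features. Training positives keep their edges — that is
the protocol's stated form, and its consequences are discussed below.
Precision, recall, accuracy and F-score use a 0.5 operating point (the
protocol does not fix one; 0.5 is the natural choice for calibrated
probabilities); degenerate denominators report 0 with a warning. AUC is the
concordance probability with ties counted one half, computed per fold and
averaged.

## The synthetic benchmark

The generator produces seeded networks with planted associations so that
every stage is testable without external data. Its structure mirrors the
traits of curated association data that matter to this pipeline:

* **Protein modules with cores.** Proteins are partitioned into 32 modules,
  each with a core of up to 4 proteins (a complex). Every miRNA acts
  through one module. A *wired* positive adds miRNA→core target edges and
  core→disease association edges, and strengthens within-module
  protein-protein weights into [0.5, 1) so the wiring survives the edge
  threshold. The wiring — unlike the association edge itself — is never
  removed by the CV protocol, so it is the recoverable signal: a held-out
  pair is still connected through M-P-D and M-P-P-D routes.
* **Degree mixture.** Positives come from three populations: eight *triad
  groups* (four miRNAs sharing one disease, plus one private disease each —
  miRNA families), two hub miRNAs and two hub diseases with twelve
  associations apiece (well-studied nodes), and a uniform remainder.
* **`signal`** is the probability that a planted pair receives module
  wiring. It gates only the protein-layer signal; the association structure
  is identical at all signal levels.

The degree mixture is not decorative. Under the protocol, training
positives retain their own association edges, and several metapath features
that traverse the C block (M-D-M-D and M-P-M-D most prominently) contain a
self-path term that effectively encodes "this pair's edge exists". On a
small uniform benchmark those features separate the training set perfectly,
gradient boosting then stops learning anything else, and held-out pairs —
whose edges are removed — are scored at chance. Real association data does
not behave this way because association degrees are heterogeneous: for
well-connected nodes the self term is one contribution among many. The hub
positives reproduce exactly that dilution, and the triad groups contribute
the complementary half: a group mate's private disease forms a
non-associated pair whose chain profile resembles a true pair's, so
label-adjacent features stop being clean separators of the training set.
Those confounder chains are one-sided by construction — once a pair's own
edge is held out, the association graph carries no trace of it — which is
what keeps the no-signal calibration honest: at `signal = 0` the 10-fold
AUC sits near chance (≈0.55–0.65 across seeds, the residue being the
hub-popularity prior that real databases share), while at `signal = 1` the
combined features recover held-out associations at AUC ≈ 0.8, roughly 0.33
above a shuffled-label control.

What the passing benchmark does and does not show: it demonstrates that the
pipeline extracts protein-mediated association signal under the
leakage-controlled protocol and that the two feature families are
complementary at this scale. It does not emulate realistic degree
distributions fitted to real interactomes, disease ontologies, or the
four-order-of-magnitude larger pair space of the full corpus, so absolute
AUC values are not comparable to full-scale results.

## Problem sizes used in tests and the acceptance script

The benchmark condition is 50 miRNAs, 100 proteins, 40 diseases and 120
planted positives, evaluated with full 10-fold leakage-controlled CV over 3
seeds (5 for the no-signal calibration), with `svd_k = 50` and a 1:1
negative ratio. Oracle-equivalence suites use 20 random networks of at most
12 nodes. Structural constants (pair counts, negative-set sizes, fold
sizes) are computed at the full corpus dimensions, which costs only
sampling and arithmetic.

## Known limitations

* The odd-metapath averaging convention is one defensible reading of an
  underdetermined step; scores for paths with mixed midpoint types would
  differ under, e.g., zero-padded matrix averaging.
* The protocol's asymmetry (training positives keep their edges) means
  label-adjacent features dominate what the booster learns; on data without
  degree heterogeneity this degrades held-out ranking sharply. This is a
  property of the protocol, reproduced faithfully, not of the
  implementation.
* Dense N×N diffusion profiles and a dense SVD are used throughout; this is
  exact and fine up to a few thousand nodes but does not scale to the full
  25,811-node corpus without landmark or randomized variants, which are out
  of scope.
* `sample_negatives` treats all non-associated pairs as negatives; some are
  unknown true associations, which is inherent to the problem setting.
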