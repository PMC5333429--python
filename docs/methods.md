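# Methods

This note documents the models and procedures implemented in `gsompul`,
the parameters that matter, and the design choices made where the
literature leaves the design open.

## Positive-unlabeled setting

Known drug–drug interactions are positives; every other unordered drug
pair is unlabeled. The pair universe over `n` drugs is the set of
`n(n−1)/2` canonical (lexicographically sorted) pairs; all modules join on
this key. Drugs absent from any feature source are dropped (with a logged
warning) before pair enumeration, so the universe is built on the drugs
common to all sources.

## Similarity feature representations

Let `f(d)` be a drug's binary profile in one source.

* **SFR1** concatenates one Jaccard index per source. The Jaccard of two
  all-zero profiles is defined as 0: absence of shared evidence is not
  similarity. SFR1 values already lie in [0,1] and are not rescaled.
* **SFR2** concatenates element-wise averages; on binary input entries are
  0, ½ or 1, so it records *which* features overlap. Two pairs with equal
  intersection/union counts are SFR1-identical but generally
  SFR2-distinct; this granularity is why both representations are run and
  their negative sets intersected.
* **Variance projection.** SFR2 is sparse and high-dimensional, so a PCA
  retaining the smallest number of components whose cumulative explained
  variance reaches the configured fraction (default 0.90) is fitted on all
  available pair vectors (transductive; configurable). Determinism across
  platforms is enforced by a sign convention: each component's
  largest-magnitude entry is made positive.

## Growing self-organizing map

The GSOM starts from a 2×2 lattice whose weights are initialized on
distinct randomly chosen input rows (so duplicate-free data starts with
zero quantization error on those rows). Each presented input updates its
best-matching unit (ties broken toward the smallest node id) and all
nodes under a Gaussian lattice kernel. The BMU accumulates its squared
quantization error; when that exceeds `GT = −D ln(SF)`:

* a boundary winner grows nodes into all free orthogonal positions —
  new weights extrapolate through the winner from the opposite neighbor
  when one exists, otherwise interpolate toward the node beyond the free
  slot, otherwise extrapolate from any lattice neighbor; new nodes start
  with zero accumulated error;
* an interior winner distributes its error to its four lattice neighbors
  scaled by the error-distribution factor (default 0.5);
* in both cases the winner's error resets to `GT/2`.

Training is two-phase: a growing phase (default 20 epochs, learning rate
decaying linearly from 0.3, Gaussian radius shrinking 2.0 → 0.5) and a
smoothing phase with growth disabled (default 10 epochs, rate from 0.05,
radius 0.5). These schedule values are package choices — the method's own
literature fixes only the growth threshold — and are all exposed in
`GSOMConfig`; on the data sizes this package targets, maps converge well
within these epoch counts. A `max_nodes` cap (default 1200) bounds the
degenerate `SF = 1` case where the threshold is zero and every sample
would trigger growth. Presentation order is reshuffled per epoch from the
config seed; identical data, config and seed give bit-identical maps.
Squared Euclidean distance is used throughout, consistent with the
within-cluster diagnostic `AWCD = Σ inputs ‖x − w_winner‖² / #nodes`.
After training, inputs are assigned to their final BMU and empty nodes
are pruned, so every surviving node has at least one member.

## Node profiling and consensus negatives

A node with positive proportion 0 is *negative*, 1 is *positive*,
anything between is *ambiguous*; nodes below `min_node_size` (default 2)
are *excluded* — single-member "negative" nodes are the easiest way to
manufacture false negatives. Inferred negatives are the members of
negative nodes; running both representations and intersecting their
negative sets gives the consensus set used for training (a
single-representation mode exists behind the provenance tag). Unlabeled
members of ambiguous nodes form the prediction universe; the pipeline
takes the union of both maps' universes minus the consensus negatives,
the permissive reading of combining two maps.

## Classifier ensemble

Balanced training sets pair the smaller class in full with an equal-size
uniform subsample of the larger class, independently per set with
deterministic sub-seeds. (In the intended regime inferred negatives are
scarce relative to positives; the generalization to the opposite case
subsamples negatives instead, and an optional per-class cap — 600 in the
benchmark experiments, close to the set sizes the regime implies — bounds
SVM cost.) Each set trains an SVC with an inhomogeneous polynomial kernel
(degree 2 by default; C defaults 10⁻² for SFR1 and 10⁻³ for projected
SFR2). Platt's sigmoid is fitted by L-BFGS on the smoothed-target
Bernoulli likelihood of 3-fold cross-validated decision values —
calibrating on in-sample scores is optimistically biased — with targets
`(N₊+1)/(N₊+2)` and `1/(N₋+2)`; tiny sets (fewer than twice the fold
count per class) fall back to in-sample scores. The ensemble averages all
models' posteriors and thresholds the mean (default 0.5; a
high-confidence preset of 0.995 is exposed for calling only the strongest
predictions).

Comparators: the *baseline* draws its negatives uniformly from the
unlabeled pool (as many as there are positives), then trains the same
ensemble; a one-class SVM trained on positives only is provided for
reference.

## Evaluation conventions

Precision, recall and F1 use the zero-denominator conventions P = R = 0
and F1 = 0 when undefined. Cross-validation is stratified (balanced sets
make that the natural reading), metrics averaged per fold and then across
balanced sets. The holdout split is stratified with exact train-fraction
sizing.

## CYP annotation

An ambiguous node inherits the union of the isoform sets of its known
positive members; a non-empty union makes it CYP-Dependent. Negative
nodes are CYP-Independent. A predicted pair unions its node labels across
the two maps (OR on dependence). Pairs falling in excluded or
purely-positive nodes of one map contribute no CYP evidence from that
map. Isoform names outside {CYP1A2, CYP2C9, CYP2C19, CYP2D6, CYP3A4} are
rejected unless explicitly allowed.

## Synthetic benchmark

The generator emulates the structure the method exploits: drugs are
assigned evenly to latent groups; each source gives each group a block of
characteristic features drawn at `within_group_feature_prob` (default
0.4) against a background rate (default 0.08), so within-group drug pairs
have visibly higher Jaccard similarity — asserted as a generation-time
diagnostic. True interactions default to the shared-group rule perturbed
by a 2 % label flip (a noiseless rule would make the task trivially
separable); an overlap-threshold rule is available. A fraction `upp`
(default 0.3) of true interactions is masked into the unlabeled pool.
CYP isoforms are attached to a random subset of observed positives with
configurable per-isoform weights — purely synthetic, never claimed
biological.

What passing on this benchmark shows: that clustering-based negative
inference beats uniform sampling *when similar pairs share interaction
status and a substantial minority of positives is hidden*. What it does
not show: performance on real interaction data, whose feature marginals,
degree distributions and interaction mechanisms are far richer than
block-structured Bernoulli matrices.

The default experiment scale is 200 drugs (19 900 pairs), six groups,
four sources of dimensions 40/30/30/50, chosen as the package's standard
desk-scale benchmark; end-to-end comparisons use five generator seeds,
and the acceptance script uses three.

## Numerical and degenerate-input choices

* BMU ties resolve to the smallest node id; duplicate initial weights are
  harmless for the same reason.
* Platt evaluation is overflow-safe and clipped into (10⁻¹², 1−10⁻¹²).
* Jaccard of empty unions is 0; constant feature tables reject PCA
  fitting; single-class training sets reject SVM and Platt fits; empty
  maps reject BMU/AWCD queries.
* All sampling (lattice init, epoch shuffles, balanced subsets, baseline
  draws, generator) flows from explicit integer seeds; sub-seeds are
  spawned deterministically and kept below 2³¹.

## Known limitations

* The GSOM is the canonical single-threaded formulation; no batch or
  hierarchical variants, and no interactive map analytics beyond a static
  lattice plot.
* Map selection across spread factors is left to the user (the sweep
  utility reports node counts and AWCD); no automatic selection rule is
  claimed.
* The variance projection is fitted transductively by default; fitting on
  training pairs only is a config choice the caller must make.
* Negative inference quality degrades as the unlabeled-positive
  proportion grows; the benchmark invariants target UPP ≤ 0.5.
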