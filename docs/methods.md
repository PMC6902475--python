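# Methods

## Problem and model

The package scores unordered sets of ≥ 2 drugs for combination
effectiveness. Its central assumption is a network-pharmacology one: an
effective combination perturbs a *coherent neighborhood* of the protein
network — the drugs' targets sit close together or share downstream
context — whereas an arbitrary drug pair scatters its influence. A random
walk with restart (RWR) on a two-layer drug–protein network turns that
intuition into a feature vector: seeding the walk at the combination's
drugs and targets and iterating

P(t+1) = (1 − α) T′ P(t) + α P₀

to its fixed point yields a probability distribution over all n drugs and
m proteins that concentrates wherever the combination's joint influence
accumulates. A gradient-boosted tree ensemble then classifies these
vectors.

## Network construction

**Associations.** Drug–protein confidences arrive on a 0–1000 scale and are
divided by 1000; they are used as continuous weights throughout (never
binarized), so weighted degrees reduce to count degrees in the binary case.
Before any network step, each drug's associations are filtered: drop scores
below 0.5, keep the top 3 of the survivors (all of them if fewer). The
filter is idempotent and ties at the k-th score break by protein input
order.

**Drug similarity.** Jaccard over binary substructure fingerprints, fused
with the two-step resource-allocation projection through the association
bipartite graph. The projection is directionally asymmetric (drug i may
route a different fraction of its resource to j than vice versa);
`bipartite_projection_flow` exposes the directed matrix, whose columns over
associated drugs each sum to 1 with binary associations, while the fused
similarity uses the symmetrized average — similarity matrices in this
package are symmetric by contract.

**Protein similarity.** Normalized Smith–Waterman, SW(i,j)/√(SW(i,i)·SW(j,j)),
under BLOSUM62 with affine gaps (open 10, extend 4; a length-L gap costs
open + (L−1)·extend). These scoring choices are the package's defaults, not
values asserted by any upstream source, and are configurable via
`AlignmentParams`. GO semantic similarity uses Wang's graph-based measure:
each term's ancestors receive semantic contributions decaying by relation
weight (is_a 0.8, part_of 0.6) along the best path, pairs of terms are
scored by their shared ancestors' contributions, term sets aggregate by
best-match average, and namespaces (BP/MF/CC where annotated) are computed
separately then averaged over the namespaces in which *both* proteins carry
annotations. Both the term measure and aggregation are pluggable; these
defaults mirror common practice in semantic-similarity tooling.

**Fusion.** Probability disjunction s = 1 − (1 − s₁)(1 − s₂): treat the two
measures as independent "evidence of relatedness" events. The result
dominates both inputs and is monotone in each.

**Transition matrix.** Within-layer blocks are row-normalized similarities
scaled by (1 − λ) for nodes that have cross-layer associations (unscaled
otherwise); cross-layer blocks are row-normalized association weights
scaled by λ. Numerical/degenerate-input policies, chosen where the
construction is otherwise underdetermined:

- within-layer diagonals are zeroed before normalization — self-loops only
  slow mixing;
- a node with associations but zero off-diagonal similarity mass routes
  *all* its mass through associations (effective λ = 1 for that row,
  logged) — the (1 − λ) share is otherwise a 0/0;
- a fully isolated node keeps an all-zero row and is flagged dangling; at
  propagation time any probability sitting on dangling rows is re-seeded
  through P₀, so each iterate sums to 1 exactly;
- T stores from→to transitions row-stochastically; the iteration uses its
  transpose.

## Propagation

P₀ places η on the combination's drugs (equal split) and 1 − η on the union
of their filtered targets (equal split); a combination with no surviving
target puts full mass on the drug layer (logged). Convergence is declared
when the L1 difference of successive iterates falls below 1e-10 — L1 is the
natural norm for probability vectors — with a 10,000-iteration cap that, at
α ≥ 0.1, is never approached (the residual contracts at least geometrically
with ratio 1 − α). Defaults λ = 0.7, α = 0.2, η = 0.9 follow the tuned
operating point; η = 0.5 is a documented alternative from the same source's
methods text. A dense direct solve of the same fixed point
(`closed_form_stationary`, guarded at 2000 nodes) serves as an independent
oracle in the test suite; iterative and direct solutions agree to < 1e-8 L1
on random networks.

The feature vector is the full (n+m)-dimensional distribution, not the
protein block alone, matching the dimensionality the method reports at full
scale (features = drugs + proteins).

## Benchmark assembly

Positives come from a curated combination list; negatives are drawn
uniformly at random from unordered drug pairs of the universe, excluding
every positive *as a set*, until the classes balance — drawing is
rejection-based with an exhaustive fallback and raises before emitting
anything if the request is infeasible. Universe expansion
(`expand_drug_universe`) adds each seed drug's top-k neighbors by a scored
pair table; k defaults to 3, with k = 10 selectable (the two values both
appear in the method's source description; neither is derivable from the
other, so both remain configuration).

## Classifier and evaluation

The ensemble is stagewise additive logistic-loss boosting with per-tree row
subsampling, backed by scikit-learn's `GradientBoostingClassifier` — the
engine satisfies the loss/ensemble contract (monotone training loss in the
stage count, checked in tests), while this package owns the configuration,
tuning and evaluation surface. Defaults K = 300 trees of depth 13 are the
full-scale tuned values; learning rate 0.1 and subsample 0.8 fill the two
hyperparameters the tuning left unstated, and both sit in the default grid.
`grid_search` maximizes mean CV AUC with ties broken toward fewer trees,
then smaller depth.

Evaluation is stratified 10-fold cross-validation (stratification keeps
both classes in every fold; fold assignment is seeded), averaging per-fold
precision, recall, F-measure, MCC (threshold 0.5 — confusion metrics need a
cutoff and the scores are probabilities) and threshold-free AUC. AUC is
computed as the Mann–Whitney rank statistic with ties credited ½, which
equals the cutoff-sweep construction; the test suite verifies that equality
against two independent oracles. Zero-denominator metrics are defined as 0
and flagged. `cross_validate` accepts any `(X, y) → scorer` factory, so
alternative classifiers can be evaluated under the identical protocol
without re-implementing them here.

## Synthetic universe and planted signal

The generator emulates the five real inputs at desk scale. Proteins are
partitioned into modules; module members share a mutated copy of a common
core sequence (150 aa, 10% point mutations) and draw GO leaves from
module-specific branches of a generated two-namespace DAG (mixed
is_a/part_of edges). Drugs belong to modules and share module-specific
fingerprint bit blocks over 880 bits. Associations link drugs to their own
module's proteins with confidence ~ U(0.5, 0.9) at density 0.3, plus
uniform cross-module noise mostly below the 0.5 filter.

The combination signal is *topological*: modules are paired, each pair owns
a small pool of bridge proteins, and every drug carries high-confidence
(≥ 0.85, filter-surviving) associations to two bridges from its pair's
pool. Effective combinations are cross-module pairs sharing at least one
bridge; controls have the same module-pair composition but disjoint
bridges. Because both classes have identical module structure, fingerprints
and GO-term unions are class-balanced by construction — only the shared
network neighborhood separates them, which is precisely the mechanism the
propagation features claim to capture, and labels never leak into features.

Two generator choices matter for signal integrity and were set at design
time. First, bridge proteins are *individually* distinct (own random
sequence, own unique GO leaf under the pair's bridge branch): if bridges
were near-copies of each other, protein-layer diffusion would spread the
shared-bridge probability uniformly over the pool and erase the planted
contrast. Second, the bridge pool is small (4 per module pair at the
default `bridge_fraction` = 0.1): each bridging neighborhood then recurs
across enough positive samples (~25 of 100) for axis-aligned trees to learn
its coordinate; with larger pools the univariate signal remains nearly
perfect (max protein-coordinate mass separates the classes with AUC ≈ 1.0)
but 100 positives spread too thinly over coordinates for a tree ensemble
trained on 180 rows. This is the effect-size calibration that keeps the
end-to-end study informative at small scale.

What the synthetic universe does **not** reproduce: real STITCH confidence
distributions, realistic chemistry or PaDEL fingerprint statistics, GO's
depth and term co-occurrence structure, or the scale (thousands of drugs,
6k+ network nodes) of a real benchmark. Passing the end-to-end study
demonstrates that the pipeline's mechanics recover a planted
network-topological signal that raw ontology unions miss; it does not
certify performance on real pharmacological data.

## Scaled end-to-end study

The study conditions are 150 drugs, 120 proteins, 6 modules, 100 positive +
100 negative combinations, 10-fold CV. The classifier for this study is
K = 200 trees of depth 3 (lr 0.1, subsample 0.8): the full-scale tuned
depth-13 configuration targets an order-of-magnitude more training rows and
gains nothing here (measured equivalent within noise), so the smaller
configuration was fixed once as the study condition. The label-permutation
control reports the mean CV AUC over three independent label permutations:
a single permutation's CV AUC at n = 200 has a sampling sd of ≈ 0.045,
so averaging three tightens the null estimate without changing what is
estimated. Typical results (seeds 0–5): RWR-feature AUC 0.96–0.99,
raw fingerprint/GO-union baseline 0.72–0.82, permuted control 0.44–0.56.

## Known limitations

- The bipartite projection symmetrization halves the directed asymmetry;
  workflows needing the directed flow should use
  `bipartite_projection_flow` directly.
- Dense (n+m)² transition matrices are practical to a few thousand nodes;
  beyond that a sparse backend would be needed.
- Sequence similarity is all-pairs Smith–Waterman (O(n² · L²)); for
  hundreds of proteins this is seconds-to-minutes, for tens of thousands it
  is the bottleneck.
- GO semantic similarity caches per-term ancestor contributions but scores
  term-set pairs exhaustively; very heavily annotated proteins would slow
  it.
- The SMILES→fingerprint path (rdkit Morgan bits folded to the configured
  length) is a convenience, not the 880-bit substructure scheme the curated
  inputs assume; precomputed fingerprints are the canonical path.
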