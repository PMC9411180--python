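# Methods

This note records the models implemented in `skullnet`, the conventions and
defaults chosen where the underlying methods admit alternatives, what the
synthetic generators do and do not emulate, and the package's known
limitations.

## Networks and validation

A skull network is an unweighted, undirected graph on labelled bones with a
symmetric 0/1 adjacency matrix and zero diagonal. Isolated bones (degree 0)
are valid nodes — some squamates have a jugal that articulates with nothing —
and every parameter below is defined in their presence. Validation happens at
construction: asymmetry is reported with the offending bone pair, and
non-binary entries are rejected (articulations are present/absent; the
package deliberately has no weighted variant).

Bilateral symmetry is checked against a laterality map (left/right bone
pairs plus midline bones): the skull passes when the left↔right relabeling
is a graph automorphism, and the report lists every articulation whose
mirror image is missing. By default laterality is inferred from `_L`/`_R`
label suffixes; an explicit map overrides this.

## Whole-network parameters

- **Density** `D = 2K/(N(N−1))`. Exact; no conventions.
- **Mean clustering** `C`: the average of local clustering coefficients.
  Bones with fewer than two neighbours have an undefined local coefficient
  and are *excluded* from the average by default (`low_degree="exclude"`),
  which matches the behaviour of the graph library ecosystem this analysis
  family is built on; `low_degree="zero"` counts them as zero instead. The
  choice shifts C downward by a roughly constant factor and does not affect
  orderings strongly, but published values are only comparable under one
  convention.
- **Mean shortest path** `L`: averaged over unordered bone pairs with a
  finite path; cross-component pairs are excluded. This is forced by the
  data: networks with isolated bones still need a finite L.
- **Heterogeneity** `H = sd(k)/mean(k)` with the sample (n−1) standard
  deviation by default (`sd="population"` available) and isolated bones
  included — an isolated bone is real anatomical imbalance and raises H.
- **Parcellation** `P = 1 − Σ (Nᵢ/N)²` over communities from Newman's
  leading-eigenvector algorithm, implemented in-package: recursive bisection
  along the sign pattern of the leading eigenvector of the (generalized)
  modularity matrix, stopping when the leading eigenvalue is non-positive or
  the split does not increase Q (tolerance 1e-10). Determinism: the
  eigenvector's global sign is anchored on its largest-magnitude entry, and
  zero entries join the positive side. Each degree-0 bone forms its own
  singleton community, the reason this algorithm is used rather than
  spin-glass methods that cannot place isolates. P is 0 for one community
  and at most 1 − 1/N.

## GTOM, UPGMA and module detection

The generalized topological overlap of order m scores two bones by their
shared m-step neighbourhoods: for m = 1,
`t_ij = (|shared neighbours| + a_ij) / (min(k_i, k_j) + 1 − a_ij)`, and for
m > 1 the same formula on m-step neighbourhoods. The default is m = 1, the
base case of the measure and the common default of the scripts this analysis
family derives from; m is exposed everywhere (`--gtom-steps`). Pairs of
isolated bones get overlap 0, hence distance 1: isolates join the dendrogram
last and surface as their own modules.

UPGMA (average linkage) is implemented in-package so that merge tie-breaking
is deterministic and documented: among equal-distance candidates the pair
whose combined sorted member-label tuple is lexicographically smallest
merges first. This matters for bilaterally symmetric skulls, where left and
right replicas produce exactly tied merges; the package resolves them
reproducibly rather than by floating-point accident, which is also how the
left/right asymmetries seen in reconstructed modules of symmetric skulls
should be read: an artefact of tie order, not anatomy. The implementation is
cross-checked against scipy's average-linkage cophenetic matrix to 1e-10.

**Q-modules.** Newman–Girvan modularity `Q = Σₛ (e_ss − a_s²)` is computed
on the *original binary adjacency* (not GTOM weights) for the partition
induced by every dendrogram cut k = 1..N; the arg-max cut is the module
partition, with ties broken toward fewer modules. The full (k, Q) profile is
returned so consumers can inspect secondary optima.

**S-modules.** Every dendrogram cluster of size ≥ 2 yields two samples —
per-bone counts of within-cluster and outside-cluster articulations — tested
one-sided (internal > external) with a Mann–Whitney U test. For combined
sample sizes up to 20 the p-value is the exact permutation null, enumerated
by a dynamic program over rank sums; this is valid with tied counts (the
null conditions on the observed values), which matter here because
articulation counts are small integers. Larger clusters use the normal
approximation with tie and continuity corrections. Raw p-values are reported
in tiers (p < 0.001, < 0.01, < 0.05) without multiple-testing correction,
matching the reporting convention of the AnNA literature; the root cluster
has no outside and is flagged degenerate.

*Limitation:* S-module p-values are calibrated for clusters chosen
independently of the network's edges (for such clusters the test is
conservative, as the internal sample has at most as many potential
connections as the external one). Clusters proposed by the dendrogram of the
same network are selected *because* they look module-like, so their raw
p-values overstate evidence at small α. Tiers should be read as descriptive
annotation of the dendrogram, not as family-wise controlled inference.

## Topospace

PCA operates on the correlation matrix (the seven parameters live on
different scales), via eigen-decomposition of the correlation of
standardized columns; component signs are fixed by making each component's
largest-magnitude loading positive. Variance fractions use all seven
eigenvalues and sum to 100%.

Phylogenetic PCA follows the Brownian-motion GLS formulation: with C the
matrix of shared root-to-MRCA path lengths, the ancestral mean is
`a = (1ᵀC⁻¹1)⁻¹1ᵀC⁻¹X`, the evolutionary covariance
`(X−1a)ᵀC⁻¹(X−1a)/(n−1)` is rescaled to a correlation matrix and
eigen-decomposed, and scores are the centred, sd-scaled data projected on
the eigenvectors. On a star tree with unit branch lengths this reduces
exactly to the ordinary correlation PCA (asserted numerically). Taxa are
matched to tree tips through a synonym map (congener substitution or
`drop`), with unmatched tips pruned; two taxa mapping to one tip is an
error, not a warning.

Convex hulls are 2-D on user-chosen score axes (components 1–2 by default,
where interpretation concentrates); groups with fewer than three points or
collinear points are flagged degenerate with area 0. Intersection areas come
from exact polygon clipping.

## Group tests

PERMANOVA uses Anderson's pseudo-F from the Euclidean distance matrix of the
score rows, `F = (SS_between/(a−1))/(SS_within/(n−a))` with sums of squares
from pairwise squared distances, free (unrestricted) label permutations from
a seeded generator, and `p = (count+1)/(n_perm+1)` (10 000 permutations by
default). By default the test runs on the full score matrix: for a full-rank
PCA this equals testing the standardized parameters themselves, which avoids
an arbitrary axis cutoff; restricting to leading components is a caller-side
row/column selection. Pairwise PERMANOVA runs one test per unordered
category pair on that pair's rows. F is permutation-invariant; only p
carries Monte-Carlo noise.

Size classes use two thresholds on snout–occiput skull length with an
explicit `ambiguous` class for the gap between them; the defaults
(≤ 11.74 mm miniaturized, ≥ 14.05 mm non-miniaturized) are the break in the
observed squamate length distribution, and `find_distribution_break`
recomputes such thresholds as the endpoints of the largest inter-value gap
exceeding a minimum width (1 mm by default, the creep rate below the break).

## Synthetic data

The skull-network generator emulates the structural features the analysis
assumes: bilateral symmetry (paired `_L`/`_R` bones plus midline bones),
planted modules of differing within/between connection density, and
optional isolated bones. Sampling is by mirror-orbit: the left↔right
relabeling partitions unordered bone pairs into orbits of one or two pairs,
and a single Bernoulli draw per orbit (p_in within a planted module, p_out
between) sets all its edges, so symmetry is exact by construction while
every bone pair keeps its nominal marginal edge probability. Planted module
labels are mirror-consistent (both members of a pair share a module).
Defaults — 14 bone pairs, 5 midline bones, 4 modules, ≈ 33 bones — sit in
the 30–57 bone range of real squamate skulls. What the generator does *not*
emulate: anatomical constraints (planarity-like contact geometry, the
specific hub role of parietal/parabasisphenoid), degree sequences of real
skulls, or ontogenetic fusion; recovery results on synthetic networks
therefore demonstrate the pipeline's correctness, not field performance on
real anatomies.

Trees are pure-birth (Yule): exponential waiting times with rate λk on k
lineages, all tips extended to the present (ultrametric); mean root height
matches the analytic Σ_{k=2..n} 1/(λk). Trait tables are multivariate normal
with covariance σ²ⱼ·C per variable plus additive per-category offsets — the
exact model under which the pPCA corrects and the PERMANOVA separates
groups; σ² → 0 collapses tips onto their group means.

The fixture suite (`make_fixture_suite`, also `skullnet simulate`) is
byte-deterministic per seed and spans three planted-module regimes chosen to
cover easy (p_in = 0.9, p_out = 0.02; ARI ≈ 1), medium (0.6/0.15) and hard
(0.3/0.25; near-chance) recovery.

## Numerical choices and problem sizes

- Eigen tolerance 1e-10 for "non-positive eigenvalue" and "no Q increase" in
  community detection; eigenvalues of correlation matrices clipped at 0.
- UPGMA and dendrogram heights are exact Lance–Williams averages; height
  monotonicity is asserted with 1e-12 slack.
- PERMANOVA's permutation comparison uses `F_perm ≥ F_obs − 1e-12` so exact
  ties (permutations reproducing the group split) count toward p.
- Simulation sizes in the test suite and acceptance script — 50 seeds for
  module recovery, 500 null replicates at 999 permutations for PERMANOVA
  calibration, 250 networks for S-module calibration, 1000 trees for the
  Yule height check — were chosen to keep Monte-Carlo error comfortably
  below the asserted margins while running in seconds on one core.

## Known limitations

- Scoring articulations from specimens is out of scope: the package starts
  at the adjacency matrix and treats every `1` identically (it cannot
  distinguish sutural from ligament-mediated connections).
- C, L, H conventions are configurable but defaults must match between
  datasets for comparability; published tables rarely state them.
- The GTOM order used by any given published dendrogram may differ from the
  default m = 1; module composition is usually robust, merge heights are not.
- The leading-eigenvector algorithm is a greedy bisection heuristic; on
  graphs whose optimal partition is not reachable by recursive bisection it
  can return a lower-Q partition than exhaustive search.
- PERMANOVA assumes exchangeability under the null; with strong phylogenetic
  signal in the scores, free permutations can overstate significance —
  running it on pPCA scores (as the workflow does when a tree is supplied)
  mitigates but does not eliminate this.
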