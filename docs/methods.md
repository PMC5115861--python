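# Methods

This note documents the models, conventions and numerical choices behind
`phylosym`, in the order data flows through the pipeline.

## Preprocessing

**Taxon filtering** removes OTUs whose semicolon-delimited lineage contains
any of a set of case-insensitive substrings (defaults: `chloroplast`,
`unassigned`, `wolbachia` — organellar reads, unclassifiable sequences and
intracellular endosymbionts that would otherwise swamp host-associated
signal). OTUs with no taxonomy at all are treated as matching `unassigned`.

**Rarefaction** subsamples each sample *without replacement* to a common
depth (multivariate hypergeometric per sample), so every retained column
sums exactly to the target depth. The default depth is the smallest sample
sum of the table at hand. Sampling without replacement — rather than
multinomial resampling — is what "rarefaction" means in the QIIME lineage
of tools this pipeline's conventions follow.

**Alpha diversity**: Shannon entropy in log base 2 (bits; natural log via
the `base` argument) and bias-corrected Chao1,
`S_obs + F1(F1−1) / (2(F2+1))`, which is defined even when no doubletons
are observed.

**Collapsing** sums rows by lineage prefix truncated at a rank
(kingdom…genus; OTUs whose lineage does not reach the rank pool into an
`unclassified-at-<rank>` row), or sums columns by host species. Both
conserve totals exactly; taxonomic collapsing is one-way (a class-collapsed
table cannot be re-collapsed at genus).

## Beta diversity and ordination

Bray–Curtis is `1 − 2·Σ min(x_i, y_i) / (Σx + Σy)`. UniFrac metrics walk
the OTU tree once per sample pair, restricted to the subtree spanned by the
table's OTUs (the traversal is rooted at their lowest common ancestor, so
tree tips absent from the table contribute nothing; table OTUs missing from
the tree are an error, never silently dropped). Weighted UniFrac defaults
to the normalized variant (divided by the maximal attainable value given
the tree and the two tip-proportion vectors, hence bounded by 1) because
dendrogram comparisons mix metrics; the raw variant is a flag away.
Multifurcating trees, including star trees, are handled.

PCoA is classical metric scaling: double-center `−D²/2`, eigendecompose,
scale eigenvectors by the square roots of the positive eigenvalues.
Negative eigenvalues — routine for Bray–Curtis — are reported untouched and
their axes flagged; no Lingoes/Cailliez correction is applied. Variance
explained is reported relative to the positive-eigenvalue total.

## Dendrograms

UPGMA merges the closest pair at height `d/2` (average linkage over
original distances, weighted by cluster sizes), so a distance matrix that
is exactly ultrametric is recovered exactly. Ties between equally close
pairs are broken by the lexicographically smallest pair of member labels,
making output deterministic. The jackknifed dendrogram performs `n`
rarefactions of the species-collapsed table, computes a distance matrix per
replicate, UPGMA-clusters the *element-wise mean* matrix into the master
tree ("master tree" behavior of the QIIME jackknife, rather than a
consensus of per-replicate trees), and annotates each cluster with the
fraction of per-replicate trees containing it.

## Topological congruence

Clusters are *nontrivial proper* clusters — the leaf set below each
internal node, excluding singletons and the full leaf set. With this
convention RF = 0 ⇔ MC = 0 ⇔ identical rooted topology, and RF's maximum
between two bifurcating trees on `n` leaves is `2(n−2)`.

The MC distance is solved exactly with the Hungarian algorithm on the
padded cost matrix. Its normalization constant is the maximum MC distance
from the host tree to *any* rooted bifurcating topology, found by
exhaustive enumeration for n ≤ 8 (≤ 135,135 topologies) and otherwise as
the maximum over the sampled null, with the mode recorded in the result.
(An alternative convention normalizes by an average over random tree pairs;
the maximum was chosen because the score is then a fraction of the worst
attainable incongruence for this host tree.)

The null samples topologies *uniformly* over the `(2n−3)!!` labelled rooted
bifurcating topologies via stepwise addition: each successive leaf attaches
to an edge chosen uniformly among all current edges including the root
edge. Uniform — rather than Yule — is the least-informative null for
"random trees with the same number of leaves"; the sampler is chi-square
tested against exact enumeration in the test-suite. The p-value is

    p = #(null distance ≤ observed) / n_random        (default n_random = 100,000)

exactly as defined for this analysis; a `plus_one` flag provides the
never-zero `(k+1)/(n_random+1)` estimator. Trees are compared as-rooted;
multifurcating host trees are accepted (cluster definitions generalize)
while the null remains bifurcating. At least 3 leaves are required (below
that there is no topology variation).

**Calibration and discreteness.** RF and MC are integer-valued, so on few
leaves the null distance has only a handful of atoms and the plain p-value
cannot be uniformly distributed — it is conservative between atoms. The
calibration check therefore uses tie-randomized p-values
(`randomized_null_pvalue`): `p = (#{d < obs} + V·(1 + #{d = obs})) / (n+1)`
with `V ~ U(0,1)`, which is exactly uniform when the observed tree is
exchangeable with the null draws. Reported p-values are always the plain
(conservative) estimator; the randomized form exists for calibration only.

## Supporting statistics

ANOSIM ranks all `M = n(n−1)/2` pairwise distances together (midranks for
ties) and reports `R = (mean between-group rank − mean within-group rank) /
(M/2)`; significance is by permutation of group labels with
`p = #(R_perm ≥ R_obs)/n_permutations` (default 1,000). Every group must
have ≥ 2 members.

The intra- vs interspecific comparison partitions the pairwise distances by
whether the two samples share a species and applies a two-sided
Mann–Whitney U (exact null when the smaller group has ≤ 8 observations and
no ties; normal approximation with tie correction otherwise). The pairwise
distances are not independent observations — each sample participates in
many pairs — so these p-values are descriptive, a caveat recorded in the
result object's `method` field and here.

The clade-age regression is OLS of per-clade ANOSIM R on log10 divergence
age (ages in My must be positive; n ≥ 3 so the slope t-test has residual
degrees of freedom). The Kruskal–Wallis screen tests each taxon of a
(collapsed, relative-abundance) table across host groups and corrects over
all taxa with Benjamini–Hochberg step-up FDR and Bonferroni; constant taxa
are flagged untestable with p = 1. The transplant overlap summary defines
donor-specific OTUs as present in the donor and absent from control
recipients, and reports the percentage transferred and their share of
post-transplant sequence abundance.

## Synthetic data

The generator realizes both competing assembly hypotheses. Per OTU, a root
log-abundance is drawn `N(0, sigma_root²)`; along each branch of length `t`
it accrues independent `N(0, sigma_host²·t)` Brownian increments. A
species' expected composition is the softmax of its tip log-abundances;
each sample adds `N(0, sigma_sample²)` per-OTU noise before softmax and
draws `Multinomial(depth)` read counts. `sigma_host = 0` is the stochastic
null (all species share one expected composition); `sigma_host > 0` makes
expected dissimilarity increase with phylogenetic distance — the generative
analogue of the divergence-age effect. Log-abundance Brownian motion with
softmax was chosen over Dirichlet drift because it yields this
monotonicity explicitly and mirrors standard comparative-methods machinery.
Each OTU consumes its own derived random stream, so enlarging `n_otus`
leaves existing OTU trajectories unchanged.

Defaults (6 species × 10 samples, 200 OTUs, `sigma_root = 1`,
`sigma_host = 2`, `sigma_sample = 0.3`, depth 5,000) constitute the
reference strong-signal regime used by the recovery tests; the same
parameters with `sigma_host = 0` are the reference null.

**The reference host phylogeny.** `reference_host_tree()` is a fixed
six-species ultrametric tree (two cherries and a free tip in the ingroup,
plus an outgroup) with divergence times 0.016, 0.03, 0.06, 0.11 and 0.2 —
*geometrically* spaced with ratio ≈ 1.9. Two deliberate design points:

- Divergence times are geometric rather than evenly spaced because UPGMA
  resolvability depends on the relative gaps between successive merge
  heights, and the Bray–Curtis response to Brownian divergence is concave,
  compressing deep gaps. Recovery under the reference regime is robust to
  the overall depth scale (verified across a 2.5× range) but not to linear
  time spacing.
- The total depth keeps the host effect inside the metric's informative
  range: at the deepest split the per-OTU log-abundance divergence is
  `sigma_host·√(2·0.2) ≈ 1.3` standard deviations, giving median
  interspecific Bray–Curtis around 0.3–0.6 — comparable to real
  interspecific gut-community distances. Much deeper trees push
  compositions into a saturated regime (a few dominant OTUs, all distances
  near 1) where distances carry no topological information at any
  sequencing depth.

Yule (pure-birth) host trees can be simulated instead, but note that random
Yule trees on few taxa frequently contain near-zero internal branches that
no method can resolve; they are appropriate for averaging studies, not for
exact-topology recovery checks.

**What the generator does not emulate:** environmental or dietary
covariates (the study design this pipeline targets controls them), OTU
correlations beyond the compositional constraint, phylogenetic structure
among the microbes themselves (so UniFrac exercises use separately supplied
OTU trees), overdispersion beyond multinomial, and uneven per-sample
sequencing depth (rarefaction is exercised by the pipeline regardless).
Passing recovery tests on these simulations demonstrates the machinery is
correct and calibrated — not that real communities follow Brownian
compositional drift.

## Problem sizes and defaults

Simulation-based checks in the test-suite use the reference regime
(60 samples × 200 OTUs), 50 replicates per condition, 10,000-tree nulls
and 199–999 permutations; the topology sampler is verified against exact
enumeration at 150,000 draws (n = 4, 15 topologies) and 1,050,000 draws
(n = 5, 105 topologies). Production defaults are higher: 100,000 random
trees, 1,000 permutations, 1,000 rarefactions. All stochastic stages take
explicit seeds and identical seeds give byte-identical outputs.

## Known limitations

- The MC normalization switches from exhaustive to null-sample maxima
  above 8 leaves; the normalized score is then a slight overestimate of
  congruence if the sampled maximum falls short of the true one (the raw
  distance and p-value are unaffected).
- UPGMA assumes rate-constancy (ultrametric signal); strongly non-clock
  dissimilarities will distort dendrograms before the congruence test ever
  sees them.
- The uniform-topology null treats all labelled topologies as equally
  likely, whereas dendrograms estimated from noise have a shape
  distribution of their own; on the reference null this makes the
  congruence test slightly conservative (empirical false-positive rate
  below nominal in the recovery tests).
- Sample exclusion by rarefaction-curve inspection is left to the user;
  only explicit depth thresholds are automated.
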