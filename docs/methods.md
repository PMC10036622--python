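# Methods

## Model and procedure

The package infers an undirected dependence network per experimental
condition and compares conditions through annotation-derived edge types.
The working assumptions are:

- samples within a condition are independent draws from one joint
  distribution over molecules; there is no time-series structure within a
  condition;
- pairwise statistical dependence (mutual information above zero) is the
  criterion for an edge; conditional independence given other molecules is
  *not* assessed, so indirect associations appear as edges;
- edge intensities are unreliable at cohort sizes of 10–12 samples, so all
  downstream comparison uses only edge presence/absence and annotation
  classes, never MI magnitudes.

Inference proceeds in four steps: (1) test every unordered molecule pair
for independence by a permutation test on the B-spline MI estimate;
(2) connect pairs with p < p₀ (strict inequality); (3) annotate nodes with
one or more node-type labels; (4) type every edge by the unordered label
pair(s) of its endpoints, splitting a multi-label edge's unit weight
equally over the distinct edge types (ETs) formed by all label
combinations. The weighted ET counts are the network's fingerprint.

## Estimator details

**Standardization.** Each molecule row is centered and scaled to unit
sample standard deviation (ddof = 1). Constant rows cannot be standardized
or range-mapped; they are excluded and reported, and their pairs are
treated as untested rather than absent.

**B-spline binning.** For spline order k and bin count M, clamped uniform
knots span [0, M−k+1]; sample values are mapped linearly from
[min, max] onto that domain (the right endpoint is nudged into the
half-open support of the last basis function). Each sample's weight row is
the M basis values — nonnegative, summing to 1 — so the joint table is a
smoothed 2-D histogram. Order k = 1 reduces exactly to hard binning, which
the tests exploit: on bin-aligned data the estimator must equal discrete
MI from the contingency table.

**Bin-count rule.** M is chosen per pair by a registered rule. The default
is Sturges' rule, M = ⌊log₂ n⌋ + 1, clamped to [k, n/2]; it is symmetric
in the pair, deterministic, and non-decreasing in n (M = 4 at n = 12,
M = 9 at n = 500). A fixed-M rule (`"fixed:M"` or an integer) is always
available and custom rules can be registered. No claim is made that this
rule matches any particular published bin-selection procedure; it is a
documented, reproducible default.

**Independence test.** B = 500 uniform permutations of x (y fixed; the
marginals are permutation-invariant, so only the joint table is
recomputed, vectorized over all permutations). The p-value is the plain
count ratio #(null > observed)/B with strict inequality, so p = 0 occurs
whenever the observed MI beats every null sample; the smoothed
(c+1)/(B+1) convention is available behind `add_one_smoothing`. With the
count convention the rejection probability at p₀ = 0.05 is
25/501 ≈ 0.0499, which the calibration test verifies empirically.

**MI-difference test.** For a pair measured in two conditions the
statistic is |I₀ − I₄|. The null distribution pools the (x, y) sample
pairs of both conditions and randomly re-splits them into groups of the
original sizes, preserving within-sample pairing while enforcing equal
dependence — a design choice, since several resampling schemes would be
defensible. Bin counts are fixed per condition by the rule before
re-splitting.

**Seeding.** One root seed; every pair derives its own generator from
(root seed, blake2b of the sorted molecule IDs), so results are identical
under any pair-evaluation order or parallel schedule, and reruns are
byte-identical.

## Edge types and comparison statistics

- ET catalog: all unordered label pairs including self-pairs,
  lexicographic by label index; t = s(s−1)/2 + s (66 at s = 11 — the
  package defaults to the 11 KEGG "Metabolism" classes, user-replaceable).
- Multi-label weighting divides by the number of *distinct* ETs (the two
  orderings of a cross pair collapse before weighting), so every typed
  edge contributes total weight exactly 1.
- Edges with an unannotated endpoint are excluded from ET counts and
  reported separately, never silently dropped.
- ET graph density: D_ET = 2E_ET/(N_ET(N_ET−1)) with E_ET the fractional
  weighted edge count and N_ET the number of nodes carrying either label
  of the ET. For a cross-type ET this denominator includes same-type pairs
  that can never realize the ET; the formula is kept in this form for
  consistency with the density definition on the whole graph, and a
  tighter bipartite denominator N_a·N_b is available via `bipartite=True`.
  ETs with fewer than two eligible nodes yield a missing value.
- Response networks assign every node pair one fate (P→P / A→P / P→A /
  A→A); per-ET fate histograms type A→A pairs with the same fractional
  weighting as edges so the four fates partition each ET's pair share.
- Chi-squared histogram distance normalizes both inputs to sum 1, skips
  bins empty in both, and is bounded in [0, 1]; it is not a metric and no
  triangle inequality is assumed anywhere.
- The two-sample Cramér–von Mises test treats ET indices as ordinals;
  weighted ET counts are expanded to replicated ordinal observations at a
  configurable weight resolution (default: round to nearest 1). This
  expansion is an interpretive choice — a weighted categorical fingerprint
  has no canonical "sample" form — and the reported statistic is the
  standard two-sample CvM T computed from pooled EDFs (midrank ties), with
  asymptotic, exact, or permutation p-values. Bonferroni correction over
  the comparison family (6 for four conditions) is applied by the caller
  and capped at 1.
- Torgerson MDS double-centers the squared distances,
  B = −½ J D² J, and takes the top eigenpairs; negative eigenvalues
  (non-Euclidean χ² distances) are truncated, and if fewer positive
  eigenvalues than requested dimensions exist, fewer columns are returned.
  Signs are fixed by making each coordinate's largest-magnitude loading
  positive.
- Threshold-robustness scan: networks are re-thresholded from stored
  p-values (no re-permutation); each statistic's profile — per-ET
  densities for ET density, per-node vectors for path length, clustering
  and the centralities (a scalar summary would have no rank correlation) —
  is compared to the reference-threshold profile by |Spearman ρ| with
  pairwise NaN exclusion, and each curve is normalized to 1 at the
  reference.

## Synthetic data

The generator emulates the shape of a two-genotype, two-timepoint
perturbation study: 11–12 samples per condition, tens to hundreds of
molecules, multi-label annotations (default multiplicity: one label with
probability 0.8, two with 0.2, exercising the fractional-weighting path),
and a planted dependence structure that differs between conditions purely
through edge-set changes. Dependence kinds are linear (y = rx + noise),
symmetric quadratic (near-zero correlation) and a random-sign coupling
("xor", zero correlation) — the latter two exist to demonstrate MI's
advantage over correlation. Default planted strength is 0.92–0.95,
i.e. strong dependencies, matching the regime where n ≈ 12 gives high
power.

What the generator does **not** emulate: realistic abundance scales or
count distributions (standardization removes scale), correlated noise
across molecules, batch effects, missing values, or realistic annotation
co-occurrence structure. Passing tests therefore demonstrate correctness
of the machinery and its statistical calibration, not performance on real
measurement noise.

## Numerical choices and degenerate inputs

- MI terms with zero joint mass contribute 0; the plug-in estimate is
  nonnegative up to 1e−12 and tests assert that tolerance.
- Zero-range vectors (all values equal) are an error for the basis
  mapping; constant matrix rows are excluded upstream with a report.
- Graph densities are evaluated in exact arithmetic (integer counts) and
  rounded only for display.
- Isolated nodes: closeness 0, undefined mean path length (NaN, excluded
  pairwise from correlations).
- Ranking ties break lexicographically by ET label pair.
- All-zero distance matrices embed to the origin.

## Problem sizes

The test suite and the acceptance script run at metabolome scale and
below: networks of 12–40 molecules, B = 500 permutations (200 in some
pipeline tests), calibration over 1000 pair replicates, recovery studies
at n = 500 samples, and five-replicate robustness comparisons. The
architecture (per-pair seeding, re-thresholding from stored p-values)
supports much larger inputs, but transcriptome-scale runs (~10⁷ pairs)
are out of scope for the bundled tests.

## Known limitations

- No conditional-independence estimation; hub molecules induce indirect
  edges.
- No MI bias correction; at n ≈ 12 the MI values themselves are biased
  upward, which is precisely why downstream analysis discards them after
  thresholding.
- The count/B p-value cannot distinguish effects below 1/B, and p = 0 is
  reported as printed (use `add_one_smoothing` for downstream procedures
  that require p > 0).
- CvM on expanded ordinal samples depends on the weight resolution;
  fingerprints with very small weighted counts are poorly represented at
  the default resolution of 1.
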