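# Methods

This note documents the models, the numerical conventions, and the design
choices behind `vulnmap`, and states precisely what the synthetic-data
generator does and does not emulate.

## 1. Data model and weighted statistics

A survey table holds one row per adult respondent: a positive survey weight
(population expansion factor), an opaque area code, a self-reported type-2
diabetes flag, 35 candidate socioeconomic/behavioral indicators (nominal or
ordinal), and three biometric variables (high blood pressure, body-mass
index in kg/m², age in integer years). Ordinal indicators carry their
category order in the schema, but the pipeline is deliberately nonmetric: no
stage ever assigns numeric scores to categories. Missingness is a sentinel
(`NA` in files), never a category.

All reported proportions except tree statistics are survey-weighted,
Σ w·1[condition] / Σ w. The weighted percentile is the left-continuous
inverse of the weighted empirical CDF — the smallest value v whose weighted
fraction of observations ≤ v reaches q/100. This definition is exact and
deterministic, which matters because the 75th-percentile screen and the
area-quartile rule both sit directly on it; both statistics are invariant to
uniform weight rescaling.

## 2. Two-step clustering of the diagnosed

Clustering is unweighted and operates on the diabetic subset, complete cases
only (listwise within the active variable set).

* **Distance.** A cluster is summarized by its per-variable category counts
  (mergeable by addition). The cost of a cluster is the entropy term
  ξ(C) = Σ_v n·H_v with H_v = −Σ_l (n_vl/n)·ln(n_vl/n); the merge distance is
  d(A,B) = ξ(A∪B) − ξ(A) − ξ(B) ≥ 0. Ordinal variables are treated
  multinomially.
* **Pre-clustering.** A sequential leader pass assigns each case to the
  nearest sub-cluster. The first pass merges only exact duplicates (distance
  0), which provably leaves the subsequent hierarchy unchanged; only when the
  sub-cluster count would exceed the capacity (default 50) is the threshold
  raised to the 10th percentile of sampled pairwise singleton distances and
  doubled until the pass fits, restarting deterministically. For ≤ 12 cases
  the pipeline is therefore *exactly* equivalent to exhaustive greedy
  agglomeration, and the test suite enforces this against an independent
  pooled-recount oracle.
* **Cluster number.** BIC(k) = 2·Σ_clusters ξ + r·k·ln N with r = Σ_v(L_v−1)
  free parameters per cluster. Selection is the standard two-stage
  heuristic: the coarse candidate is the smallest k whose BIC-change ratio
  d(k)/d(1) (d(k) = BIC(k) − BIC(k+1)) falls below 0.04; it is refined by the
  ratio of merge distances R(k) = dist(k)/dist(k+1), where dist(k) is the
  cost of merging k clusters into k−1, accepting the largest-R candidate only
  when it dominates the runner-up by a factor 1.15. Both constants are
  configurable; candidate k is capped at 15. Distance ties in agglomeration
  break on the lowest index pair, with a 1e−9 tolerance so tie classification
  is robust to float summation order.
* **Importance and quality.** Indicator importance is −log10 of the
  Pearson chi-square p-value of indicator × cluster (p floored at 1e−300),
  rescaled so the top indicator is exactly 1.0; a constant indicator scores
  0. Quality is an average silhouette where a case's distance to a cluster
  is the merge distance of its singleton against the cluster's counts (own
  cluster with the case removed); bands are poor < 0.2 ≤ fair ≤ 0.5 < good.
  Note that this distance carries an n·ln n size term, so the silhouette of
  truly unseparated clusters is negative rather than zero, and greedy
  clustering of pure noise can look "fair" in-sample — overfit clusters are
  genuinely cohesive on their own data. Passing quality bands therefore
  certify in-sample cohesion/separation, not generalization.
* **Variable elimination.** Starting from the 35 candidates, the
  lowest-importance indicator is dropped (ties: later in schema order) until
  all of: complete cases per variable ≥ 10, band fair or good, and largest /
  smallest cluster < 2. If the set shrinks to 8 variables without
  satisfaction, the best-quality iteration is returned with a
  non-convergence flag. The size-ratio criterion is stated as < 2 in the
  procedure this reimplements even though its reported solution violates it
  (174/78 ≈ 2.23); the same tension appears here — the planted shares
  (0.494/0.284/0.222) imply a ratio of 2.23, so truthful solutions cannot
  satisfy the criterion and convergence, when it occurs, happens at
  iterations whose noise happens to balance the cluster sizes. The
  recovery guarantees (k = 3, high adjusted Rand index) are therefore
  stated for clustering on the informative indicators, and the elimination
  loop is guaranteed to *retain* the informative set, not to halt on it.

## 3. Profile-match screening

Each undiagnosed respondent's score against cluster c is
Σ_v w_v·1[x_v = m_cv] over the solution's active indicators (missing
values contribute 0; an optional graded mode gives half credit to ordinal
categories adjacent to the modal one, off by default). The per-cluster
threshold is the survey-weighted 75th percentile of that cluster's score
distribution over the pooled undiagnosed population; a matcher exceeds the
threshold for at least one cluster and is attributed to its highest-scoring
qualifying cluster (ties to the lower index), so area tallies never
double-count. Raising the percentile can only shrink the matcher set.

Because the synthetic population is, by design, a mixture of exactly the
three planted segments, the three quartile tails are nearly disjoint and the
union matcher share is ≈ 70% — much higher than a real population would
show, where most residents resemble no diabetic profile. Similarly, matcher
vs non-matcher contrasts on the biometric predictors arise only through
segment composition: blood pressure and age are clearly enriched among
matchers, while BMI comes out approximately even (as in the reference
comparison). Passing tests certify these structural patterns, not
real-population magnitudes.

## 4. Recursive partitioning

Binary CART on the 35 candidates plus the three biometrics, unweighted (the
method accommodates only unweighted data; weights re-enter downstream).

* **Equal priors.** With π = (½, ½) and root class totals (N₀, N₁), node
  class probabilities are p̃_c ∝ π_c n_c(t)/N_c and impurity is
  G = 2p̃₁(1−p̃₁). The decision boundary consequence: a terminal node
  predicts the outcome exactly when its event rate ≥ the root baseline rate
  (9.1%-style baselines), which is how a rare outcome stays predictable.
* **Splits.** Exhaustive search — midpoint thresholds for continuous and
  ordinal (ordered-code) predictors, all proper category subsets for nominal
  predictors up to 12 categories (event-rate-ordered scan beyond). Gain is
  the priors-weighted impurity decrease; ties break on predictor order, then
  the lower threshold / earlier subset. The stored per-node decrease is the
  node-mass-weighted value μ(t)·ΔG(t), the quantity importance sums.
* **Surrogates.** Up to 5 per internal node, ranked by Breiman's predictive
  association λ = (min(p_L,p_R) − p_miss)/min(p_L,p_R) (both threshold
  orientations considered; nominal categories assigned to their majority
  direction). Surrogates route missing values at prediction time (then the
  majority direction) and contribute their own mass-weighted decrease to
  importance. Importance is rescaled so the top predictor is exactly 100.
* **Pruning and selection.** Minimal cost-complexity pruning (all weakest
  links with equal link strength collapse together) gives the nested
  sequence; 10-fold outcome-stratified seeded cross-validation of the
  priors-weighted misclassification (mean of the two class error rates),
  evaluated at geometric-midpoint complexities, selects the subtree with
  minimal CV error, ties toward the smaller tree. The conventional
  one-standard-error rule is available (`se_rule`); the default is the
  strict minimum, which on pure noise can retain small spurious trees —
  the 1-SE option is the remedy when parsimony matters.
* **Defaults.** min_node 20, min_child 7, max_depth 10, all configurable.
  Reported node rates are 100·n⁺/n computed in double precision and rounded
  half-up to one decimal.

## 5. Areas and the composite spectrum

Per area and cluster, two weighted percentages: **share** (of all matchers
of the cluster countywide, summing to 100 across areas) and
**concentration** (of the area's own population). An area is selected for a
cluster when it reaches the top quartile (the q = 75 weighted-percentile cut
across areas, each area one observation) on *both* axes and actually
contains matchers of the cluster; the vulnerable set is the union over
clusters ranked by concentration, optionally capped for presentation.

Within selected areas, physical vulnerability is ≥ 2 of {high blood
pressure, age ≥ 45, BMI > 26.93 (strict)}, financial vulnerability ≥ 2 of
{rent-or-food hardship above "never" (one combined indicator), income below
200% of the Federal Poverty Level, ≥ 1 public assistance program}; missing
components count as absent (conservative). The four-group spectrum is the
survey-weighted cross-tabulation over all residents of the selected areas;
it always sums to 1 and is weight-rescaling invariant. The "older than 45"
vs "age ≥ 45" wording tension in the source material is resolved toward the
tree threshold (≥ 45).

## 6. The synthetic survey generator

The generator defines the study conditions: 4,749 respondents, 9.1% target
prevalence, three planted segments with modal-category profiles mirroring
the reference cluster table (shares 0.494/0.284/0.222 *of the diabetic
population*, adherence 0.8), 28 areas, lognormal weights.

* **Causal structure.** Segment membership shapes the 11 informative
  indicators (modal category with probability = adherence, else a background
  draw — uniform except a young-skewed age background); 24 further candidate
  indicators are pure background noise. Diabetes is Bernoulli with
  logit p = c + 1.7·HBP + 1.1·1[age ≥ 45] + 0.055·BMI; biometrics depend on
  segments only through segment-specific age-bin draws, an age-driven blood
  pressure curve (≈ one third positive overall), and lognormal BMI
  (segment log-means ln 28.5 / ln 27.0 / ln 30.0, σ = 0.17, so the 26.93
  threshold is interior). Thus biological variables dominate prediction
  while socioeconomic profiles cluster the diagnosed — the structure the
  analysis assumes.
* **Calibration.** A seeded pilot simulation per segment solves the logistic
  intercept c so overall prevalence hits the target, and sets population
  segment shares π_s ∝ share_s / p̄_s(c) so the *diabetic* shares land on the
  configured values. Both are analytic consequences of the config, not
  post-hoc tuning.
* **Geography.** Per-area segment mixtures are Dirichlet(25·π); the first
  three areas are enriched (0.75 mixture weight) for one segment each and
  pinned at the average population size, while the remaining areas get
  heterogeneous Dirichlet(6) sizes — with uniform sizes the share and
  concentration axes would rank areas identically and the two-axis rule
  would degenerate.
* **Not emulated.** The real survey's stratified sampling design,
  nonresponse and raking, spatial autocorrelation beyond area mixtures, a
  background population resembling no diabetic profile, and real-data
  missingness. Consequently the matcher share (~70%) and the spectrum
  composition differ from what restricted real data would produce; recovery
  tests certify that the *machinery* finds planted structure, not that the
  synthetic population reproduces published population figures.

## 7. Determinism

A single integer seed feeds a seed sequence with independent per-stage
streams (generation, CV folds), so toggling one stage never perturbs
another. The pipeline manifest records a SHA-256 checksum per artifact;
identical config + seed reproduce identical checksums byte for byte.

## 8. Known limitations

* In-sample silhouette rewards overfit structure (Section 2); quality bands
  are necessary, not sufficient, evidence of real segmentation.
* The size-ratio halting criterion conflicts with the planted (and the
  reference) cluster-size ratios; the elimination loop's convergence flag
  should be read together with the retained-variable list.
* Strict-minimum CV selection can keep small spurious subtrees on noisy
  outcomes; use `se_rule=1.0` for the parsimonious convention.
* The quartile-based area rule returns however many areas qualify (about
  10–16 under default synthetic conditions), not a fixed four; `area_cap`
  exists for presentation.
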