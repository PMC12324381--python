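# Methods

`bristlekit` quantifies the spatial organisation of spot patterns —
concretely, the microchaete (small sensory bristle) precursor patterns
on the *Drosophila* dorsal thorax — from per-tissue centroid tables,
and classifies patterns as wild-type-like or perturbed. This note
documents the models, the parameters that matter, the synthetic data
the tests run on, and the numerical choices taken where the design was
genuinely open.

## Pattern features

One tissue (a heminotum, one lateral half of the notum) is a point
cloud of N bristle-cell centroids, in microns, with a tissue area A.
Five global features summarise it.

**Relative sensory area (RSA).** RSA = N·a_cell / A, where a_cell is
the mean apical area of a single bristle precursor cell. The default
a_cell = 24.5 μm² was measured on control tissues at 24 h after
pupariation and is overridable per cohort (other stages or genotypes
may differ). RSA is a pure density measure: it is blind to spatial
arrangement.

**Clustering features.** The remaining four features derive from a
DBSCAN clustering of the centroids at a per-tissue optimal (ε, MinPts):

* CN — number of clusters K;
* OP — outlier prevalence, the fraction of points assigned to no
  cluster;
* CQ — cluster quality, the *pattern silhouette score* (below);
* CSV — cluster size variance: with cluster occupancies η_1..η_K and
  mean η̄, CSV = (1/(K−1)) Σ_i ((η_i − η̄)/N)². Scaling the deviations
  by N makes the statistic comparable across tissues with different
  point counts. CSV is defined as 0 when K ≤ 1 (a single cluster has
  no between-cluster heterogeneity; the 1/(K−1) normalisation is
  undefined there, and the zero convention keeps cohort tables
  rectangular). N counts all pattern points including outliers by
  default; a switch restricts it to clustered points.

## DBSCAN with deterministic tie-breaks

The clusterer is self-contained so that a labeling is a pure function
of the point sequence:

* ε-balls are closed disks and a point counts itself among its
  neighbours, so a point is *core* when ≥ MinPts points (self
  included) lie within ε — the convention of the original DBSCAN
  literature; MinPts = 1 makes every point core.
* Clusters are connected components of the graph on core points with
  edges at distance ≤ ε, numbered 0..K−1 by each component's lowest
  point index.
* A non-core point within ε of a core point is a *boundary* point and
  joins the cluster of the lowest-index such core point (classic
  DBSCAN leaves this order-dependent; the explicit rule makes repeated
  runs and the feature table reproducible).
* All remaining points are *outliers*.

Distances are Euclidean. The O(n²) distance matrix is computed once
per tissue and shared across the parameter grid; tissues hold on the
order of 10² points, so no spatial index is warranted.

## Silhouette and parameter selection

For point i in cluster C_i, a_i is the mean distance to the other
members of C_i (denominator |C_i| − 1) and b_i the minimum over other
clusters of the mean distance to all their members; S(i) =
(b_i − a_i)/max(a_i, b_i) ∈ [−1, 1]. S(i) is undefined for outliers
and for members of singleton clusters, and requires K ≥ 2.

The pattern silhouette score is CQ = (1/N) Σ S(i) over all N points,
with undefined S(i) entering as 0 — the mean is taken over the whole
pattern, not just the clustered points. This is the default
(`cq_outliers="zero"`); `"exclude"` averages over valid points only.
The distinction matters beyond bookkeeping: when parameters are chosen
by maximising CQ, the exclude variant rewards degenerate solutions
that keep two tight micro-clusters and discard ~90% of points as
outliers, whereas the over-N mean penalises unclustered points and
selects clusterings that engage most of the pattern — the behaviour
real tissue profiles (CQ ≈ 0.4, OP ≈ 0.2–0.3) reflect.

(ε, MinPts) are selected per tissue by exhaustive search: every grid
pair is clustered and scored; pairs with K < 2 (or no point with a
defined silhouette) are invalid and score −∞; ties break toward
smaller ε, then smaller MinPts, making the argmax independent of grid
order. When every pair is invalid, the pair giving the most clusters
is kept and CQ is recorded as missing (NaN), which downstream analyses
drop pairwise. Default grids are scale-free: 15 log-spaced ε values
between the 5th percentile of nearest-neighbour distances and 4× their
95th percentile, and MinPts ∈ {3, 4, 5, 6}. Both are configurable, and
a cohort-level shared-parameter mode is not provided at the estimator
level — each tissue is tuned independently.

## Group statistics and feature selection

All tests are two-sided at α = 0.05; p-values are reported raw per
feature and comparison (Benjamini–Hochberg adjustment is available but
off by default). Heminota are treated as independent patterns.

* Kruskal–Wallis (tie-corrected, χ² approximation) screens each
  feature across all groups.
* Mann–Whitney U compares each mutant group with its paired control;
  the p-value is exact by enumeration when the smaller sample has ≤ 8
  observations and the pooled data are tie-free, otherwise the normal
  approximation with tie and continuity corrections is used.
* Logistic regressions (control = 0, mutant = 1) are fit by
  Newton/IRLS with convergence at relative log-likelihood change
  < 1e-10 or 100 iterations. Complete separation — perfect
  classification with a diverging linear predictor — is flagged
  (`converged = False`) rather than raised, and propagates into
  reports as a warning; Wald p-values are still reported but are not
  trustworthy under separation.
* The likelihood-ratio test compares nested fits: statistic
  2(ℓ_full − ℓ_nested) clamped at zero, χ² with df = added parameters.
  The per-mutant report fits the standard augmented sequence on the
  RSA base model (RSA+CQ, RSA+CSV, RSA+OP, RSA+CSV+OP, RSA+CSV+CQ) and
  reports each model's test against the base and, for three-feature
  models, also against its two-feature parent (RSA+CSV) — the two
  natural readings of a stepwise table — plus Wald p-values from the
  multiple regression on RSA, OP, CQ and CSV.

## Wild-type region and penetrance

Features (default pair RSA, CSV) are z-scaled with the mean and
standard deviation (ddof = 1) of a designated reference control group,
applied to all groups, so the classification space reads as "control
standard deviations". A soft-margin SVM separates controls (class 0)
from perturbed patterns (class 1) after a stratified 60/40 train/test
split at a required, logged `split_seed`. Hyperparameters — kernels
linear/polynomial/RBF, C ∈ {0.1, 1, 10, 100, 1000}, γ ∈ {0.001, 0.01,
0.1, 1, 10}, degree ∈ {2, 3, 4} — are chosen by stratified 5-fold CV
accuracy on the training portion; ties prefer the simpler kernel
(linear < poly < RBF), then smaller C, γ, degree, so reruns are exact.
The winner is refit on the full training portion; held-out accuracy
and per-group outside-region fractions are reported as exact empirical
fractions. The predicted-class-0 set is the wild-type patterning
region; a group's *penetrance* is the fraction of its patterns
predicted outside it. The SVC solver is iteration-capped (2×10⁵) so
ill-conditioned grid corners terminate; at cohort sizes any useful fit
converges far earlier. Probability calibration and class weighting are
deliberately out of scope.

## Synthetic patterns

No raw images accompany the study's data, so the generator emulates
the statistical structure the features respond to, not the signalling
mechanism:

* **Domain** — a 250 × 400 μm rectangle, heminotum scale; tissue area
  is the domain area.
* **Spacing** — simple sequential inhibition: the target count is
  Poisson(intensity × area); uniform proposals are accepted only at
  ≥ `hardcore_radius` from every accepted point. This reproduces the
  hard minimum spacing lateral inhibition imposes; it is
  deterministic per seed and cheap, at the cost of not matching any
  particular Gibbs process. The proposal budget is 10⁴ per requested
  point; if it runs out with ≥ 50% placed the shortfall is logged,
  below that the configuration is rejected as infeasible.
* **Structure** — points are seeded along `n_rows` vertical rows
  (lateral jitter σ = `row_jitter`), echoing the longitudinal bristle
  rows of the notum, and thinned by a block-modulated intensity field:
  the domain is partitioned into `block_shape` blocks whose
  multipliers are gamma-distributed with mean 1 and coefficient of
  variation `block_heterogeneity`, renormalised to preserve the
  expected count. Blocks create local density differences and hence
  clusters of unequal occupancy.
* **Isolated points** — a fraction `outlier_rate` of placed points is
  relocated uniformly, at least `isolation_distance` (default
  max(3 × hardcore, 50 μm) on the default domain) from every other
  point where feasible, with a best-effort fallback. The distance is
  deliberately larger than the tuned ε scale (~20 μm for the wild-type
  preset) so relocated points register as outliers rather than being
  re-absorbed as boundary points.

**Presets.** `wildtype` uses intensity 1.1×10⁻³ μm⁻² (≈ 110 points,
RSA ≈ 0.028), 3 rows with 4 μm jitter, hard core 9 μm, 3×3 blocks at
CV 0.5, outlier rate 0.05. Three rows rather than the tissue's five:
at control-like density, five rows on this domain put the within-row
spacing far above the hard core, and rows fragment into many small
clusters; three rows sit near the inhibition-saturated spacing and
yield cohesive row-segment clusters with wild-type-like CQ (≈ 0.43)
and OP (≈ 0.20). The perturbation presets each move one knob:
`dense` ×1.8 intensity and ×0.6 hard core (raises RSA), `heterogeneous`
×3 block CV (raises CSV), `dense_heterogeneous` both, `outlier_rich`
outlier rate 0.3 (raises OP).

**What the generator does not emulate:** Notch/Delta or cytoneme
dynamics, anisotropic tissue geometry, curvature and edge effects of
real heminota, segmentation noise in centroid extraction, or the
correlation between the two heminota of one animal. Passing tests
therefore demonstrate that the pipeline recovers density,
heterogeneity and isolation differences it is pointed at — not that it
would detect any particular biological perturbation in real images.

## Problem sizes and numerics

The shipped checks run cohorts of 40 tissues per group (≈ 110–200
points per tissue), 20 seeded replicates for discrimination and 50 for
null calibration, and 1000 replicates (n = 100) for the
likelihood-ratio size check — sizes at which every distributional
claim has clear resolution while a full run stays comfortably
desk-sized. Silhouette equality against direct formula evaluation is
asserted at 1e-12; I/O round-trips at 1e-9 (12 significant digits
written). Degenerate inputs are defined, not exceptional: empty point
sets cluster to K = 0; patterns with no valid clustering carry a
missing CQ; duplicate coordinates (zero distances) are legal
throughout; identical samples give H = 0, p = 1 in the rank tests.

## Known limitations

* Per-tissue silhouette maximisation has a rugged objective; for
  patterns with weak structure the selected (ε, MinPts) — and hence
  CN/OP/CSV — can jump between coarse and fine regimes across
  near-identical tissues. The cohort statistics absorb this as
  variance, but single-tissue feature values should be read with care.
* Under complete separation (common when a perturbation is strong and
  groups are small), logistic coefficients are unbounded; reports
  flag these fits and their Wald p-values should be ignored in favour
  of the Mann–Whitney results.
* CSV's K ≤ 1 convention (0) conflates "one big cluster" with
  "perfectly homogeneous clusters"; cohorts where many tissues
  collapse to a single cluster compress CSV toward 0.
* The SVM wild-type region is only as interpretable as the two scaled
  features spanning it; with other feature sets the boundary export
  and the region reading still work but the axes lose their Fig-style
  meaning.
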