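# Methods

## Pipeline overview

The package starts where image preprocessing ends: a T × N table of ROI
time series per subject (T time points, N network nodes). Everything
upstream — acquisition, motion correction, normalization, nuisance
regression, band-pass filtering — is out of scope. Downstream it
implements four stages: functional-connectivity construction, sparsity
thresholding, graph-metric computation with random-network
normalization and AUC summarization, and group/brain-behavior
statistics, plus a synthetic cohort generator used to validate all of
them.

## Connectivity and thresholding

Connectivity is the sample Pearson correlation of every node pair,
Fisher-transformed (`z = atanh(r)`) for variance stabilization.
Correlations are clipped to ±(1 − 1e−7) before the transform so
duplicated signals produce a large finite z (≈ 8.41) instead of
infinity; a constant column is a hard error naming the offending node,
never silently dropped.

Graphs are binarized by **network sparsity** rather than by a fixed
correlation cutoff: at sparsity `s` the target edge count is
`E(s) = round(s·N(N−1)/2)` (round half away from zero; the rounding
convention of reference toolboxes is not published, so ours is stated
explicitly). The E(s) largest strictly **positive** z-values become
edges; negative and zero correlations are never edges. Ties in z are
broken by ascending (i, j) order, making the edge set deterministic.
If fewer than E(s) positive entries exist, all positive entries are
used and a warning is recorded on the graph (`truncated=True`); a
matrix with no positive entries raises. Because thresholding is by
rank, edge sets are nested across the band: the graph at 0.05 is a
subgraph of the graph at 0.40, which makes Eglob and nodal degree
non-decreasing in sparsity.

The default band is 0.05–0.40 in steps of 0.05 (8 points): the lower
end keeps the mean degree above ln N (at N = 264 and s = 0.05, mean
degree 13.15 > ln 264 = 5.58 — `check_connectedness_floor` reports
this), the upper end stays below 50 % density. A 0.01 step is available
as a robustness alternative; the pipeline test asserts that switching
steps does not flip the sign of any significant global difference.

## Graph metrics

All metrics operate on dense binary adjacency matrices; the inner loops
(BFS all-pairs distances, neighbor-subgraph efficiency, Brandes
betweenness, double-edge swaps) are numba-compiled, which keeps a full
cohort sweep (43 subjects × 8 thresholds) in the tens of milliseconds
at N = 60.

Conventions, chosen once and fixed:

- **Cp / NEloc for low-degree nodes.** Nodes of degree < 2 contribute 0
  and are *included* in the means (the common toolbox convention).
- **Lp on disconnected graphs.** Lp averages over pairs with finite
  distance and sets an explicit `disconnected` flag; infinities never
  enter the mean. The efficiency metrics handle disconnection by
  construction (1/∞ = 0).
- **Betweenness** is reported as raw unordered-pair counts, not
  normalized by (N−1)(N−2)/2; group t-tests are invariant to that
  scale factor.
- **AUC** is the trapezoidal integral over the band; a metric constant
  at c over the default band integrates to 0.35·c.

### Null-model normalization

gamma, lambda and sigma = gamma/lambda compare Cp and Lp to the mean of
an ensemble of degree-preserving random graphs built by Maslov–Sneppen
double-edge swaps: pick two disjoint edges (a,b), (c,d) and rewire to
(a,d), (c,b) when neither replacement edge exists. Defaults: 100 nulls
and 100·E swap attempts per null, both configurable; the endpoint
orientation of each attempted swap is randomized to avoid the bias of
always pairing stored endpoints. The ensemble is seed-controlled and
bit-reproducible. Graphs with no two independent edges (stars,
triangles) are rejected. Validity checks: every null preserves the
degree sequence exactly; an Erdős–Rényi graph is its own null
(gamma ≈ 1 ± 0.3 at N = 60 with 100 nulls); rewiring destroys lattice
clustering (gamma > 1 for a ring lattice).

## Statistics

- **Two-sample t** accepts raw samples or printed (mean, sd, n)
  summary triples. Welch (unequal variances, Satterthwaite df) is the
  default: published demographic tables of this design reproduce under
  Welch for the clinical scores but under pooled Student for age, so
  both variants are exposed. Two-sided p throughout.
- **Permutation test** shuffles group labels and recomputes the Welch
  t; the two-sided p uses the add-one estimator
  (1 + #{|t*| ≥ |t|})/(n_perm + 1), never exactly 0. When the design
  admits ≤ 10,000 distinct relabelings, exhaustive enumeration replaces
  sampling and p is exact. Default 5,000 shuffles.
- **Mann–Whitney U** uses exact enumeration for tie-free designs up to
  n = 12 total and the tie-corrected normal approximation otherwise.
- **Chi-square (2×2)** implements both the uncorrected and Yates
  formulas. On the 16:8 vs 10:9 sex table of the motivating design the
  uncorrected statistic is 0.873 and the Yates statistic 0.385; neither
  matches some published values (0.48), so both are reported and the
  discrepancy is documented rather than resolved.
- **Partial correlation** is the Pearson correlation of the residuals
  after least-squares projection of both variables onto
  [intercept + covariates], with df = n − 2 − k; sex is encoded 0/1.
  A rank-deficient design or a variable fully explained by the
  covariates raises.
- **Multiple comparisons.** Nodal tests use Bonferroni only, at the
  strict α/N and the liberal exploratory 1/N level (0.000189 and
  0.0038 at N = 264, α = 0.05). Global AUC tests and behavior
  correlations run at uncorrected α = 0.05, the usual convention when
  AUCs rather than per-threshold values are compared.
- Brain-behavior correlations are computed within the patient group
  only; the control group sits at the ceiling of the clinical scales by
  construction, so pooled correlations would be driven by the group
  gap.

## Synthetic cohorts

The generator emulates the data structure of a two-group (24 patients /
19 controls) resting-state study with modular covariance:

- **Covariance.** Nodes partition into modules (default 6 × 10 at
  N = 60; N = 264 mirrors the full atlas). Correlation is `rho_within`
  (default 0.6) inside a module and `rho_between` (default 0.1) across,
  giving block-constant, provably PSD matrices; the smallest eigenvalue
  is checked (≥ −1e−10) and tiny negatives clipped, otherwise the
  config is rejected.
- **Lesion model.** A designated node subset (default: the first two
  modules) marks "lesioned" modules. Each patient carries a scalar
  severity drawn uniformly from [1 − spread, 1]; within lesioned
  modules the correlation drops to
  `rho_within − severity·strength·(rho_within − rho_between)`.
  A per-subject scalar severity (rather than per-node damage) makes one
  latent variable drive both network damage and clinical scores, so
  brain-behavior recovery is well-posed. With the default strength 0.7
  and severity 1 the lesioned blocks fall from 0.6 to 0.25.
- **Time series** are i.i.d. multivariate-normal draws of length
  T = 150. No temporal autocorrelation, hemodynamics, motion spikes or
  voxel-space lesion geometry are simulated: graph construction uses
  only inter-node correlation, so these are irrelevant to what the
  tests validate — and accordingly, passing tests say nothing about
  preprocessing robustness on real data.
- **Clinical scores.** Each of the four aphasia-battery sub-scores is
  `baseline + coupling·(1 − severity) + N(0, noise)`, truncated to
  [0, 100]; the composite language ability is their arithmetic mean.
  Defaults: coupling 30 score units, noise sd 10, severity spread 1.0,
  and baselines 38/61/59/39 — chosen so the patient group mean and
  dispersion of each sub-score land near typical published
  motor-aphasia cohort values (means ≈ 53/76/74/54 with sds in the
  10–20 range, composite ≈ 64), while controls sit near ceiling
  (≈ 99.5). The full severity spread reflects the wide clinical
  heterogeneity of such cohorts (composite sd ≈ 19 in published
  tables). Cognition screens (MMSE/MoCA, 0–30) are mildly coupled to
  the same severity. Age, sex, duration and head motion are drawn from
  plausible ranges *independently* of severity, giving
  partial-correlation tests a known null. Head-motion units are
  arbitrary (published designs use it only as an exclusion criterion
  and covariate).
- Determinism: one `numpy` Generator seeded from the config; identical
  configs give bit-identical cohorts.

## Validation experiments

`fcnet.experiments` runs the full chain (generate → FC → binarize →
Eloc → AUC → Welch test) repeatedly. Local efficiency is the monitored
metric because the within-module lesion attacks exactly the
neighbor-subgraph connectivity it measures:

- **Type-I error:** 500 no-lesion cohorts; rejection rate of the
  Eloc-AUC test should sit in the binomial band around α = 0.05.
- **Power:** 20 strong-lesion cohorts (0.6 → 0.25 in two of six
  modules); expected rejection (with the correct sign) in ≥ 90 %.
- **Brain-behavior recovery:** 20 coupled cohorts; a positive,
  significant patient-group correlation between Eloc AUC and the
  composite language score in ≥ 80 %.

Problem sizes (60 nodes, 150 time points, 500/20/20 replicates) are the
package's standard test-bed: large enough for stable operating
characteristics, small enough that the whole battery runs in a few
minutes on one core.

## Known limitations

- The generator's block-constant covariance is far simpler than real
  functional connectomes (no hubs, no distance dependence, no negative
  correlations), so gamma/sigma values on synthetic cohorts are not
  calibrated to empirical small-world ranges.
- Betweenness on very large dense graphs (N ≫ 264) would benefit from
  an adjacency-list Brandes variant; the dense-matrix kernel is tuned
  for the atlas scales this package targets.
- Weighted, directed and negative-edge networks, modularity/hub
  analyses and FDR correction are out of scope.
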