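# Methods

## Data model

All analyses operate on localization tables: records of (x, y) in
Cartesian nanometres (y increasing upward, no image-axis flip), a
channel label (at most two channels), a frame index, and a stable
integer id. Analyses are restricted to a polygonal region of interest
(ROI) — for nuclear-envelope work, an annulus — using a
boundary-inclusive point-in-polygon test so that localizations on the
ROI outline are kept. Column names and unit scaling of input files are
dialect-driven because localization-fitting software varies its export
schema; coordinates are converted to nm on read.

## Degree-of-colocalization (DoC) scoring

For each localization i of the source channel, same-channel
(excluding i) and cross-channel neighbour counts are taken in closed
balls of radii r_k = kΔr up to R_max, and converted to area-normalized
gradients D(i, r_k) = (N(i, r_k)/N(i, R_max))·(R_max²/r_k²). The score
is the Spearman rank correlation (average-rank ties) of the same- and
cross-channel gradient vectors over k, damped by exp(−d_i/R_max) with
d_i the cross-channel nearest-neighbour distance. Conventions:

- Δr = 20 nm, R_max = 500 nm by default (K = 25 radii); both
  config-exposed. R_max must be an integer multiple of Δr.
- If either total count at R_max is zero, or either rank vector has
  zero variance, the score is 0 (neutral, not anticorrelated).
- No edge correction is applied at ROI boundaries. Points within R_max
  of the boundary see truncated neighbourhoods in both channels.
- Percent colocalized = 100 × |{score ≥ 0.4}| / |scored localizations|
  per direction, with the 0.4 boundary included.

### Null-calibration behaviour (important caveat)

On two independent CSR channels the *mean* score is close to zero
(≈ +0.09 at 125 localizations/µm²; the small positive offset comes from
shared zero-count tie blocks at small radii, and from the shared
boundary-truncation trend where no edge correction is applied). The
score *distribution*, however, is intrinsically broad: cumulative
counts are strongly autocorrelated across radii, so the rank
correlation has far fewer effective degrees of freedom than K = 25 and
its null spread is wide. In consequence roughly 15–20% of CSR
localizations exceed the 0.4 threshold. This is a property of the
score definition (the same breadth is visible in published
coordinate-based-colocalization null histograms), not an implementation
artifact — the implementation agrees with an independent O(n²)
brute-force evaluation of the definition to ~1e-16. Percent-colocalized
values should therefore always be compared against a matched null or a
contrast condition, never read as absolute fractions; the package's own
tests rely on the coloc_fraction = 1 vs 0 contrast (≈ 70% vs ≈ 6%),
which is large and stable.

## Cluster detection and interaction classes (Clus-DoC track)

DBSCAN (default eps = 20 nm, min_pts = 3, counting the point itself)
finds per-channel clusters. The implementation uses kd-tree
neighbourhood queries and a two-pass rule — core points are grouped
into connected components, then each border point joins the cluster of
its lowest-id core neighbour — making labels independent of the input
point order.

Retained clusters must have ≥ 5 localizations (5-LO) or ≥ 10 (FLAP);
the higher FLAP floor reflects its homotrimeric stoichiometry (≥ 3
functional units). Clusters are single-channel objects; classification
counts the cluster's own members with DoC ≥ 0.4: NIC (0 interacting),
LIC (1–4), HIC (≥ 5). All thresholds are config-exposed.

Morphometrics: convex-hull contour (counterclockwise vertices, shoelace
area); density = members/area; relative density = mean over members of
(count within 20 nm including the focal member)/(π·20²), divided by the
cluster-average density. Collinear clusters get area 0, are kept for
counting and classification, and are excluded from area/density
averages. Note that the focal-member term makes relative density exceed
1 when the expected 20 nm neighbourhood count is small: the
"uniform ≈ 1" reading holds for clusters dense enough that ~10+ members
fall within 20 nm, which DBSCAN-retained nanoclusters (eps 20 nm,
min_pts 3) generally are, while a sparse uniform cloud is inflated by
the 1/(π·20²) self term.

Per-ROI summaries report class counts, mean areas, per-channel mean
member counts and relative densities, and the percent of interacting
localizations that sit in retained clusters (undefined — reported as
missing, not 0 — when a channel has no interacting localizations).
When aggregating across ROIs, classes contributed by fewer than 3 ROIs
are flagged excluded. The trimer helper floor-divides a localization
count by 3.

## Unbiased cluster analysis (VBMS track)

1. **Pre-partitioning.** eps is the 99.9th percentile — linear
   interpolation between order statistics, stated explicitly because
   the far tail is convention-sensitive — of exclude-self
   nearest-neighbour distances. DBSCAN with that eps and min_pts = 2
   (the most conservative non-trivial setting; its noise points are
   exactly the "single isolated points", which are removed) splits the
   data into islands that are processed independently.
2. **Bandwidths.** Fixed mode assigns every point the same isotropic
   bandwidth (default 250 nm) and is the reproducible reference
   configuration. Auto mode derives per-point diagonal bandwidths from
   the per-axis spread of the k = 50 nearest neighbours (floored at
   1 nm per axis to survive degenerate geometry), rescaled so the
   median bandwidth equals a global scale; candidate scales on a
   geometric grid are each evaluated by running the clustering, and the
   scale whose retained-cluster count changes least against its grid
   neighbours wins (ties to the smaller scale). This stability selector
   is this package's own construction — the automatic selector the
   track is modelled on is not fully specified by its description —
   and auto mode falls back to fixed (with a logged warning) below
   k + 1 points.
3. **Mean shift.** m ← Σ w_j x_j / Σ w_j with Gaussian weights using
   each *data point j's own* bandwidth pair, summed over points within
   4× max(h_j,x, h_j,y) of the current mean. Kd-tree radius queries are
   exact within the stated radius (truncation is a performance
   contract, not an approximation of membership). Iteration stops when
   the shift is below 0.1 nm or at 500 iterations (non-convergence is
   logged and the last position kept).
4. **Mode grouping.** Converged positions within merge_tol (default:
   median bandwidth / 2 — not fixed by the source description,
   config-exposed) are merged by single linkage; groups with > 3 member
   localizations become clusters with convex-hull area and density =
   members/area. Islands are mean-shifted separately but mode grouping
   runs on the union, so the partition cannot split a genuine cluster.

## Synthetic scenes

The generator stands in for microscope data and provides per-localization
ground truth (molecule id, parent cluster or background, shared-parent
flag). It emulates:

- CSR backgrounds (uniform over a polygon, by rejection sampling);
- Thomas processes: uniform parents, Poisson(μ) offspring at
  parent + isotropic Gaussian(σ_cluster); offspring straddling the ROI
  edge are kept — ROI filtering is a separate explicit step;
- the two-channel compound model: a fraction `coloc_fraction` of
  channel-A parents is reused by channel B (true colocalization);
  molecules blink Geometric(1/blink_mean) times (memoryless on/off
  approximation, support ≥ 1), and every localization carries
  isotropic Gaussian localization error σ_loc;
- a ring ROI: the annulus is rendered as one simple polygon via a
  ~1e-6 rad radial seam (a zero-width seam would self-touch); the area
  deficit is far below the 2% tolerance at ≥ 64 vertices.

Defaults emulate the imaged system: a 4–5 µm-radius nuclear-envelope
annulus, σ_cluster = 50 nm (hull areas of order 10⁴–10⁵ nm²),
σ_loc = 15 nm (typical dSTORM precision), blink_mean = 4, ~20 parent
clusters and ~100 background molecules per channel. One integer seed
drives a splittable generator (`SeedSequence.spawn`), so identical
seed + parameters give byte-identical scenes and adding channels does
not perturb earlier draws.

What the simulator does *not* model: PSF/camera noise, astigmatic 3D,
spectral crosstalk, drift, or the spatially correlated blinking of real
fluorophores. Passing tests therefore demonstrate correctness of the
algorithms under a clean generative model, not robustness to every
artifact of real acquisitions.

## Statistics and histograms

Point-weighted histograms weight each cluster by its localization
count; bins are [edge, next_edge) with the last bin right-closed,
out-of-range weight goes to a logged overflow tally, and frequencies
are normalized over in-range weight (they always sum to 1). Auto
binning is Freedman–Diaconis on the weighted sample (weighted IQR,
effective n from the weights). Group comparisons wrap scipy: Welch's
t (two groups, unequal variances), two-sample Kolmogorov–Smirnov,
one-way ANOVA with Bonferroni (pairwise pooled t, p × #comparisons
capped at 1) or Tukey HSD post-hoc — off-the-shelf plumbing, both
post-hoc variants provided since practice mixes them. Summaries can be
pooled across clusters (unbiased track) or across ROIs (Clus-DoC
track).

## Problem sizes and numerical choices

The test suite and the acceptance script run on desk-scale scenes —
300–2000 points per channel for calibrations, 10-seed recovery suites
of ~1000-point Thomas scenes — chosen so the whole suite completes in
well under a minute while keeping Monte-Carlo intervals tight.
Convergence and identity checks use: mean-shift tolerance 0.1 nm;
truncated-vs-untruncated agreement asserted at 1e-9 on blobs whose
diameter keeps truncation inactive; brute-force oracle agreement for
DBSCAN, nearest-neighbour distances, convex hulls and the NND quantile
asserted exactly or at double-precision round-off (~1e-12 relative,
the difference between kd-tree and naive distance evaluation).

## Known limitations

- DoC scores carry the broad null distribution described above; use
  contrasts, not absolute thresholded fractions.
- No edge correction: metrics for localizations within R_max of the
  ROI boundary are biased; with a guard-band ROI the bias disappears
  from reported points.
- Localizations over-count molecules by the blink factor; the trimer
  estimate is a stoichiometric upper bound, not a molecule count.
- Auto bandwidth selection is a heuristic stand-in; the fixed-250 nm
  configuration is the reference and is what all quantitative tests
  exercise.
- 2-D only; no temporal (per-frame) analysis.
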