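# Methods

## Model and procedure

The segmenter treats a preprocessed grayscale image as an unordered set of
1-D intensity samples $x_i \in [0, 255]$ and partitions them into $c$ fuzzy
clusters by minimizing

$$J_m = \sum_{i=1}^n \sum_{j=1}^c u_{ij}^m \lVert x_i - c_j \rVert^2 ,$$

with memberships $u_{ij} \in [0,1]$ summing to 1 per pixel.  The alternating
minimizer is the classical one: for fixed centers,
$u_{ij} = 1 / \sum_k (d_{ij}/d_{ik})^{2/(m-1)}$ (computed in ratio form on
squared distances, which is overflow-safe); for fixed memberships,
$c_j = \sum_i u_{ij}^m x_i / \sum_i u_{ij}^m$.  Each half-step is exactly
optimal for its block, so the objective trace is monotone non-increasing —
asserted as a test invariant.

The hybrid stage re-minimizes the same $J_m$ with a grey wolf optimizer over
candidate center sets (a position vector concatenates all $c$ centers;
fitness re-derives memberships optimally before evaluating $J_m$).  The pack
is seeded with exactly one wolf at the FCM solution; combined with elitist
leader retention this guarantees the hybrid objective never exceeds the FCM
objective on the same input — the property the whole design rests on, and a
strict test gate.  The two stages run sequentially (FCM to completion, then
GWO), not interleaved.

Hard labels are per-pixel membership argmax (ties to the lowest cluster
index); with $c = 3$ clusters on one intensity feature, clusters map to
tissue classes by brightness rank — darkest = nucleus (hematoxylin logic),
middle = cytoplasm, brightest = background.

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| clusters $c$ | 3 | — | nucleus / cytoplasm / background |
| fuzziness $m$ | 1.5 | — | membership softness; $m\to1$ is crisp k-means-like |
| FCM iterations | 5 (cap) | — | alternating rounds; early stop on center movement < `tol` |
| FCM `tol` | 1e-5 | intensity | center-movement convergence threshold |
| GWO agents | 5 | — | pack size (≥ 3 so alpha/beta/delta exist) |
| GWO iterations | 5 | — | exploration scalar $a$ ramps 2 → 0 over these |
| search bounds | [0, 225] | intensity | box for candidate centers, clipped per step |
| resize target | 800×600 | px | working resolution of the preprocessing chain |
| median window | 5×5 | px | camera-noise suppression, reflect padding |
| closing element | disk r=2 | px | fills dark pits smaller than the disk |

The 225 upper bound is kept as the package default even though 8-bit
intensities reach 255; it is configurable (`GwoConfig.upper_bound=255`) and
matters only if a cluster mean should exceed 225, which the targeted
three-population images do not produce.

The iteration counts are deliberately small — the method is designed to work
at a handful of alternating rounds — and both are caps, configurable upward.
The $a$-schedule uses denominator $T-1$ so both endpoints 2 and 0 are
attained within $T$ iterations.

## Initialization

FCM initialization is the one genuinely open design choice.  Two modes are
provided:

- `init="spread"` (default): initial centers evenly spaced over the
  per-feature data range.  On images dominated by one intensity population
  (background is ~90 % of a sparse smear), this reliably separates the three
  populations within the 5-iteration default cap.
- `init="random"`: a seeded random row-stochastic membership matrix.  This
  starts all centers near the global mean; symmetric starts of that kind
  need many more iterations to break apart on heavily imbalanced images, so
  it is not the default.

GWO draws fresh $r_1, r_2$ per agent, per leader, per dimension, per
iteration from a single seeded generator owned by the run; everything
downstream (labels included) is bit-reproducible under a fixed seed.

## Numerical choices

- Coincident point/center (zero distance): full membership split equally
  among the coincident centers — removes the division singularity
  deterministically.
- A cluster with zero total membership weight raises
  `DegenerateClusterError` rather than producing NaN centers.
- A constant image yields coincident centers; the result reports
  `n_effective_clusters = 1` in provenance instead of erroring.
- Out-of-bounds GWO positions are clipped componentwise; FCM centers are
  clipped into the box before seeding the pack.
- Paired *t*: all-zero differences give $t=0,\,p=1$; nonzero differences
  with zero variance have no defined statistic and raise
  `DegenerateTestError`.
- Partition entropy uses the natural log by default ($V_{pe}\le\ln c$, which
  exceeds 1 for $c=3$); pass `log_base=c` to normalize the maximum to 1.
- Davies–Bouldin and Calinski–Harabasz are computed on crisp argmax labels
  with crisp centroids (scikit-learn backends, cross-checked in the tests
  against naive double-loop implementations).

## Synthetic images

The generator emulates the three-population intensity structure of stained
smears: dark nucleus disks (mean 40) concentric inside cytoplasm disks
(mean 130) on a bright background (mean 220), additive Gaussian noise
(σ = 8, clipped to [0, 255]), cells allowed to overlap with later cells
painted on top.  Defaults: 400×300 px, 10 cells, nucleus radii 8–12 px,
cytoplasm radii 16–24 px — a sparse smear with ~90 % background, which is
the regime that stresses initialization hardest.  Accuracy against the exact
mask is computed after optimal bijective label matching (Hungarian
assignment), so cluster numbering is irrelevant.

What the generator does **not** model: chromatin texture, H&E color physics,
stain and illumination variation, defocus blur, or touching-cell boundary
ambiguity.  Passing tests therefore demonstrate correct recovery of
well-posed intensity populations and the hybrid's optimization guarantees —
not performance on real slides, where intensity overlap between nuclei and
other dark objects is exactly the hard case.

## Problem sizes

Tests and the acceptance script run the full pipeline on 400×300 synthetic
images (120 000 pixels; 20 images for the dominance gate, 10 for parameter
recovery) and down-scaled 120×90 variants where only behavior, not scale, is
under test.  These sizes were chosen to exercise the imbalanced-background
regime while keeping a full suite run in well under a minute of compute.

## Known limitations

- Clustering uses one grayscale feature; color or texture features would be
  needed to separate objects with similar luminance.
- Five GWO iterations with five agents is a very short search; the hybrid's
  value here is the never-worse guarantee plus occasional escape from poor
  FCM optima, not a thorough global search.  Both budgets are configurable.
- No instance separation or cell counting: output is a per-pixel tissue
  class map.
- The paired-comparison workflow applies no multiple-testing correction
  across the four indices, matching the evaluation design it reproduces.
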