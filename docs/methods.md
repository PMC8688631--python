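# Methods

## Resection geometry

The tibial mechanical axis joins two user-supplied landmarks, the proximal
tibial center and the ankle center; its unit direction points distally.  The
resection plane sits `depth_mm` (default 6 mm) below the lateral tibial
plateau along that direction, and its normal is the axis direction rotated
by `posterior_slope_deg` (default 7°) about the mediolateral axis, with the
rotation sense chosen so the posterior edge of the plane drops distally.
Landmark placement is deliberately an input: reconstructed CT meshes carry
no canonical anatomical frame, so the proximal/ankle centers and a
medial-side marker must be supplied.  The lateral plateau point and the
mediolateral direction are derived (most proximal vertex on the lateral
half; the medial-marker → axis component perpendicular to the axis).

Slicing delegates the raw triangle/plane intersection to `trimesh`; the
resulting segments are chained into loops by clustering endpoints within a
1e−3 mm gap tolerance (union–find), and the largest closed loop by enclosed
area wins — smaller loops (fibula remnants, noise shells) are discarded.
The loop is projected onto the in-plane frame: +x is medial→lateral with the
sign fixed so the medial marker lands at negative x (left and right tibiae
share one canonical frame, justified by the study's left/right symmetry);
+y is posterior→anterior, derived from the in-plane projection of the
proximal direction when the slope is nonzero and from `ml × normal` at
exactly zero slope.  Vertices interior to straight runs (wall-diagonal
crossings on prismatic meshes) are dropped; loops are returned
counterclockwise.  STL vertices closer than 1e−6 mm are merged on load.

## Measurement conventions

* **ML** — extent of the contour along x.
* **AP** — length of the vertical chord at the ML midpoint.  The chord must
  cross the contour exactly twice after merging crossings closer than
  1e−6 mm; anything else raises an error rather than guessing.
* **MAP / LAP and CM / CL** — the condylar AP line runs through the
  *posterior-most point* of the half-contour on each side of the AP line;
  the width is the full vertical chord there and CM/CL are the distances of
  those lines from the AP line.  A "maximal chord over the half" reading was
  rejected: on real tibiae the chord at the ML midpoint (= AP) exceeds the
  lateral condylar width, so a max-chord rule could never report LAP < AP.
  The posterior-extreme rule is self-consistent, anatomically grounded (the
  posterior condyles are the posterior extremes; the intercondylar fossa
  sits between them), and reproduces the published summary values.  Its
  localization precision is bounded by the contour vertex spacing, which is
  why the CM/CL stability under 0.37 mm resampling is quoted as ±0.25 mm
  rather than a relative error.
* **MAR / LAR** — contour points in the outer mediolateral quarter of each
  side lying anterior of the condylar chord's vertical midpoint are fitted
  with a least-squares circle: a Kåsa algebraic seed followed by at most 50
  Gauss–Newton steps on the geometric residual (convergence 1e−10 mm).  On
  noiseless arcs of ≥ 20° span the fit is exact to 1e−9 mm.
* **AR** — ML/AP, recomputed (never stored independently).

All measurements are translation invariant; mirroring swaps the
medial/lateral labels.

## Synthetic contour generator

A contour is built from an anterior (top) and posterior (bottom) boundary
over the mediolateral span so that measurement recovers the eight generator
parameters essentially exactly:

* the anterior boundary over each outer quarter is an exact circular arc of
  radius MAR (medial) / LAR (lateral) whose west/east pole forms the
  contour tip, so the arc also rounds the tip; the arc is additionally
  extended a short way below the pole so that every point that can enter
  the anterior-radius selection lies on the circle;
* the posterior boundary attains its per-half minimum exactly at x = −CM
  and x = +CL, where the vertical chords equal MAP and LAP; a 3 mm bump at
  the midline emulates the intercondylar fossa (so the AP chord is measured
  notch-to-tubercle, as on real cuts);
* everything else is shape-preserving monotone (PCHIP) interpolation, which
  cannot overshoot its control values, and the assembled loop is verified
  to be a simple polygon.

Shape constants (3 mm notch, 2 mm anterior drop to the quarter line, 1 mm
arc dip) are fixed package choices, not fitted quantities.  Feasibility
requires, beyond positivity: MAP, LAP > AP/2; CM, CL strictly inside the
central half-span; MAR, LAR > ML/4 (the arc must span its quarter) without
lifting the tip above the condylar mid-height.  Infeasible vectors raise;
the population sampler rejects and redraws them.

## Population model

Each gender is a multivariate normal over the eight parameters with the
published per-gender means and SDs.  The study prints only *pooled*
correlations, which are inflated by the gender mean gap, so sampling each
gender with the pooled r would overshoot it.  The within-gender correlation
for each pair is therefore calibrated by the equal-mixture identity

    r_within = (r_pooled·σp_a·σp_b − g_a·g_b) / (σw_a·σw_b),

where g is half the male–female mean gap and σp² = mean within-variance
+ g²; applying this per gender with that gender's SDs reproduces the pooled
covariance exactly.  The ten published pairs use their printed r; the
remaining pairs default to a pooled r of 0.45 (the middle of the published
0.17–0.74 range for unlisted pairs; configurable).  The assembled matrix is
projected to the nearest positive-semidefinite correlation matrix
(eigenvalue clipping at 1e−8, diagonal renormalized).

Each subject owns one feasible parameter vector; each side adds independent
N(0, 0.2 mm) noise per parameter (so paired side tests are non-degenerate
null tests), and every record in the output table is *measured* from its
generated contour.  Sampling is deterministic under the spec seed; the CLI
fans a single master seed out to per-stage seeds by hashing the stage name.

What the generator emulates: the first and second moments and pairwise
correlations of the published population, exact parameter recovery, and
left/right exchangeability.  What it does not: real cortical outlines
(asymmetric posterior condyles, tubercle shape), osteoarthritic remodeling,
cartilage, and any higher-order structure of the real data beyond a
Gaussian with the printed moments.  Consequently, quantities that depend
only on means/SDs/correlations reproduce well, while quantities sensitive
to the full joint shape of the real point cloud need not — see Limitations.

## Statistics

ICC(2,1) (two-way random effects, absolute agreement, single measurement)
is computed from the two-way ANOVA mean squares; the study does not name
its ICC variant, and this form is the standard choice for two observers
measuring repeated replicates (pingouin's ICC(A,1) is the test-suite
cross-check).  Independent t-tests default to pooled variance (the reported
SPSS style), with Welch available by flag; a pooled-variance two-sample t
from summary statistics supports comparisons against other published
populations.  All p-values are two-sided; no multiplicity correction is
applied, matching the source analysis.  Zero-variance degeneracies follow
the conventions t = 0, p = 1 (no difference) and |t| = ∞, p = 0 (constant
nonzero difference).

## Sizing and fit

K-means runs on raw (ML, AP) millimetres (no standardization — the axes
share units) with k-means++ seeding, 10 restarts, Lloyd iterations to a
1e−6 mm centroid shift, and empty clusters reseeded to the farthest point.
The WSS curve over k = 2..12 is min–max normalized on both axes and the
elbow is the point farthest from the chord joining the curve's endpoints,
ties to the smallest k.  The cluster count is chosen on the pooled data and
K-means is then re-run per gender, reproducing a single optimum count with
gender-specific dimensions; centroids are rounded to integer millimetres
and sorted by AP.

Fit is point-based: nearest size by Euclidean distance in the (ML, AP)
plane (ties to the smaller index), per-axis signed mismatches classified as
absolute overhang (> 2 mm), relative overhang (0–2 mm), acceptable
(−2–0 mm), relative underhang (−5 to −2 mm) or absolute underhang
(< −5 mm), boundaries assigned to the less-severe class; coverage is the
share of knees within a 2.5 mm circle of their nearest size.  True plate
outline overlap and rotational placement are out of scope.

## Problem sizes and numerical choices

The default study population is 240 subjects per gender with two sides each
(960 measured contours of 720 points; generation plus measurement takes a
few seconds).  Tests draw 200 random vectors for the round-trip property,
10⁴ simulations for the type-I calibration, 10⁵ permutations and 10⁶
mixture draws for the statistical oracles, and exhaustive 3¹⁰ partition
enumeration for the K-means oracle.  Kåsa + Gauss–Newton circle fitting,
PCHIP interpolation and eigenvalue clipping are the only numerically
delicate steps; their tolerances are stated above.

## Limitations

* The elbow rule applied to the pooled synthetic population selects k = 4:
  a two-gender Gaussian mixture yields a smooth, featureless WSS curve,
  whereas the study's real data produced a bend at seven.  A cluster count
  read off a WSS curve is only as real as the structure in the data; the
  deterministic elbow geometry itself is verified exactly on a constructed
  curve.
* Coverage of the moment-matched population by the published seven-size
  table is ≈76% (female) / ≈81% (male), not the published ≈96%/95%.  Even
  optimally placed 7 circles of radius 2.5 mm cover only ≈93% of a Gaussian
  cloud with the published within-gender SDs and the calibrated
  r(ML, AP) ≈ 0.49, and two published size rows lie far off the gender
  regression trend.  The published coverage therefore reflects a tighter
  real point cloud than its printed moments imply.
* The generator's condylar minima are symmetric V-shaped wells; real
  posterior condyles are broader and may shift the posterior-extreme line
  under heavy smoothing or sparse meshes.
* Cartilage is not modeled and only the single 6 mm resection level is
  measured.
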