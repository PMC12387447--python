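# Methods

This note records the measurement model, the algorithmic choices that were
genuinely open, the synthetic phantom's scope, and the numerical details a
maintainer would need. Units are mm, radians and 8-bit intensities; image
coordinates are 0-based (row, col) with row 0 at the top.

## Measurement model

A laser sheet intersects the camera's optical axis at triangulation angle θ.
With image distance M₁ (lens to sensor), object distance M₂ (lens to the
reference plane) and a sensor-plane stripe displacement n, similar triangles
give the surface height

    h = M₂ · n / (n + M₁ · tanθ),

strictly increasing in n and bounded by M₂. Pixel shifts convert to
sensor-plane mm through the pixel pitch; image columns convert to lateral mm
through a per-calibration lateral scale; the scan axis position of frame i is
i · (conveyor speed / frame rate). The standard radial (k₁,k₂,k₃) +
tangential (p₁,p₂) lens model is inverted by fixed-point iteration
(10 iterations, 10⁻⁸ px tolerance) when calibration provides coefficients;
synthetic frames are rendered distortion-free and skip it.

The default desk-scale camera (`phantom.default_camera`): M₁ = 25 mm,
M₂ = 150 mm, tanθ = 0.3, pixel pitch 5 µm, lateral scale 0.15 mm/px,
640×480 frames, reference row 420, conveyor 20 mm/s at 30 fps. With these
constants the dome's 25 mm of height spans ≈300 rows of stripe shift, i.e.
≈0.08 mm of height per row — so half-pixel centerline quantization
contributes ≈0.03 mm RMS to reconstructed heights, and sub-pixel refinement
proportionally less.

## Stripe segmentation

Gamma correction s = c·rᵞ is applied to the HSV value channel on
[0,1]-normalized intensities and re-quantized to 8 bits (round-half-up)
before Otsu thresholding; γ defaults to 8 and c to 1 (the rescaling absorbs
any constant). The Otsu step maximizes the inter-class variance exactly over
all 255 candidate thresholds, skipping thresholds with an empty class and
taking the smallest maximizer on plateaus. A constant image has no valid
split and is rejected. Connected components (8-connectivity) smaller than
5% of the largest are removed by default; setting `min_area_frac=0`
disables the filter.

## Centerline extraction

Thinning uses the Zhang–Suen two-subiteration rules (via scikit-image).
On the skeleton, the 8-neighbourhood count N_p classifies pixels: endpoints
(N_p = 1), interior (N_p = 2), branch points (N_p > 2); isolated pixels
(N_p = 0) are dropped. Pruning keeps the **main branch**, defined as the
longest endpoint-to-endpoint *simple path* in the skeleton's 8-adjacency
graph — the same quantity an exhaustive path enumeration computes, which is
how the tests check it. Tie-breaks are deterministic: endpoints are visited
in row-major order, neighbours in the fixed order E, SE, S, SW, W, NW, N,
NE, and only strictly longer paths replace the incumbent. Note that around a
right-angle junction the longest simple path may legitimately pick up one
pixel of a side arm via a diagonal step; downstream stages are insensitive
to this single-pixel detour.

Sub-pixel refinement replaces each path point by the intensity centroid
sampled (bilinear) along the local path-perpendicular within ±half_width
pixels. It is off by default at the library level but the pipeline enables
it (half_width 6): integer skeletons cut the corner of deep, narrow stripe
dips, and the perpendicular centroid recovers most of that shortfall.

The grayscale centre-of-gravity baseline computes, per image column, the
intensity-weighted mean row over the mask. Two bright regions in one column
fold into a centre between them, which is exactly the failure mode the
branch-pruning design addresses; the acceptance suite reproduces the
resulting accuracy ordering on branch-artifact frames.

## Reconstruction and registration

Profiles are stacked at their nominal conveyor positions by default. ICP
(point-to-point, k-d-tree correspondences, closed-form SVD update, stop when
the RMS change < 10⁻⁶ or 50 iterations) is available both as a standalone
aligner and inside `merge_profiles`. Two registration caveats are inherent
to single-stripe scanning and are handled explicitly:

- **Degeneracy along the scan axis.** Consecutive profiles are different
  y-slices with no overlap, so unconstrained ICP collapses the scan spacing
  by pulling each profile onto its predecessor. `merge_profiles` therefore
  treats ICP as a *refinement of the conveyor prior* and rejects corrections
  whose translation exceeds half the conveyor step or whose rotation exceeds
  2°, or whose residual exceeds 5× the median pair residual, falling back to
  the prior with a warning. On exact-kinematics data the gate rejects all
  corrections and ICP-on equals nominal stacking.
- **Grid aliasing.** For whole-cloud alignment, identity initialization can
  settle into local minima one profile-spacing off; `icp_align` therefore
  seeds from a centroid + principal-axes coarse alignment (axis signs chosen
  to keep the rotation minimal) unless an explicit init is given.

## LSPIA curve fitting

Cubic B-splines on clamped knot vectors, uniform interior knots on [0,1],
normalized chord-length parameters. The collocation matrix B[j,i] = N_i³(u_j)
is built with scipy's B-spline basis; the LSPIA update
P^{k+1} = (I − μBᵀB)P^k + μBᵀQ uses the optimal step μ = 2/(λ₀+λ_n) from the
extreme eigenvalues of BᵀB (symmetric eigensolver) and stops when the largest
control-point displacement drops below tol (10⁻⁸ default). The fixed point
satisfies the least-squares normal equations, which the tests verify against
a direct solve; the iteration contracts with spectral radius
ρ = (λ₀−λ_n)/(λ₀+λ_n), checked against the eigenvalues of the iteration
matrix and, asymptotically, against the observed per-iteration error ratio.
Initial control points are taken from the data at uniformly spaced indices.
Rank-deficient collocation (λ_n = 0) yields ρ = 1 and a non-contractive
warning rather than an error.

## Ideal curve and groove detection

Cross-sections are y-bins of the cloud (bin width = conveyor step by
default), with points at or below a z-floor (0.5 mm) excluded as conveyor
plane/rim clutter and bins under 10 points dropped.

The **ideal curve** — the section as if no groove existed — is a trimmed
LSPIA fit: fit all points, discard points whose below-curve residual is more
than 3 robust (MAD) sigmas below the median, refit, and repeat (≤5 passes)
until no material outlier remains, never discarding more than `trim_frac`
(0.3) of the points in total. Two design points matter here. First, the
control count is deliberately small (8): stiffness is what prevents the
pass-1 spline from sagging into broad grooves before they can be trimmed
(measured sag at a groove centre: −0.75 mm with 12 controls, −0.19 mm with
8, on the default phantom). Second, a single trim-refit pass leaves the
groove shoulders in the fit and biases the ideal curve by ≈6% of the groove
depth; iterating the trim reduces the bias below 1%.

Deviations are measured along the **ideal curve's normals**: the curve is
sampled uniformly in parameter (400 samples, excluding a 3% margin at each
end where the spline is least constrained), the normal at each sample is the
minor eigenvector of the local point covariance (window of 9 samples,
de-meaned; the major eigenvector is the tangent), oriented away from the
section centroid, and cast against the measured section polyline up to
±10 mm. The signed distance to the first intersection is the deviation,
negative where the surface lies below the ideal curve. Note the normal is
the *minor* axis of point covariance — for points the major axis is the
tangent; treating the largest eigenvector as the normal is correct only for
gradient covariance.

Grooves are maximal runs of deviation < −τ (the sign restriction makes
reflection bumps, which deviate positively, invisible to the detector; an
absolute-value mode exists). Runs shorter than `min_run` samples (5 ≈ 1.2 mm
of contiguous extent at default sampling) are rejected: a real groove
crossing is never a hairline. Each run reports its deepest sample, refined
by parabolic interpolation of the deviation around the minimum. Hits are
linked across sections by greedy nearest-neighbour tracking in the x–z plane
(gate 3 mm); after linking, hits whose measured depth is under 0.6× the
track's median depth are dropped — a physical groove has near-constant
depth, and half-depth measurements are unresolved crossings whose lateral
position is unreliable (observed displacement ≈0.5–0.7 mm). Tracks with
fewer than 5 supporting sections are discarded.

The threshold τ defaults to 0.8 mm (≈40% of the default groove depth, well
above the noise-induced deviation floor of ≈0.1 mm); `calibrate_threshold`
reproduces the sweep procedure — run detection over a τ grid, score each
against truth lines (mean matched distance, misses penalized), return the
error-minimizing τ, smallest on ties.

## Synthetic phantom

The phantom emulates what the method needs from a citrus scan and nothing
more: a convex fruit (half-ellipsoid dome, default 40 × 18 × 25 mm half-axes)
with n angular grooves of constant depth (2 mm) and Gaussian azimuthal
profile (σ = 0.12 rad, ≈2–4 mm arc width at mid-flank), tapered to zero at
the apex where azimuth is undefined (taper radius 1.8 mm); stripe frames
with Gaussian cross-profile (σ = 2.5 px, peak 220) in the green channel,
additive Gaussian sensor noise (σ = 2), and with 10% per-frame probability
one artifact — a bright blob or a spur branch attached to the stripe — to
exercise the segmentation filter and branch pruning. All randomness flows
from one seeded generator; identical spec + seed is bit-identical output.

The groove width default is a resolvability compromise documented here
deliberately: azimuthal grooves are geometrically narrow near the apex
(σ_x ≈ σ_φ·r), and crossings under ≈6 px of lateral extent fall below what
a thresholded stripe plus thinning can resolve; far from the apex the same
grooves cross flank sections obliquely and become very broad. Real
separation lines are a few mm wide at mid-fruit, which 0.12 rad reproduces.

What the phantom does **not** model: photorealistic peel texture and oil
glands, specular BRDF, lens distortion (rendered distortion-free), occlusion,
motion blur, and conveyor-speed jitter. Passing the end-to-end suite
therefore demonstrates the geometric chain — segmentation through line
localization — under realistic noise, artifacts and quantization, not
robustness to every optical effect of real fruit.

The ground truth contains per-frame stripe centre rows, one 3D polyline per
groove tracing the depression bottom from where the apex taper reaches half
depth out to the rim, and per-section ideal (grooveless) dome curves.

## Evaluation conventions

Matched MAE/RMSE and similarity follow the one-to-one matching realization:
both lines resampled to equal counts by normalized arc length (at least 50
points), orientation aligned (polylines carry no canonical direction), truth
clipped to the prediction's y-span before matching. Similarity is the cosine
of the flattened xy-projected position sequences — the printed variant
without the square-rooted denominator is available behind a flag but is not
1 for identical inputs, so the cosine form is the default. The
"fraction within 4 px" statistic uses each detected point's distance to the
truth polyline, converted to pixels by the lateral scale: index-matched
resampling adds arc-length offsets unrelated to detection accuracy, while
point-to-line distance measures exactly "how far from the groove bottom is
each detected point". The centerline statistic R = √(Σ(xᵢ−x̄)²/n) is the
spread of point-to-fitted-curve distances about their mean (a conventional
RMS-about-zero variant exists behind `about_zero=True`); orthogonal
distances are minimized over the curve parameter by dense sampling (2000)
plus parabolic refinement of the squared distance.

## Problem sizes and runtime

Default problem sizes: 60 frames of 640×480 for the end-to-end runs
(≈14 s each), 24 frames for noiseless round-trip checks, 20 frames for the
centerline comparison, 100 tree skeletons ≤ 500 px for the pruning oracle,
m = 200 / n = 15 for the LSPIA oracle. The full test suite runs in about
two minutes; `scripts/acceptance.py` in about 90 s.

## Known limitations

- Grooves occluded from the camera/laser (fruit sides beyond the silhouette)
  are invisible by construction; the method detects what the stripe sees.
- Near-apex groove crossings below the stripe's lateral resolution are
  rejected by the depth-consistency filter rather than localized; lines
  therefore start a few mm from the apex.
- The ICP stage adds nothing on exact conveyor kinematics (the gate reduces
  it to the prior); it becomes useful only with an imperfect prior and
  overlapping geometry, which single-stripe scans do not provide.
- `calibrate_threshold` needs ground truth (phantom or annotation); on real
  data τ must come from a calibration run or the default.
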