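# Methods

## Pipeline overview

`run_pipeline` executes, with no user interaction:
noise reduction → Sobel gradient magnitude → automatic marker extraction →
marker-controlled watershed flooding → mass-region selection → Chan–Vese
level-set refinement → optional post-processing (hole filling + largest
8-connected component, on by default and logged) → optional evaluation
against a reference mask. Both the coarse (watershed) and final (level-set)
masks are returned. Every stage is deterministic; reruns are bit-identical.

All images are `(row, col)` 0-based arrays, 8-bit at I/O boundaries and
float during processing; every float→8-bit conversion rounds
half-away-from-zero. An optional block-mean downsampling stage
(`io.downsample_factor`, default 1 = native ROI resolution; the standalone
`downsample` function defaults to factor 4) trades resolution for speed;
when active, metrics are counted at processing resolution with the
reference reduced by majority vote (ties to foreground).

## Noise reduction

Mammographic film noise makes the gradient surface rough, which multiplies
spurious prominence peaks and hence watershed markers. Three filters are
provided (`denoise.method`):

* `mean` — box average, default 5×5, edge-replicated borders;
* `gaussian` — default σ = 2 px, kernel truncated at 4σ;
* `anisotropic` (default) — Perona–Malik diffusion, explicit 4-neighbor
  flux-form scheme with mirrored boundaries:
  per step, I += rate·Σₙ g(|dₙ|)·dₙ over the four neighbor differences dₙ.
  Defaults: 15 iterations, rate 0.25 (the explicit-scheme stability limit),
  conduction g(s)=exp(−(s/κ)²) with κ = 30 gray levels (≈2× the standard
  phantom noise σ, well below the mass contrast, so noise diffuses while
  the mass edge does not). The flux form makes the intensity sum an exact
  invariant, and since rate·Σg ≤ 1 each update is a convex combination of
  the neighborhood, so per-step extrema never expand.

## Marker extraction

Foreground (candidate-mass) markers are the 8-connected components of the
extended-maxima transform of the denoised image — bright plateaus rising
at least `h` = 20 gray levels above their surroundings — with components
under `min_area` = 20 px discarded. The background marker is the set of
sub-Otsu pixels at city-block distance ≥ 15 px from every foreground
component. Two deterministic fallbacks handle degenerate inputs: the
brightest pixel if no foreground component survives, and the image border
frame if the background set is empty.

The prominence threshold was chosen between the phantom's texture
amplitude (10) and mass contrast (80): genuine masses always seed a marker,
while noise-induced prominence peaks seed markers exactly when noise
survives the filtering stage. This is the design point of the recipe — an
undenoised standard phantom yields ≈19 markers against ≈3–6 after
filtering, so the over-segmentation the watershed literature attributes to
noise is visible and measurable as the region count. An earlier candidate
recipe based on opening/closing-by-reconstruction with a disk-10
structuring element was rejected after measurement: on raw noise the
erosion floor is nearly constant and the reconstruction returns an almost
flat surface whose only regional maximum is the mass itself, so it
*inverted* the filter ordering by acting as a (very strong) denoiser
inside the marker stage. It remains available as an optional pre-smoothing
via `markers.disk_radius` (default 0 = off), as does a marker erosion step
(`markers.erosion_radius`, default 0).

## Watershed flooding

`marker_watershed` treats the gradient magnitude as topography and floods
it from the markers with a priority queue ordered by
`(height, insertion counter)`: marker pixels enter at their own gradient
height in row-major order; the popped pixel passes its label to any
unlabeled 8-neighbor, which enters at `max(own height, popped height)`.
Ties are strictly FIFO, so the labeling is a deterministic total partition
of the image into one catchment basin per marker — no one-pixel dam label,
since the level set only needs a region mask and boundaries are
recoverable as label transitions. The implementation is verified against
an independent brute-force flood (exhaustive minimum scan over a plain
list) on hundreds of random small instances.

The mass is selected among the foreground-seeded basins as the one with
the highest mean original intensity (ties: larger area, then smaller
label).

## Level-set refinement

The Chan–Vese functional is minimized with the smooth global
regularization H_ε(z) = ½(1 + (2/π)·arctan(z/ε)), δ_ε = H_ε′, ε = 1 px,
which keeps all level sets active so interior holes can be detected
without reinitialization (an optional signed-distance reinit every N
accepted steps exists and is off by default). Intensities are min–max
normalized to [0, 1] inside the module so the default weights are
scale-free: λ₁ = λ₂ = 1, μ = 0.1, dt = 0.5, max 200 iterations.

φ is initialized as the signed Euclidean distance of the coarse mask with
the interface midway between pixel centers (boundary pixels at ±0.5) —
with the interface on pixel centers the lattice co-area sum
Σ δ_ε(φ)|∇φ| samples δ only at |φ| ≥ 1 and underestimates a disk perimeter
by ≈16%, while at half-integers it is ≈tanh(π)-unbiased.

Each iteration updates c₁, c₂ as H_ε-weighted means and steps along
δ_ε(φ)·(μ·curv(φ) + λ₁(I−c₁)² − λ₂(I−c₂)²), the descent direction of the
regularized functional under the φ<0-inside sign convention (a pixel
resembling the inside mean is pushed negative; the length term shrinks the
contour). Curvature uses central differences with a 1e-8 denominator
guard. Two pieces of step control:

* the force field is normalized to unit maximum amplitude, making `dt` the
  largest per-step φ displacement in pixel units (the raw δ-damped force
  on [0,1] intensities is otherwise far too small to move the contour);
* backtracking: a step is accepted only if the *regularized* energy (data
  terms weighted by H_ε) does not increase by more than 1e-6 relative,
  else dt is halved. The hard-partition energy exposed by `energy()` is
  piecewise constant in the data terms between sign flips and therefore
  unusable for line search — it cannot see a pixel approaching its flip —
  so `energy_history` records the regularized functional, which is
  monotone by construction.

Evolution stops when, over a 5-iteration window, both the fraction of
pixels changing sign and the fraction still moving strictly toward the
zero level fall below `tol` = 0.001 (at a true fixed point every pixel
moves away from the contour, so an exact two-region partition stops within
5 iterations), or at `max_iter`, or when one region empties (degenerate:
the last valid state is returned flagged, and the pipeline falls back to
the coarse mask with a warning).

On ideal two-level input with the watershed initialization the refinement
recovers the generating disk exactly. From arbitrary rough
initializations, recovery is near-exact but 1–2 boundary pixels can freeze
in a local minimum of the regularized flow; and on *soft* boundaries the
optimum of the functional sits where intensity crosses the (c₁+c₂)/2
midline, which is the model's definition of the boundary, not necessarily
a reference radiologist's.

## Evaluation metrics

From pixel counts TP, FP, FN (TN deliberately unused — in an ROI the
background dominates and says nothing about the contour):

Hitting = TP/(TP+FN), Missing = FN/(TP+FN), OverHitting = FP/(TP+FN),
RelativeHitting = TP/(TP+FP), RelativeMissing = FN/(TP+FP),
Kappa = 2·Hitting/(2·Hitting + Missing + OverHitting) ≡ 2·TP/(2·TP+FP+FN),
the Dice coefficient.

All ratios are computed unrounded; the report view rounds to 2 decimals
half-away-from-zero. Kappa is computed from the unrounded ratios (computing
it from pre-rounded ratios reproduces the same published 2-dp values on
all eight reference cases, but unrounded is the less lossy convention).
Note that OverHitting and RelativeMissing are ratios to *different*
denominators than their names suggest symmetry with: OverHitting may
exceed 1, and RelativeHitting + RelativeMissing = (TP+FN)/(TP+FP), not 1.

## Synthetic phantoms

`generate_phantom` renders
clip₀²⁵⁵(background + texture + contrast·sigmoid((r−d)/softness) + noise)
with ground truth d ≤ r, fully determined by an integer seed. The texture
field is seeded white noise smoothed with a σ = 16 px Gaussian and rescaled
to the requested amplitude — a minimal model of fibro-glandular clutter,
enough to provoke spurious watershed markers when undenoised. The standard
test suite is 20 phantoms (seeds 0–19), 256×256, radius 40 px, contrast 80,
softness 6, background 100, texture σ 10, noise σ 15 — a bright,
soft-edged, moderately noisy mass occupying ≈8% of the ROI.

What phantom results do and do not show: they validate the algorithmic
claims (marker control suppresses noise-induced over-segmentation;
anisotropic diffusion preserves the edge best; the level set refines the
watershed mask; the metric suite reproduces published values from counts)
under controlled conditions with exact ground truth. They do not model
spiculation, architectural distortion, overlapping vasculature or
compression physics, so they bound algorithmic behavior, not clinical
accuracy.

## Problem sizes and numerical choices

The test suite exercises the full pipeline at the native 256×256 phantom
scale (the filter comparison runs all four filters over the 20-phantom
suite once per session, ≈3 minutes); watershed correctness is proven
against the brute-force oracle on 200 random ≤8×8 grids, where exhaustive
scanning is tractable. Degenerate inputs (constant images, all-one masks,
empty regions, zero-marker maps) raise informative validation errors or
take documented fallbacks rather than propagating NaNs. Exit codes of the
CLI: 0 success, 2 validation error, 3 degenerate segmentation.
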