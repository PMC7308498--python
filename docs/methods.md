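# Methods

## Problem setting

Time-of-flight MR angiography renders flowing arterial blood bright against
suppressed background tissue. Radiologists read these volumes as
maximum-intensity projections (MIPs) of adjustable slab thickness; automated
analysis therefore has to work on 2D projections whose content depends on
that thickness. The package segments vessels on such projections and reads
per-vessel radii off the segmentation. All processing assumes bright vessels
on a darker background and intensities normalized to [0, 1] by the global
maximum.

## Pre-processing

Volumes are resampled to isotropic 0.23 mm voxels with bicubic interpolation
(negative overshoot clamped to zero) before projecting, so one pixel always
corresponds to 0.23 mm and radii in pixels have a fixed physical meaning. A
slab of thickness `t` centred on slice `c` is the half-open index range of
`round(t/s)` slices centred on `c` (`s` = slice spacing); a single-slice slab
is exactly that slice. Non-overlapping slabs tile the volume, so the
pixelwise maximum over a tiled series equals the full-volume MIP; the
"central" projection of a series is the slab containing the volume's central
slice.

## Adaptive scale selection

The core problem with fixed-ladder multiscale Frangi filtering is that the
cross-scale maximum lets large scales respond beyond thin vessels'
boundaries: thin vessels come out broadened, thick ones narrowed, and radii
read from the result are wrong.

The pipeline instead derives the admissible scales from the image itself:

1. Coarse vessel mask: intensity `≥ 0.5 × max` (the bright-vessel regime).
   If that is empty or covers more than 30% of the image, Otsu's threshold
   is used instead. Components smaller than 5 px are dropped as specks;
   components whose EDT radius exceeds `max_vessel_radius` (default 12 px =
   2.8 mm, beyond any artery calibre on a 0.23 mm grid) are excluded from
   scale planning as unsuppressed-background patches.
2. The 2D EDT of the coarse mask gives a radius estimate; the **local
   thickness** (inscribed-disk radius, quantized at 0.5 px) assigns every
   pixel of a radius-r vessel the value r, and background pixels inherit the
   value of the nearest coarse-mask pixel. This keys the scale ladder to
   radii ranges rather than to connected components — essential because a
   vascular tree is one component spanning all calibres.
3. Per pixel, the admissible ladder is `{0.8, 1.0, …, σ_max}` px with
   `σ_max = √radii_max` snapped up to the 0.2 grid and clamped to ≥ 0.8.
   The σ–radius relation deliberately grows sublinearly: smoothing at
   σ ≈ √r is enough to score a tube of radius r while staying too small to
   respond past its boundary.

The minimum scale 0.8 px and step 0.2 px follow the established practice for
vessels at this resolution; both are configurable.

## Vesselness and its parameters

At each scale the Hessian is computed with γ=2 scale-normalized Gaussian
derivative filters (responses multiplied by σ²), boundary mode "nearest" (a
linear background ramp then stays curvature-free at the borders), and a
zero-DC correction: the sampled second-derivative kernel's small nonzero sum
is removed so a constant image yields exactly zero curvature. Eigenvalues
are ordered |λ1| ≤ |λ2| and the standard 2D measure

V = exp(−R_B²/2β²) · (1 − exp(−S²/2c²)),  R_B = λ1/λ2,  S = √(λ1²+λ2²)

is set to zero wherever λ2 ≥ 0 (bright tubes curve downward across the
vessel). Defaults: β = 0.5 (conventional blob suppression) and c = "auto" =
half the maximum Hessian Frobenius norm over the image **across the whole
scale stack** (floored at 1e-8). Resolving c per scale would normalize every
scale's peak to the same vesselness and defeat scale selection, so the stack
shares one c. Ties in the cross-scale maximum go to the smaller σ, which
stabilizes the winning-scale map.

## Binarization

The vesselness map is binarized by seeded front propagation with speed equal
to the vesselness and acceptance region V ≥ 0.001. Because the speed is
strictly positive inside the acceptance region, the claimed set equals the
V ≥ 0.001 connected components that contain a seed, and it is computed that
way. Seeds are the union of (a) coarse-mask components of at least 50 px —
each detected vessel anchors its own front, and bright specks below the size
of any real vessel segment (≥ 2 px wide over ≥ 25 px) do not — and (b) the
99.5th-percentile pixels of nonzero vesselness, which keep the main tree
when poor background suppression merges the coarse mask into one excluded
patch.

## Radii quantification

The binary mask is thinned to a one-pixel 8-connected centerline
(topology-preserving skeletonization) and multiplied with the mask's EDT:
each centerline pixel carries its distance to the nearest background pixel,
i.e. the local vessel radius in pixels. Conventions chosen where several are
defensible:

- EDT boundary condition: the image border counts as background.
- Radius convention: the raw EDT value at the centerline (a tube rasterized
  with half-width r yields ≈ r, an odd-width discrete tube of width 2k+1
  yields k+1); no sub-pixel −0.5 correction is applied.
- Histograms default to unit bins from 0.5 to 10.5 px; out-of-range values
  go to a flagged overflow count. 1 px = 0.23 mm for mm conversions.
- Length sums unique 8-adjacency steps (√2 × pixel size for diagonals);
  volume is voxel count × voxel volume in ml.
- Bifurcations: 8-connected clusters of skeleton pixels with ≥ 3 skeleton
  neighbours count as one branch point each.

## Synthetic phantoms

The generator emulates randomly branching vascular trees: recursive binary
splitting from a root (default radius 6 px) with child radii = parent × 0.75
(±10% jitter, "varying widths"), bifurcation angles drawn from 20–50°,
branch length proportional to radius (16 px per px of radius), terminating
at 1 px radius, the image border, or the branch-count target (default 48 on
a 512² grid). All randomness flows from one integer seed; phantoms are
byte-for-byte reproducible.

Rendering: pixels within a segment's radius of its axis form the mask;
intensity is uniform (1 inside) or Gaussian across the cross-section
(exp(−d²/2(r/2)²)), uniform along the vessel — the line profile vessels show
on projections. A resize-erode degradation (block-average downscale by 2,
bilinear upscale, 3×3 grayscale erosion) emulates the partial-volume
softening and vessel thinning of TOF-MRA acquisition. Because the
degradation genuinely thins the vessels, the ground truth tracks it: the
binary mask passes through the same resize at the 0.5 level set followed by
binary 3×3 erosion, the centerline is restricted to the surviving mask, and
truth radii are the EDT of the degraded truth on the centerline. Without
degradation the truth is the exact rasterization with analytic radii.

Two further degradations reproduce common angiographic artifacts:

- **Column-wise Gaussian noise** with mean = sd = level gray values, level ∈
  {50, 100, 150, 200}, drawn independently per column. Levels are
  interpreted on a 12-bit gray scale (0–4095, the standard MR storage
  depth), i.e. sd 1.2–4.9% of the intensity range — the regime in which
  noise visibly degrades but does not bury the vessels. The scale is
  config-exposed (`gray_scale_max`); an 8-bit reading would make the noise
  sd up to 78% of the range, which no segmentation method could survive.
- **Horizontal background gradient**: a left-to-right linear ramp up to 75%
  of the maximum intensity, mimicking poor background suppression.

What the phantoms do **not** emulate: curved vessels (segments are
piecewise-linear), overlap/occlusion effects of true 3D projection, flow
artifacts, and intensity inhomogeneity along a vessel. Passing phantom tests
therefore demonstrates correctness of the scale-selection/radii machinery
under controlled geometry, not clinical-grade accuracy on real scans.

## Evaluation statistics

Dice, Jaccard, precision/recall/F (with an optional boundary tolerance in
px; at tolerance 0, F ≡ Dice), Lin's concordance correlation (population
moments; both-constant-equal-means → 1, one-constant → 0 with a warning),
the overlap/symmetric-difference error ratio (identical masks → flagged ∞),
and Bland–Altman bias with 1.96·SD limits. Volume-agreement CCC pairs
per-component pixel counts matched 1-1 by maximal overlap and falls back to
per-radius-bin centerline counts when fewer than two pairs overlap (a single
connected tree).

## Benchmark behaviour and known limitations

On the standard phantom conditions (radii 1–6 px, most branches 1–2 px,
resize-erode degradation) the adaptive pipeline reaches mean Dice ≈ 0.83
clean and ≈ 0.73–0.75 under noise level 100 plus the 75% gradient, Jaccard
≈ 0.71, boundary F (1 px) ≈ 0.95–0.97, volume CCC ≈ 0.92, with per-tube
radii errors ≤ 0.5 px down to 1 px radius; the fixed-ladder baseline scores
Dice ≈ 0.67 and 1.3–1.5 px radius error on thin tubes. The residual
boundary error of the adaptive pipeline is a ≈ 0.4 px halo inherent to
Gaussian-scale filtering at σ_min = 0.8 on vessels 1–2 px in radius; on
trees whose calibres are larger relative to the grid the overlap scores rise
accordingly. Heavy per-pixel noise (sd ≳ 4% of range) eventually percolates
across the 0.001 acceptance threshold and degrades segmentation for every
variant.

Out of scope by design: true 3D (non-projected) Hessian filtering, skull
stripping (pre-masked input is accepted), vessel-graph topology beyond
bifurcation counting, and surface-distance metrics.
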