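# vesselrad

Automated segmentation of arteries on MR-angiography maximum-intensity
projections (MIPs) and quantification of per-vessel radii, built around an
**adaptive-scale Frangi filter**: the admissible Gaussian scales of the
vesselness filter are chosen per vessel from a Euclidean-distance-transform
(EDT) radius estimate, so thin vessels are never broadened by large scales
and thick vessels are still filled.

## Who this is for

Researchers quantifying cerebrovascular structure from TOF-MRA (or similar
bright-vessel angiography): vessel masks, centerline radii maps, radii
histograms, total vessel volume/length, and bifurcation counts, for
projections of any slab thickness. A synthetic vascular-tree generator with
exact ground truth makes the whole pipeline testable without scanner data.

## The method

For a normalized 2D projection `I` the pipeline (all defaults shown) is:

1. **Coarse radii**: threshold at `0.5 · max(I)` (Otsu fallback), take the
   2D EDT; the local inscribed-disk radius `r(x)` estimates each vessel's
   radius.
2. **Scale plan**: per pixel, admissible Frangi scales are the ladder
   `σ ∈ {0.8, 1.0, …, σ_max(x)}` with `σ_max = √r` (snapped up to the
   0.2-step grid) — large σ only where a thick vessel actually is.
3. **Vesselness**: at each σ, Hessian eigenvalues `|λ1| ≤ |λ2|` of the
   γ=2 scale-normalized Gaussian derivatives give

   `V = exp(−R_B²/2β²) · (1 − exp(−S²/2c²))`, `R_B = λ1/λ2`,
   `S = √(λ1²+λ2²)`, `V = 0` where `λ2 ≥ 0`,

   with β = 0.5 and `c` auto-resolved to half the maximum Hessian norm over
   the whole scale stack; the per-pixel maximum over the admissible ladder
   is the adaptive vesselness.
4. **Binarization**: seeded front propagation (speed = vesselness) claims
   everything reachable from the detected vessels through `V ≥ 0.001`.
5. **Radii**: skeletonize the mask; radii map = EDT × skeleton (px, with
   1 px = 0.23 mm after the standard resampling); histograms, volume (ml),
   length (m) and bifurcation count follow.

`segment(img, mode="plain")` runs the conventional fixed-ladder Frangi
baseline for comparison.

## Worked example

```python
import vesselrad as vr

phantom = vr.generate_phantom(vr.PhantomSpec(seed=0))   # 49 branches, radii 1-6 px
for mode in ("adaptive", "plain"):
    mask, vmap, plan = vr.segment(phantom.image, mode=mode)
    s = vr.segmentation_scores(mask, phantom.truth_mask)
    print(mode, round(s.dice, 3), round(s.jaccard, 3))
```

prints

```
adaptive 0.853 0.744
plain 0.709 0.549
```

— the adaptive ladder keeps every branch at its true width, while the fixed
ladder broadens the thin ones (Dice 0.85 vs 0.71 against the exact truth
mask). `examples/` contains one short script per capability: segmentation,
radii quantification, noise/background robustness, projection-thickness
sweeps, and scan-rescan repeatability; each prints the numbers it computes
and what they mean.

A thin CLI wraps the same functions:

```bash
vesselrad phantom --seed 7 --out phantom/
vesselrad segment phantom/image.png --out seg/
vesselrad evaluate seg/mask.png phantom/truth_mask.png --out scores.json
```

## Layout

- `src/vesselrad/preprocess.py` — NIfTI/PNG loading, normalization,
  isotropic resampling, MIPs of arbitrary slab thickness
- `src/vesselrad/frangi.py` — coarse mask, EDT, scale planning, Hessian
  vesselness, seeded binarization
- `src/vesselrad/radii.py` — skeletonization, radii maps/histograms,
  volume, length, bifurcations
- `src/vesselrad/metrics.py` — Dice, Jaccard, precision/recall/F, Lin's
  CCC, error ratio, Bland–Altman
- `src/vesselrad/synth.py` — vascular-tree phantoms with exact truth and
  the noise/background degradations
- `src/vesselrad/pipeline.py`, `cli.py` — orchestration and the `vesselrad`
  command

`docs/methods.md` documents the model, parameter choices and known
limitations.
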