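# Methods

## Problem and model

The leakage point of chronic central serous chorioretinopathy appears in
fluorescein angiography as a compact hyperfluorescent blob on a smooth
retinal background, amid equally hyperfluorescent vessels. The package
treats its segmentation as small-target detection by low-rank and sparse
decomposition, after removing the vessel confound with information from a
registered color fundus photograph.

Within an operator-selected ROI, the (vessel-inpainted) angiography block
`G_P` is rearranged into a patch-image matrix `M` — columns are the
row-major vectorizations of all 50×50 sliding patches at stride 10, plus a
boundary-clamped final origin per axis so every pixel is covered — and
modeled as

```
M = L + S + N
```

`L` low-rank (the background: neighboring patches are nearly linearly
dependent), `S` sparse (the blob touches few entries), `N` a small dense
residual (sensor noise, assumed i.i.d.). The components are recovered from
the convex program

```
min  ||L||_*  +  λ ||S||_1  +  (1/2μ) ||M − L − S||_F²
```

The per-pixel `L`/`S` maps are folded back by aggregating, at each pixel,
the values of every covering patch (median by default; mean available).
The sparse map is clipped at zero: leakage is hyperfluorescent, so only
positive excursions are candidates.

## Solver

Accelerated proximal gradient on the joint block `(L, S)`. The smooth term
has gradient `(L + S − M)/μ` in each block and joint Lipschitz constant
`2/μ`, giving step `μ/2`; each iteration applies singular-value
thresholding at `μ/2` to the `L` extrapolate and soft thresholding at
`λμ/2` to the `S` extrapolate, with Nesterov momentum.

* **Continuation burn-in.** `μ` starts at `0.1·||M||₂` and shrinks ×0.9
  per iteration to a floor of `1e-4·||M||₂` (both configurable). Large
  early thresholds cheaply sketch the solution; the floor fixes the
  objective actually minimized.
* **Monotone phase.** After burn-in the iteration uses MFISTA-style
  acceptance (an extrapolated candidate that raises the objective is
  rejected in favor of the incumbent while the momentum sequence
  continues), so the objective trace is provably non-increasing from the
  burn-in iteration on.
* **Stopping.** Relative change of `(L, S)` below `apg_tolerance`
  (default 1e-5), evaluated after burn-in; `max_iter` 500. At 1e-5 the
  seeded rank-1 + 5%-sparse benchmark (2500×36) is recovered to 1.4% in
  `L` and 0.02% in `S` in ~100 iterations.
* **λ.** The solver's own "auto" is the classic RPCA weight
  `1/sqrt(max(p, q))`, appropriate for entrywise-random sparse support.
  The *pipeline* resolves its "auto" to `0.5/sqrt(max(p, q))`: a leakage
  blob is a clustered structure of hundreds of contiguous pixels whose ℓ1
  mass is far larger than random speckle, and at the full weight the
  blob's dim skirt drains into `L` (on phantoms this halves sensitivity).
  Both are configurable and logged in the run report.

Degenerate inputs: an all-zero matrix returns zero components
immediately; NaN/Inf raise. A zero-singular-value SVT result is returned
as an explicit zero matrix.

## Pipeline stages and defaults

| Parameter | Default | Meaning / rationale |
|---|---|---|
| `patch_size`, `stride` | 50, 10 | patch-image geometry of the decomposition |
| `threshold` (T) | 0.18 | region-growing admission band on [0,1] intensity; grid 0.10–0.20 step 0.02 in the ablation |
| `log_sigma`, `log_half_size` | 3.0, 3 | LoG vessel filter; 7×7 support |
| `clahe_clip`, `clahe_tiles` | 0.02, (8, 8) | CLAHE clip limit as a histogram fraction (scikit-image convention) and tile grid |
| `vessel_min_area` | 30 px | small-area removal on the vessel mask |
| `vessel_dilate_radius` | 2 | dilation before inpainting, to cover vessel edges |
| `sparse_binarize_rule` | adaptive | threshold at mean + 2·std of the strictly positive sparse-map entries |
| `biomarker_min_area` | 5 px | speckle rejection on biomarker regions |
| `rg_max_area_frac` | 0.05 | flood guard on grown regions (below) |
| `mu_floor_factor` | 1e-4 | continuation floor relative to ‖M‖₂ |
| `reconstruct_agg` | median | overlap aggregation, robust to a corrupted patch |
| `metric_scope` | roi | metrics counted inside the box (full frame available) |

**CLAHE before vessel filtering.** Cropping precedes CLAHE (cheaper, and
the enhancement adapts to the ROI's own histogram). A constant channel is
returned unchanged — adaptive equalization of a flat field must not invent
structure — and CLAHE never inverts local intensity order.

**LoG truncation and binarization.** With σ = 3 and a 7×7 support the
kernel's zero crossing (radius σ√2 ≈ 4.24) lies outside the support: every
weight is ≤ 0, the weights sum to −0.0801 (≈ 20× the center magnitude),
and the raw response is dominated by a negative multiple of the local mean
intensity. Vessel evidence is therefore the deviation of the response from
its median, whose magnitude is min-max normalized and thresholded by
Otsu's method, followed by 8-connected small-area removal. A constant
response yields an empty mask.

**Inpainting.** The dilated vessel mask is filled by solving the discrete
Laplace equation with uniform 8-neighbor weights and Dirichlet data from
the unmasked pixels (a sparse linear solve — the exact fixed point of
iterated neighborhood averaging). The maximum principle keeps filled
values inside the range of the surrounding background, and unmasked
pixels are untouched bit-exactly. A mask covering the whole block is an
error.

**Region growing.** The seed of biomarker `d` is the argmax of the sparse
map inside that region (ties: smallest row, then column); its value is
read from the angiography block. Growth is breadth-first over 8-neighbors,
admitting `p` iff `|I_a(p) − I_a(seed)| ≤ T`. Comparing to the *seed*
(not a running mean) makes growth deterministic, order-independent, and
exactly monotone in T. Fusion is the pixelwise union of all decomposition
regions and all grown regions, so the fused mask is always a superset of
the decomposition mask — the mechanism that compensates undersegmentation.

**Flood guard.** A grown region covering more than `rg_max_area_frac`
(default 5%) of the ROI is discarded before fusion: a leakage biomarker is
a small target by the same sparsity premise the decomposition rests on,
and in practice such floods arise when a spurious speckle region seeds the
growth at background intensity (observed on phantoms: one flood covered
13% of the ROI and collapsed that image's F1 from 0.92 to 0.29). True
phantom blobs reach at most ~2% of the default ROI, so the guard is far
from the operating point. Caveat: with the guard enabled, mask
monotonicity in T can break in the rare case a region floods only at the
larger threshold.

## Synthetic phantoms

`generate_phantom` emulates what the pipeline assumes about clinical
pairs, with pixel-level truth:

* **Background**: a constant plus three separable Gaussian profiles
  (matrix rank ≤ 4 by construction), scaled to [0.30, 0.50].
* **Vessels**: quadratic Bezier strokes between random border points,
  widths 3–7 px, six per image; rendered +0.35 in angiography and −0.245
  in the fundus green channel (soft-edged via a 1 px Gaussian).
* **Leakage blobs**: 2–4 isotropic Gaussian bumps, σ 6–12 px, peak
  contrast 0.45, added to angiography only (fluorescein leakage is
  invisible in a color photograph). Centers are confined to a random
  "macular" disk (radius 60 px) — clinically leakage clusters in the
  macula — mutually separated, and placed clear of vessels when possible
  (leakage sits in avascular tissue). Ground truth per blob is its
  half-maximum support (radius σ√(2 ln 2)), which is scale-free and
  analytic.
* **Noise**: i.i.d. Gaussian, σ = 0.02, both modalities.

Everything is deterministic given the seed; batches use consecutive
seeds. `roi_covering_blobs` stands in for the operator's manual box: the
blob bounding box padded by 20 px and grown to at least 160×160, which
keeps blob pixels a small fraction of the ROI (the sparsity premise) while
the patch-image matrix stays desk-scale (2500×121 columns for 160×160).

What the phantoms do **not** model: optic disc and macular pigmentation,
vessel branching/caliber variation and central reflex, photometric
differences or residual misregistration between modalities, non-Gaussian
leakage shapes, acquisition vignetting. Passing the phantom suite
therefore shows the pipeline's mechanics are correct under its stated
assumptions, not clinical performance; the phantom indicator values are
not comparable to values measured on patient data.

## Evaluation

Pixelwise confusion counts feed sensitivity `TP/(TP+FN)`, F1
`2TP/(2TP+FN+FP)`, accuracy `(TP+TN)/total`, specificity `TN/(TN+FP)`.
Any 0/0 ratio is reported as NaN (an explicit undefined marker), excluded
from averages, with the contributing count logged alongside each mean.
Metrics default to the ROI scope: over the full frame the enormous
true-negative background inflates accuracy and specificity without
informing about the segmentation; both scopes are supported and the scope
is recorded.

The ablation harness runs `LR`, `LRM`, `LRM_to_R`, `LRM_plus_R` over the
threshold grid with the decomposition stage computed once per phantom and
shared; the decomposition-only variants are T-independent and their rows
repeat across the grid, mirroring how such tables are usually printed.

## Known limitations

* The decomposition cost is dominated by one SVD of the patch-image
  matrix per iteration; very large ROIs (patch counts in the high
  hundreds) become slow. The patch geometry is fixed by the method, so
  the practical control is the box size.
* Seed-relative growth assumes the blob's peak is representative; a
  saturated or noisy peak shifts the admission band.
* The adaptive sparse-map threshold (mean + 2·std of positive entries)
  adapts to the residual speckle level but always sits below the sample
  maximum, so an entirely blob-free ROI can still yield min-area-scale
  speckle regions; the min-area filter and the flood guard contain their
  effect.
* Vessel segmentation is single-scale (one LoG width); very wide or very
  faint vessels outside that band survive into the angiography block and
  must be absorbed by the decomposition instead.
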