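# cscrseg

Semiautomatic segmentation of the leakage biomarker of chronic central
serous chorioretinopathy (CSCR) from a **registered multimodal fundus
pair**: a fluorescein angiography image and a color fundus photograph of
the same eye. The leakage point is the target of laser photocoagulation,
so its fast and accurate localization matters clinically; the obstacle is
that angiography renders both the leakage *and* the retinal vessels
hyperfluorescent.

## Method

The operator draws one rectangular box around the suspected leakage area;
everything else is automatic.

1. **Multimodal vessel removal.** Vessels are segmented on the fundus
   green channel (CLAHE-enhanced), where they are dark and the leakage is
   invisible, with a Laplacian-of-Gaussian filter
   `LoG(r,c) = -(1/πσ⁴)(1 - (r²+c²)/2σ²) e^{-(r²+c²)/2σ²}` (σ = 3, 7×7
   support), then erased from the angiography block by harmonic
   inpainting. Registration makes the two pixel grids interchangeable.
2. **Low-rank + sparse decomposition (stable RPCA).** Overlapping 50×50
   patches (stride 10) of the inpainted block `G_P` are vectorized into a
   patch-image matrix and split as `G_P = L + S + N` by minimizing

   ‖L‖\* + λ‖S‖₁ + (1/2μ)‖G_P − L − S‖²_F

   with an accelerated proximal gradient solver (singular-value
   thresholding + soft thresholding, Nesterov momentum, continuation on
   μ). The smooth retinal background is low-rank in patch space; the
   compact leakage blob is sparse.
3. **Biomarker extraction.** The reconstructed sparse map is binarized
   adaptively, labeled into 8-connected regions (largest first), and the
   result is restored to full-image coordinates via the box position.
4. **Region growing + fusion.** Each biomarker's sparse-map argmax seeds a
   breadth-first growth on the angiography block (admit pixel `p` iff
   `|I_a(p) − I_a(seed)| ≤ T`); the grown regions are fused (union) with
   the decomposition mask, compensating its undersegmentation.

Four ablation variants are exposed throughout: `LR` (no vessel removal),
`LRM` (the baseline), `LRM_to_R` (growth only), `LRM_plus_R` (the joint
framework). Evaluation uses pixelwise sensitivity, F1, accuracy and
specificity.

Because clinical pairs with annotations are private, the package ships a
first-class synthetic phantom generator (`cscrseg.phantom`): smooth
separable low-rank background, curvilinear vessels bright in angiography
and dark in the fundus green channel, Gaussian leakage blobs only in
angiography, i.i.d. noise, and half-maximum ground-truth masks.

## Worked example

```bash
python examples/02_segment_phantom.py
```

```
ROI box            : (294, 285, 454, 445) (160x160)
decomposition      : lambda=0.0100, 69 iterations
biomarkers found   : 2
  label 1: area  393 px, centroid [395.11, 371.21], full-frame bbox [384, 359, 408, 384]
  label 2: area  342 px, centroid [351.86, 357.88], full-frame bbox [342, 347, 363, 369]

agreement with ground truth over the ROI:
  F1 0.834  sensitivity 1.000  accuracy 0.992  specificity 0.992
```

The two regions are the phantom's two leakage blobs, recovered at their
true centers (truth: (352,358) and (395,371)); sensitivity 1.0 means the
fused mask covers every ground-truth blob pixel, and the F1 of 0.83
reflects a modest halo of extra pixels around the blobs. The other
examples demonstrate phantom simulation, the raw decomposition, the
threshold sweep, and the four-variant ablation.

A thin CLI wraps the same library:

```bash
cscrseg simulate --seed 0 --out phantom/
cscrseg segment --angio phantom/angiography.png --fundus phantom/color_fundus.png \
                --box 294,285,454,445 --variant lrm+r --threshold 0.18 --out seg/
cscrseg evaluate --pred seg/biomarker_mask.png --truth phantom/truth_blob_mask.png
cscrseg ablation --n 8 --seed 0 --out ablation.json
```

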