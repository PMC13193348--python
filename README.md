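# cisternatex

Quantitative image analysis for endoplasmic-reticulum (ER) cisterna
substructure, Golgi morphometry and ER→Golgi traffic in plant cells —
with a synthetic-phantom module that provides known ground truth for
every analysis stage.

## The problem

The cortical ER is a network of narrow tubules (~40 nm diameter) meeting
at three-way junctions and of expanded cisternae. Cisternae are classically
drawn as smooth sacs, but they can instead be perforated by nanoholes or
built from dense tubular matrices whose compressed lumen excludes soluble
markers — differences far below the ~120 nm resolution of confocal imaging.
ER morphogens of the Lunapark family induce cisternae of visibly identical
outline but structurally different interiors, with consequences for
ER→Golgi transport and secretion. This package implements the measurement
chain needed to tell such cisternae apart from diffraction-limited
fluorescence images, plus the accompanying Golgi-trace morphometry and
ROI-based traffic quantification, and validates each estimator on phantoms
with exact ground truth.

## Methods at the core

**Segmentation.** The ER foreground is extracted by hysteresis
thresholding (keep pixels ≥ *t*_low 8-connected to a pixel ≥ *t*_high)
after upsampling, denoising and top-hat background subtraction; cisternae
are the components surviving a morphological opening with a disc, the rest
of the foreground is tubule.

**Texture.** For each cisterna a grey-level co-occurrence matrix (GLCM)
*p(i, j)* is accumulated over all pixel pairs inside the cisterna mask
separated by at most a disc radius set to the apparent width of a single
tubule, estimated as ½·FWHM_PSF · median(I_tubule)/median(I_cisterna).
Four scalar properties summarise it:

- contrast  = Σ (i−j)² p(i,j)   (0 for a constant image)
- correlation = Σ (i−μᵢ)(j−μⱼ) p(i,j) / (σᵢσⱼ)
- energy   = Σ p(i,j)²      (1 for a constant image)
- homogeneity = Σ p(i,j)/(1+|i−j|)  (1 for a diagonal GLCM)

Per-cisterna values are pooled weighted by pixel count, and any per-image
average requires at least five cisternae. Radial lumen profiles
(distance-transform bins, bin 0 = edge) distinguish edge-confined from
uniform lumenal marker.

**Downstream.** roGFP2 405/488 excitation ratios (background- and
bleed-through-corrected, classifying cytosolic ~0.45 vs ER-lumenal ~1.34
environments); B-spline curvature κ = |x′y″−y′x″|/(x′²+y′²)^{3/2} and
shortest-distance width profiles of traced Golgi cisternae; Golgi share of
background-corrected fluorescence, 100·G/(G+E); apoplast/interior secretion
index over a 1.5 µm ring. Group statistics follow
MANOVA → per-metric ANOVA (Bonferroni across the four texture metrics) →
Tukey HSD, or Kruskal–Wallis → Dunn for the nonparametric metrics.

## Worked example

```python
import cisternatex as ct

spec = ct.PhantomSpec(image_shape=(192, 192), seed=7)
layout = ct.make_er_scene(spec, n_cisternae=6, substructure="sac_nanoholes")
image, truth = ct.render_er_image(layout, spec, channels=["lumen"])

params = ct.SegmentationParams()
segmentation, radius, summary = ct.analyze_er_image(
    image.channel("lumen"), spec.pixel_size_nm, spec.psf_fwhm_nm,
    params, {"radius": "auto", "n_levels": 8})

print(f"cisternae found: {segmentation.n_cisternae} (true: 6)")
print(f"apparent tubule radius: {radius.radius_nm:.1f} nm")
for name in ("contrast", "correlation", "energy", "homogeneity"):
    print(f"pooled {name}: {summary.pooled[name]:.3f}")
```

prints

```
cisternae found: 6 (true: 6)
apparent tubule radius: 23.0 nm
pooled contrast: 0.353
pooled correlation: 0.960
pooled energy: 0.126
pooled homogeneity: 0.833
```

All six nanohole-punctured cisternae are recovered, and their pooled
texture shows the nanohole signature: lower energy (0.126) and homogeneity
(0.833) with higher contrast (0.353) than hole-free sac phantoms at the
same signal-to-noise (typically energy ≈ 0.25, homogeneity ≈ 0.86,
contrast ≈ 0.31). A full phantom study — two conditions, segmentation,
texture and the MANOVA → ANOVA → Tukey chain — runs from one config:

```sh
cisternatex run examples/demo_config.json
```

writing per-image and per-cisterna CSVs, post-hoc tables, a provenance
manifest and a summary to the configured output directory. The other
subcommands (`phantom`, `segment`, `golgi`, `redox`, `traffic`) expose
the individual stages.

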