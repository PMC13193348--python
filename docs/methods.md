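# Methods

This note documents the models, parameter choices and numerical decisions
behind cisternatex, and what the phantom-based validation does and does
not establish about real data.

## Imaging model of the phantoms

Scenes are defined in continuous nanometre coordinates (origin at the
centre of the top-left pixel) and rasterised at pixel or sub-pixel centres.
Detection follows the standard confocal/detector model:

    counts = Poisson(photon_scale · (emission ⊛ PSF) + background)
             + Normal(0, read_noise_sd)

- **PSF**: isotropic 2-D Gaussian parameterised by its FWHM, default
  140 nm — the usual Gaussian approximation of a high-NA confocal PSF.
- **Pixel size**: default 46 nm. Acquisition metadata of the kind this
  emulates often reports "pixel scaling 0.046 µm²" with ambiguous units;
  we adopt 0.046 µm *lateral* pitch, and `pixel_size_from_scaling`
  exposes both the lateral and the area interpretation.
- **Noise**: Poisson shot noise plus additive Gaussian read noise.
  Defaults photon_scale = 200 expected photons at unit emission,
  read noise SD = 2 counts, background = 10 counts — a moderate-SNR
  live-cell acquisition. `photon_scale = inf` or `noise=False` renders
  noiseless expectations. A property test confirms the per-pixel sample
  variance across seeds equals the Poisson mean plus read-noise variance.
- **Determinism**: identical spec + seed gives bit-identical images; all
  randomness flows through `numpy.random.default_rng` seeded from the
  spec.

### ER scenes

Tubule skeletons are grown by branching: each three-way junction is
created by splitting an existing segment at an interior point and adding
a branch, so every internal node has degree 3 by construction. Tubules
are rendered as 40 nm-wide bands (the accepted plant ER tubule diameter);
at 46 nm pixels they are sub-resolution, and after PSF blurring their peak
intensity is ~0.27 of the cisternal plateau — the physical basis of the
intensity-ratio width estimate below.

Cisterna lumens come in three substructures:

- **sac** — occupancy 1 across the region;
- **sac_nanoholes** — occupancy 0 inside circular holes (default radius
  60 nm, density 8 µm⁻²; both sub-resolution at the default PSF so the
  holes appear only as texture, as intended);
- **tubular_matrix** — packed parallel internal tubule stripes at a pitch
  of 2× the tubule diameter, a continuous full-occupancy edge band
  (default 120 nm), and a low floor (0.1) in the compressed inter-tubule
  space. The paper-level observation this emulates is a lumenal marker
  confined to cisterna edges; the parallel-stripe geometry is our
  concrete stand-in for an unspecified dense matrix.

What the phantoms do **not** emulate: 3-D sectioning and axial blur,
temporal remodelling, spatially varying background, chromatic shifts, or
biological covariation between cisterna size and substructure. Passing
recovery tests therefore demonstrates estimator correctness under the
stated imaging model, not robustness to every property of real
micrographs.

## Segmentation

`preprocess`: bilinear upsampling (default 2×, to avoid pixelation in the
subsequent morphology), Gaussian denoising (σ = 1 px), white top-hat
background subtraction (disc radius 50 px — preserves cisterna plateaus),
normalisation to [0, 1] at the 99.9th percentile. The denoising step is
load-bearing for texture analysis: without it, per-cisterna quantisation
is dominated by shot noise rather than substructure.

`segment_er`: hysteresis thresholding with 8-connectivity for foreground
(4 for background), defaults low = 0.20, high = 0.40 of the normalised
range; speckles below 25 px removed. On sac phantoms at default SNR this
recovers the ER footprint with a boundary-tolerant Jaccard ≥ 0.8
(tolerance ±1 acquisition pixel). The tolerance is deliberate: tubules
are sub-resolution, so a segmentation faithful to the image recovers the
~140 nm diffraction footprint of a 40 nm structure, and pixel-exact
agreement with the geometric skeleton band is bounded away from 1 for any
threshold choice. Cisterna-region agreement is pixel-exact.

`identify_cisternae`: morphological opening with a disc (default radius
8 px on the 2× upsampled grid ≈ 180 nm half-width), 8-connected labelling,
minimum cisterna area 300 px (≈ 0.16 µm²). Zero cisternae is a valid
result; the ≥5-cisternae rule is enforced later, at averaging.

`estimate_tubule_radius`: radius = ½ · FWHM_PSF · median(I_tubule) /
median(I_cisterna), clipped to [pixel size, FWHM_PSF]. The rationale: a
sub-resolution tubule of width w blurred by a PSF of FWHM F reaches
roughly w/F of the plateau intensity of a wide region of equal lumenal
density, so the intensity ratio calibrates the unresolved width. On
phantoms with 40 nm tubules the estimate lands within ±50% of the true
20 nm radius (a sub-resolution estimate; its job is to set the texture
neighbourhood scale, not to be a precision width measurement).

## Texture metrics

The GLCM of a cisterna pools *all* integer offsets within a disc of the
user-defined (or auto-estimated) radius into a single accumulator —
offsets are not direction-resolved — with symmetric counting on by
default (each unordered pixel pair counted in both orders; turning
`symmetric` off counts each pair once in scan order). Grey levels are
quantised per cisterna over its own min–max range into 8 levels by
default; the level count is configurable and recorded in provenance. A
constant cisterna yields a single-entry GLCM (energy 1, contrast 0), and
degenerate correlation (zero marginal variance) is returned as 0 with a
flag rather than NaN so that pixel-weighted pooling stays defined.

Pooling is by cisterna pixel count — Σ areaᵢ·propᵢ / Σ areaᵢ — so many
small cisternae cannot dominate an image summary, and any per-image
average (pooled properties or radial profiles) requires at least five
cisternae, otherwise an `InsufficientCisternaeError` carrying the count
is raised.

Radial profiles assign each cisterna pixel the bin
floor(n_bins·d/d_max), d the Euclidean distance to background, bin 0 at
the edge (marked in the result) rising to the centre; per-cisterna bin
means are averaged *unweighted* across cisternae. Intensities are
background-subtracted but not per-cisterna normalised. Note that with a
finite PSF the outermost bin of even a uniform sac is dimmed by boundary
roll-off; the flatness property is therefore asserted on unblurred
phantoms, while the matrix-vs-sac comparison (edge bins exceeding central
bins) is robust to blur and is what carries the biology.

## roGFP2 ratios

C405 = max(I405 − bg405 − bleed·(I_auto − bg_auto), 0), C488 =
max(I488 − bg488, 0); ratio = C405/C488 where C488 clears a signal floor
(default background mean + 3 SD) and the pixel is unsaturated. The bleed
coefficient, if not supplied, is a least-squares slope through the origin
from an autofluorescence-only region. Per-cell means are classified
against the cytosolic (0.45) and ER-lumenal (1.34) reference ratios using
the geometric midpoint √(0.45·1.34) ≈ 0.78 with a ±10% ambiguity margin —
the references are empirical control means, and the margin guards against
over-confident calls between them. Construct-level summaries are means ±
SD over *cells*, never pixel pools across cells.

## Golgi morphometry

Traces are fitted with chord-length-parameterised cubic B-splines
(scipy `splprep`; chord-length knots chosen because the trace-point
spacing is irregular), smoothing 0 by default since manual traces are
already smooth. Curvature is sampled uniformly in arc length (not in
parameter) and averaged as mean |κ|. Width is the mean of shortest
point-to-polyline distances from samples on the shorter edge to the
longer; the "diameter range" is max−min of those distances per cisterna.
Verified invariances: rigid motions (exact), scale covariance (widths
scale by s, curvatures by 1/s), refinement convergence (<0.5% change on
doubling samples), and circle/arc recovery (κ = 1/R within 1–2%).

## Traffic and secretion

ROI means use pixel-centre, even-odd, boundary-inclusive rasterisation
(shapely). The transport fraction uses mean-of-ROI-means (3 Golgi, 3 ER)
minus a background ROI, negative corrected means clipped to 0 with a
flag; adding any constant to the whole image leaves the fraction
unchanged. The secretion ring is the binary dilation of the cell polygon
by round(1.5 µm / pixel size) pixels (33 px at 46 nm pixels) minus the
interior. The cell-scene phantom calibrates its ring level against the
rendered, blurred, noiseless means so that the *measured*
apoplast/interior ratio equals the requested ground truth — the ratio is
a property of the detected image, including PSF and detector background,
not of the raw emission map.

## Statistics

Texture comparisons: MANOVA omnibus (statsmodels; Pillai's trace and
Roy's largest root reported), then one-way ANOVA per metric with a
Bonferroni correction whose family is the four texture metrics, then
Tukey HSD (scipy) pairwise tables. Stars: * 0.05–0.01, ** 0.01–0.001,
*** ≤0.001. A single-metric call degenerates exactly to the ANOVA
(Pillai = SSB/SST, Roy = SSB/SSW, same p). Exactly-zero between-group
scatter short-circuits to p = 1 rather than a degenerate eigen-problem.
Nonparametric metrics use Kruskal–Wallis plus a Dunn post-hoc test
implemented here (rank-sum z statistics with tie correction, Bonferroni
adjustment); fully tied data give H = 0, p = 1. The analysis row is the
technical replicate (cell/image), matching how group sizes are reported;
the biological replicate is carried as a column but not modelled (no
mixed effects).

## Pipeline and problem sizes

`run_pipeline` drives phantoms → segmentation → texture → statistics from
one JSON/YAML config, writing tidy CSVs, a provenance manifest (seed,
config, package version, quantisation and neighbourhood conventions) and
a human-readable summary; reruns with the same seed reproduce outputs
byte-for-byte. Validation of the config happens before any computation.

Default study sizes were chosen to be comfortably discriminating while
staying desk-scale: 192×192 px scenes (≈ 8.8 µm field), six cisternae of
~0.65 µm radius per image, 8–20 images per condition. At these sizes the
sac-vs-nanohole separation on pooled energy is several within-group
standard deviations, and the full two-condition demo completes in a few
minutes on one CPU.

## Known limitations

- The tubule-radius estimate saturates at its clip bounds for very dim or
  very bright tubules; it is a scale heuristic, not a width measurement.
- GLCM properties depend on the quantisation convention; comparisons are
  only meaningful within a fixed (levels, radius, symmetric) setting,
  which the provenance manifest records.
- The segmentation thresholds are declared defaults, not values inherited
  from any published parameter set; for real data they should be
  re-examined per acquisition.
- Phantom validation covers 2-D cortical views only; no z-stacks or
  electron-tomography geometry.
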