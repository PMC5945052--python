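# Methods

This note documents the models, parameter choices, numerical conventions
and known limitations of `steatoscope`.  It states nothing that the test
suite or `scripts/acceptance.py` does not itself compute.

## Pipeline model

The working image is an 8-bit RGB raster at half the scanned resolution
(`downsample_half` performs 2×2 block averaging; odd dimensions round up so
no pixel rows are dropped, and block means round half away from zero).
Seven planes are derived per image — R, G, B, H, S, V and gray — all in
[0, 1].  HSV follows the hexcone model with hue scaled to [0, 1] and the
hue of achromatic pixels defined as 0; gray is the ITU-R 601 luma
(0.299 R + 0.587 G + 0.114 B).

### Tissue mask

Slide background is bright and touches the image border, so background is
grown from border seeds on the green plane: a pixel joins the background if
it is 4-connected to a seed through pixels within `tolerance` (default
0.12) of the *initial* seed mean.  Freezing the reference mean makes growth
monotone in the tolerance, which the property suite checks.  Enclosed white
lumina (fat, vessels) are never background because growth is
border-connected.  Post-processing fills background holes under 9 px and
closes 1-px gaps; both are disabled in the oracle tests so flood-fill
semantics are exact.

### Candidate white regions

Green → 3×3 mean (edge replication) → gamma 6 power law → 1-D 2-means over
tissue intensities.  The 2-means uses 25th/75th-percentile initialization
and Lloyd iterations to a 1e-9 center shift (300 iteration cap), making it
deterministic without a seed; the white class is the brighter cluster and
the threshold is the midpoint of the converged centers.  Components are
8-connected by default; regions smaller than `min_area` = 60 px are
dropped.  The size rule is implemented as a minimum because a maximum of
60 px would delete every macro droplet (hundreds of px at working
resolution); an optional `max_area` reproduces the opposite reading.

### Gabor banks

Kernels are sampled on a centered odd grid from
g(x, y; λ, θ, ψ, σ) = exp(−(x′²+y′²)/(2σ²))·exp(i(2πx′/λ + ψ)), then
DC-corrected by subtracting the complex mean so constant regions respond
exactly zero (this also makes the magnitude features illumination
invariant).  Choices the equation itself does not fix:

- σ = 0.56 λ, the one-octave half-amplitude bandwidth convention;
- base wavelength λ_min = 4 px (octave spacing λ_k = 4·2^k);
- ψ = 0 — immaterial, since magnitude responses absorb phase;
- kernel support ±⌈3σ⌉, truncated to min(H, W)/2 for the top octaves of
  the 10-octave bank (a 512 px image cannot support a λ = 2048 kernel);
  truncated kernels are flagged;
- orientation-major ordering (θ outer, λ inner) fixes the feature layout.

Filtering runs as FFT convolution on symmetrically padded planes; the test
suite checks it against a direct spatial complex convolution to 1e-6.

### Region features (554)

Block A (140): mean response magnitude per kernel per plane over the region
dilated by 20 px (Chebyshev).  Block B (385): for σ ∈ {0, 1, 2, 4, 8}
Gaussian pre-smoothing of each plane, 11 statistics over the bounding box
expanded by 25 px — mean, variance, skewness, kurtosis, min, max, median,
Shannon entropy of a 32-bin histogram on [0, 1], gradient-magnitude mean
and variance, Laplacian mean.  Derivative stencils use a 1-px halo of real
image data so window edges are not artifacts.  Skewness/kurtosis of a
numerically constant window are defined as 0.  Block C (29): morphology and
context.  Sizes and lengths (area, perimeter, axis lengths, convex
measures, bbox extents, neighbor distance/area) are log1p-scaled — region
areas span 60 px to >10⁵ px once severe-grade vacuoles merge, and raw
values would dominate a z-scored linear model; Hu invariants use the
customary signed-log10 compression.  Ratios (circularity, solidity,
extent), rim-contrast measures (green mean/SD inside vs in the 20-px
surround) and white-pixel fractions stay raw.

The 385 + 29 decomposition reconstructs a legacy statistical feature set
that is not published beyond its scale list; the decomposition is chosen so
the total is exactly 554 and every feature is individually named, with the
count enforced in tests.

### Classifier

One-vs-rest linear SVM (`C` = 1, 20 000 iteration cap) on z-scored
features, class-balanced instance weights (annotated class sizes are
heavily skewed toward fat).  The scaler, class order, feature-name order
and bank parameters are stored inside the model; prediction refuses a
matrix whose column order differs.  Ties in the one-vs-rest argmax break
toward the earlier class in sorted order.  Cross-validation is stratified
10-fold with a seeded shuffle; out-of-fold predictions pool into a single
confusion table.  Folds stratify by class only; a slide-grouped split is
available through the library for leakage-aware evaluation.

### Metrics

The confusion table keeps rows = actual.  The reproduced domain tables call
the row-wise diagonal ratio "PRECISION" and the column-wise one "RECALL" —
the reverse of the conventional naming — so the module exposes both the
table-verbatim accessors and conventional aliases.  Reported percentages
round half-up to the printed precision (2 decimals, 3 where the source
prints three).  AUROC is the Mann–Whitney rank form with ties counted ½,
cross-checked in tests against an all-pairs counting oracle.

### Quantification and grading

Percent steatosis = 100 · Σ area(regions classified macro-fat) / tissue
area, with tissue = all non-background pixels (vessel lumina included in
the denominator).  NASH-CRN bins: grade 0 for p < 5, 1 for 5 ≤ p ≤ 33,
2 for 33 < p ≤ 66, 3 for p > 66 — the overlapping printed bin edges are
resolved as closed on the left of each upper bound.  The grade correlation
fits percent as a 2nd-order polynomial of grade (the inverse regression is
available via a flag); R² = 1 − SS_res/SS_tot.

## Synthetic slides

The generator emulates what the pipeline needs from real H&E, not its full
appearance:

- palette chosen so the green channel carries the working contrast:
  background ≈ 0.97, cytoplasm ≈ 0.63, lumina ≈ 0.98, droplet rim ≈ 0.78
  (faint compressed cytoplasm), vessel rims/walls 0.31–0.40 (dark);
- macro droplets: white disks, radius uniform in [8, 30] px, thin light rim,
  optional displaced crescent nucleus; placed disjoint with a 3 px gap
  while feasible, then clustered (centers never inside existing fat) for
  high targets — disjoint random placement jams near ~50% coverage, while
  real severe steatosis shows abutting vacuoles.  Placement stops within
  ±1 percentage point of the target fraction;
- confusers: central veins (irregular lumen, dark endothelial rim,
  isolated) and portal triads (portal vein + thick-walled artery +
  bile-duct ring, co-located).  Their lumina exceed the 60 px floor so they
  genuinely enter the candidate set — the property suite asserts this;
- foamy foci: clusters of 0.5–1.5 px white vesicles at ~0.09 per px²
  within a 14–22 px disk;
- "others" survey polygons: large annotated regions that may contain
  droplets, vessels, nuclei and plain cytoplasm — everything except foamy
  foci — so the non-foamy pixel pool dwarfs the foamy one the way broadly
  annotated biopsies do;
- noise: fixed multiplicative cytoplasm texture (3%) plus additive
  Gaussian pixel noise (`noise_sd`, default 0.02).

Cohort generation samples per-grade target fractions uniformly inside each
NASH-CRN bin shrunk by 1.5 percentage points at interior edges, so the
±1 pp placement tolerance cannot push a slide's truth across its bin
boundary.  Slides regenerate bit-identically from (params, seed).

What the generator does **not** model: stain variability, scanner blur and
chromatic artifacts, ballooning, inflammation, pen marks, sectioning
artifacts, and the continuous morphological variety of real vacuoles.
Passing the synthetic end-to-end studies therefore demonstrates that the
pipeline machinery is correct and self-consistent, not that the trained
models transfer to real murine biopsies.

## Study sizes

The macro recovery study uses 12 slides (512×512, three per grade), trains
on two per grade and holds out one per grade (~340 annotated training
regions); the micro study uses 10 slides, training on 6 with subsample
rates 2% / 0.1% — the in-vivo rates scaled by 100 so a small cohort still
yields a few hundred training pixels per class — and evaluates pooled
AUROC on 4 held-out slides.  These sizes keep each study to a few minutes
on one CPU while leaving every class with enough members for 10-fold
stratified CV.

## Known limitations

- Magnitude-only Gabor pixel features are contrast-invariant: a dark
  nucleus and a white vesicle of similar scale produce similar responses,
  which is the dominant residual error of the micro classifier.
- The 414 legacy statistical features are a documented reconstruction, not
  the original (unpublished) definitions; only the scale set and the total
  dimensionality are anchored.
- Quantification counts classified white-region area only; fat smaller
  than the 60 px floor is invisible to the macro pipeline by construction.
- The region-growing tissue mask assumes background touches the border and
  is near-uniform; heavily vignetted scans would need a different seed
  policy.
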