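# Methods

This note records the models, parameter choices and numerical conventions
behind `duvtomo`, and what the synthetic validation does and does not show
about real data.

## Coordinate and unit conventions

All lengths are µm unless a name says otherwise.  Coordinates are
right-handed with `z = 0` at the top of the tissue block, increasing into
the block; a block face at `face_z` exposes material at `z >= face_z`.
Rasters are indexed `(row = y, col = x)` with half-open pixel intervals, so
the centre of pixel `(i, j)` sits at `((j + 0.5) px, (i + 0.5) px)`.

## Forward model

### Surface excitation

Excitation follows Beer–Lambert decay with 1/e depth `d` (default 20 µm,
the reference instrument's measured sectioning thickness).  A cell is two
concentric spheres: a nucleus (default radius 3 µm) and a soma (default
radius 5 µm) whose shell between the two radii carries the Nissl-like
perikaryal signal at half the nuclear amplitude — the stain marks both
compartments, and the rim is dimmer per unit volume than the chromatin-rich
nucleus; the 0.5 factor is a package choice.

The pixel contribution of a sphere is the chord integral

    ∫ exp(-z/d) dz over the chord [z1, z2],  z1,z2 clipped at the face,

which has the closed form `d (exp(-z1/d) - exp(-z2/d))`.  Using the exact
integral instead of a discretized depth sum makes depth attenuation free of
truncation error and faster; it also handles blade-cut cells (chords
clipped at the face) exactly.  Emission is blurred with a lateral Gaussian
PSF (default σx = σy = 1.5 µm), multiplied by the illumination field,
mapped through the dye→RGB mixing matrix, noised and quantized.

Out-of-focus blur of deep emitters is not modelled: within ~2–3 d of a
NA 0.3 objective's depth of field the geometric blur is small compared with
the lateral PSF, and nothing downstream depends on it.

### Illumination and noise

The oblique (60°) side illumination is modelled as a multiplicative linear
ramp across the field (default ±15 %) plus a weak radial vignette (default
5 % at the corners) — a smooth two-parameter family that flat-field
correction must undo; the true field flatness of such an instrument is not
published.  Noise is Poisson at a configurable photon scale plus Gaussian
read noise and a constant offset; quantization clips to the bit-depth range
and rounds half-to-even.  8-bit output is the default, matching the colour
camera; `to_16bit` promotes by ×257 so 255 → 65535 (exactly invertible, and
inert downstream because quantification is intensity-scale invariant).

### Spectral mixing

Each dye's emission spectrum is idealized as a Gaussian (σ = 30 nm) around
its emission peak — 659 nm (propidium iodide), 496 nm (Hoechst 33258),
613 nm (AF594) — integrated over boxcar R/G/B passbands (580–700, 480–580,
400–480 nm) and column-normalized.  The camera's true spectral response is
unpublished; the matrix is invertible for the default dye set, so linear
unmixing (`preprocess.unmix`) recovers dye abundances exactly on noiseless
data.  Propidium iodide is the first dye by convention: single-dye phantoms
render red-dominant and the counting channel is red.

### Reference stacks

`render_reference_stack` emulates confocal ground truth: each slice
sections the volume with an axial Gaussian (σz configurable; the wide-field
instrument's axial σ is ~13 µm, a confocal surrogate uses 2–3 µm) and no
Beer–Lambert decay, on the same pixel grid as the block-face render so the
two are co-registered by construction.  With `surface_z_um` set, material
above the cut face is excluded — the physical situation when the confocal
images the same cut block.

## Synthetic scenes

`generate_tissue_phantom` draws Poisson cell counts per region
(`density × volume`), uniform positions, and lognormal amplitude jitter
(σ_log = 0.3 by default) emulating the strong within- and between-cell
intensity variation of Nissl-type staining.  Cell overlap is *not*
prevented: real tissue has touching cells and the segmentation must face
them.  The default two-region fixture mimics the medial/lateral habenula
pair at a 2:1 density contrast (30 000 vs 15 000 cells/mm³ over a
0.16 mm² cross-section each).  No measured mouse habenula densities are
published alongside the imaging work this emulates, so the absolute values
are package defaults chosen from a feasibility calculation: cells visible
on a block face occupy `density × imaged depth (≈20 µm) × blurred cell
footprint (≈150 µm²)` ≈ 12 % of the frame — dense enough that touching
cells occur, sparse enough that a watershed can separate them.  At ~40 %
occupancy the watershed merges a quarter of the dense region's cells and
regional contrasts are systematically compressed; that regime is a
statement about segmentation limits, not about the imaging model.

What the phantom does **not** emulate: neuronal morphology (dendrites,
axons), white-matter autofluorescence, vasculature, stain-penetration
gradients, tissue deformation between sections, and registration error
between the block-face image and the reference stack (they share a pixel
grid by construction).  Passing recovery tests therefore shows the
*procedures* are correctly implemented and statistically calibrated — not
that they are robust to every artefact of real tissue.

## Calibration procedures

### Bead FWHM profiling

4 µm beads (the standard calibration microspheres) are detected in a
z-stack by smoothed local maxima with non-maximum suppression and refined
to sub-voxel centroids by intensity weighting.  1D profiles through each
centroid along x, y, z are aligned, averaged across beads, and fit with a
Gaussian plus offset; FWHM = 2√(2 ln 2) σ ≈ 2.35482 σ.  The recovery test
compares the fitted FWHM with the ground truth of the *bead-convolved*
profile (a 4 µm sphere is not a point source), computed by dense numerical
quadrature of the noiseless forward model.

### Optical sectioning thickness

Cells are binned by depth (default bin width 2 µm, matching the reference
stack spacing).  Per bin the estimator takes the **median of
log-intensity** and the **median depth**, then fits a straight line to
`(median depth, median log I)`; `d̂ = -1/slope`.  Medians absorb the
lognormal amplitude heterogeneity; taking the median after the log makes
the fit exact on noiseless exponential data (the median of a monotone
transform commutes with averaging in log space), which a bin-centre
convention does not.  The estimator is invariant to global intensity
scaling.  A non-negative slope raises a failure flag instead of reporting a
meaningless depth.  A nonlinear least-squares refinement of
`I0 exp(-z/d)` on the bin medians is available behind a flag; on clean
fixtures the two agree to < 2 %.

The recovery fixture scatters *whole* cells at depths `[R, R + 2d]`
(R = soma radius): blade-cut cells at the face lose part of their volume
and no longer follow `I0 exp(-z/d)`, and depths beyond ~2 d sink into the
noise floor; both would bias a fit that is meant to test the estimator
rather than the fixture.  Render gain is set so the brightest cells sit
near (not at) 8-bit saturation, keeping deep cells above the quantization
floor.

### Depth-correlation profile

Pearson correlation between the block-face image and each reference slice,
ordered by depth.  On the synthetic fixture the whole frame enters the
correlation (the background is clean); on real data a foreground mask
(default: union of the 90th-percentile foregrounds) is advisable and is the
function's default.  The profile peaks within the shallowest slices —
about one nucleus radius below the face, not at the face itself, because
the cells the z = 0 slice shows have lost most of their fluorescent volume
to the blade while whole cells a few µm deeper contribute full chords —
and decays monotonically beyond the attenuation depth toward zero.  This
shallow-peak geometry is a property of volumetric emitters sampled at 2 µm
granularity; treating the first 2–3 slices as "the surface" reproduces the
qualitative instrument behaviour (maximal similarity at the surface,
decay beyond d̂).

## Acquisition geometry

Stage resolution is `pitch × step_angle / 360` in exact rational arithmetic
(0.9°, 500 µm/rev → exactly 1.25 µm); commanded moves quantize to whole
steps with round-half-even.  Tile grids use stride `fov (1 - overlap)`
with `ceil` counts and the last tile shifted to end exactly at the tissue
extent (shift-to-fit), so coverage is guaranteed and every adjacent pair
shares at least the nominal overlap.  Visit order is serpentine.  Section
faces advance strictly by the section thickness; a thickness at or below
the attenuation depth triggers a warning because consecutive faces would
re-image overlapping material.

## Stitching

Pairwise offsets come from Hann-windowed phase correlation of the
*nominally overlapping crops* (windowing the full tiles would suppress the
shared content at the tile edges), searched within a radius of the nominal
offset; confidence is the correlation peak over the mean absolute
correlation, and low-confidence pairs fall back to the nominal grid offset
with a warning.  Offsets are integer-pixel; subpixel registration is out of
scope.  Global placement anchors tile (0,0) and accumulates offsets in
descending confidence order; redundant pairs whose loop-closure residual
exceeds 3 px are averaged in with a warning.  Compositing uses linear
feather weights (distance to tile border), which reproduces identical
overlapping content exactly — the round-trip contract.

## Quantification

Segmentation (a deterministic surrogate for manual counting): Gaussian
smooth (1 µm) → Otsu threshold → fill holes → distance-transform watershed
with peak markers ≥ 4 µm apart → area filter (defaults 12–400 µm²; the
end-to-end fixture uses 15–500 µm²).  Region assignment takes the atlas
label under the centroid pixel; background/outside cells get region 0 and
are excluded from counts but preserved in the conservation total.  Density
is areal (cells/mm² per section), as counts are made per coronal face;
volumetric density would additionally require an effective detection depth
(cells somewhat deeper than the 1/e cutoff still clear the threshold), so
regional *contrasts* — ratios and paired differences across sections — are
the supported comparisons and are what the end-to-end test asserts.

Statistics: paired t (df = n−1, two-tailed) via the standard formula;
Welch's one-way ANOVA implemented directly (scipy provides no Welch
variant) with Satterthwaite fractional df2 and verified against pingouin in
the tests; Tukey HSD via `scipy.stats.tukey_hsd`; Shapiro–Wilk via
`scipy.stats.shapiro`.  The Welch implementation holds its nominal type-I
error (5 % ± 2 % over 1000 null replicates at α = 0.05).

## Reproducibility

Every stochastic step takes a seed; composite runs spawn named substreams
from a single root seed (`numpy.random.SeedSequence`), so a pipeline run is
bit-reproducible from its YAML config.  Problem sizes in the tests and the
acceptance script (512² px calibration fields, 800 × 400 µm two-region
fixtures, 10 serial sections, 10 seeds per recovery study, 1000 statistical
replicates) were chosen so the full validation completes in about a minute
on one CPU while keeping Poisson and fit uncertainties a few times smaller
than the tolerances being tested.

## Known limitations

* The forward model is radiometrically arbitrary: exposure time and LED
  power are carried as metadata only; intensities are in arbitrary units.
* Only axis-aligned box regions are generated; arbitrary atlas geometries
  are supported at assignment time but not by the generator.
* Phase correlation assumes pure translation between tiles; rotation and
  scale errors are out of scope.
* The watershed surrogate under-splits above ~25 % cell occupancy; counts
  in very dense structures would need a learned or shape-model segmenter.
* The confocal surrogate shares the lateral PSF and pixel grid of the
  block-face render; real cross-modality registration error is absent.
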