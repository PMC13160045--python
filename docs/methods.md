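# Methods

This note records the models, conventions and numerical choices behind
`pazquant`, in the spirit of a methods supplement: what each pipeline
computes, what the synthetic scenes emulate, and where genuinely open
design questions were settled.

## Conventions

Pixel indices are 0-based; the physical coordinate of a pixel center is
`(index + 0.5) × nm_per_px`, so sub-pixel centroids convert to physical
positions without ambiguity.  All reported distances are in nm.
Conversions from nm to pixel counts round to the nearest integer with
ties away from zero (175 nm at 50 nm/px → 4 px); no rounding rule is
standard in the imaging literature, so this one is documented and
tested.  Channel roles (vesicle marker, AZ marker, protein of interest,
Brp, Nwk, …) are always declared explicitly — in the config or the TIFF
role tag — never inferred from channel order, because staining
combinations vary between experiments.  Every stage reads its parameters
from one `ExperimentConfig`; all randomness flows from its seed.

## Side-view line profiles

A side-view synapse presents the AZ (or PSD) marker as a bar at the edge
of the vesicle cloud.  The profile ROI is a rectangle through the bar
center, perpendicular to the bar, 750 nm long, with a width of the
marker bar plus up to 5 px on each side.  Design choices where the
procedure itself is under-determined:

* **Sampling.** Bilinear interpolation at one sample per lateral pixel
  pitch, averaged across the ROI width.  Finer supersampling changes
  nothing measurable because the optics already band-limit the image.
* **Rolled average.** Centered 5-sample moving mean; at the profile ends
  the window shrinks to the valid range rather than padding, so no
  intensity is fabricated outside the ROI.
* **Orientation.** The presynaptic direction is taken from the side of
  the reference peak holding the vesicle-marker centroid; positions are
  reported with positive = presynaptic.
* **Argmax ties** break toward the position closest to 0, then toward
  the presynaptic side.
* **Windows.** `symmetric_68` takes the protein maximum over [−68, +68]
  nm (inclusive); `onesided_136` over [0, +136] nm presynaptic of the
  PSD-95 peak.  At the 22.7 nm pitch the symmetric window contains the
  five samples at 0, ±22.7, ±45.4 nm.

Aligned averaging shifts each profile by an integer number of samples so
its reference argmax is at 0, takes the pointwise mean over the profiles
that reach each position, and scales by a caller-supplied reference mean
into percent.  Statistical comparisons downstream use the per-synapse
window peaks, not the averaged curve.

The geometric screen for candidate side-view synapses accepts a site iff
the thresholded vesicle signal extends ≥ 250 nm from the marker along
the presynaptic profile axis and the thresholded marker object has a
second-moment elongation ≥ 2 (a circle is 1).

## En-face clusters

The inclusion mask is the thresholded vesicle cloud dilated by a
Euclidean disk of 6 px (136 nm at the STED pitch).  Objects are
8-connected components of the thresholded protein channel inside the
mask, with intensities measured on the original, unthresholded image;
the minimum object size is 1 px.  The AZ center is the
intensity-weighted centroid of the largest thresholded marker object.
An optional [100, 300] nm radial band filter exists for analyses that
restrict to the cluster ring; it is off by default.  Thresholds are
fixed per experiment in the config (as they would be set by eye on a few
images), with an Otsu fallback used by the synthetic tests.  Object
counts are monotone non-increasing in the threshold for unimodal
clusters; this is not guaranteed for arbitrary textures, where raising a
threshold can split one component into several.

## Confocal levels

The presynaptic mask is the Otsu threshold (256 bins over the observed
range) of the vesicle channel minus user-supplied exclusion regions
(somata, out-of-focus areas).  The primary per-image statistic is the
pooled mean of each channel inside the mask.  Per-culture normalization
divides each value by its own culture's reference-condition mean (×100),
so the pooled reference mean is 100% by construction.

## NMJ bouton measurement

The 3D mask recipe: normalized sum of Nwk, Dyn and Brp (each channel
divided by its own mean; Brp dropped automatically when not stained) →
per-slice Gaussian blur (σ = 5 px; the axial pitch is much coarser than
the lateral one, so smoothing and erosion are 2D per slice) → one global
auto-threshold → per-slice erosion by a 4 px disk.  The thresholding
algorithm behind the original workflow is not published by name; it is
exposed as `nmj_threshold_method ∈ {otsu, li, triangle, isodata}` with
default `isodata` (the method behind ImageJ's *Default* thresholder) and
is always recorded in the mask provenance.  The `fig9LN` preset (σ = 4,
erosion 1, Otsu) reproduces the variant used for the FasII/Pak
experiment.

Rolling-ball background subtraction defines the background as the
grayscale opening of the image with a ball structuring element.  Two
engineering choices mirror the standard ImageJ implementation: for radii
above 16 px the background is computed on a block-averaged shrunken copy
and bilinearly re-enlarged, and the measurement pipelines estimate the
background from a 3×3 mean-filtered copy (`presmooth=True`) so that
single-pixel noise valleys do not drag the estimate down.  The exact
opening (small radii, `presmooth=False`) is verified against a
brute-force oracle in the tests.  Note the ball's intensity dimension is
fixed, so background subtraction is only approximately homogeneous in
intensity, and the ball partially penetrates plateaus wider than its
diameter — an intrinsic property of the method, visible as a ≲3% bias
when measuring a 2 µm object with a 50 px ball.

## Periactive-zone segmentation

Analysis runs on the per-channel maximum projection of the upper half of
the stack — (Z+1)//2 slices, middle slice included for odd Z; whether
"upper" means the first or last slices is acquisition-dependent and
exposed as a flag (default: first).

* **2D mask.** Auto-threshold of the plain channel sum, computed on the
  log-transformed sum.  Sum images are strongly right-skewed
  (background / tissue / bright mesh); in the intensity domain a
  bimodality-seeking threshold can lock onto the tissue–mesh gap and
  return only the brightest structures, while log compression makes the
  background–tissue gap dominant.
* **Composite.** Positive roles summed, negative roles subtracted, each
  mean-normalized first, clamped at 0.  Presets: `default`
  (Nwk + Dyn − Brp), `nwk-only` (stainings without Brp), `fasII`
  (FasII − Brp − Pak).
* **Seeds.** Regional minima of the composite smoothed with σ = 2 px
  *normalized convolution* (in-mask values only — plain smoothing drags
  the mask rim toward the background and grows false rim minima),
  suppressed at depth h = 0.5 × MAD of the in-mask composite.  The
  suppression is implemented as morphological reconstruction by erosion
  of (image + h) followed by regional minima; this fills shallow basins
  into their neighbors instead of deleting them, and avoids a
  floating-point residue comparison that can drop basins whose dynamic
  ties h exactly.
* **Growing.** A hand-written priority flood: frontier pixels are
  claimed in ascending composite intensity, restricted to the mask,
  8-connected; ties of equal intensity resolve to the earliest-inserted
  claim (seeds enqueued in raster order).  This first-in-first-out rule
  is the classical marker-watershed order; a label-id tie-break was
  rejected because every contested crest pixel carries the same value,
  so label order would systematically annex all watershed lines to the
  lowest-numbered unit.  The implementation is checked against a
  brute-force linear-scan oracle (same rule, independent mechanics) and
  against `skimage.segmentation.watershed` on unambiguous fixtures.
* **Edge exclusion.** A unit is excluded when the mean of the Euclidean
  distance map (distance to the nearest mask-background pixel) over its
  pixels is below 7.5 px — such units wrap the bouton's curved flank and
  are not planar.
* **Mesh/core split.** Boundary pixels are unit pixels 8-adjacent to a
  different label, background or the image border; the mesh is every
  unit pixel strictly closer than `nm_to_px(175 nm)` to a boundary
  pixel, the core is the remainder.  Mesh and core partition each unit.
  The "~330 nm from the center" location of the mesh is treated as an
  emergent property of unit size, not a constraint.
* **Polarization.** log₂(mesh mean / core mean), computed per channel
  after subtracting the extracellular background (median intensity
  outside the 2D mask).  Without this step a constant camera/tissue
  offset compresses the ratio toward 1; an out-of-mask estimate removes
  a flat background exactly, which rolling-ball subtraction under a
  bouton-sized plateau cannot.  Units with an empty core or nonpositive
  means carry an undefined (None) polarization and are skipped.
* **Brp objects and classification.** Connected components of the
  thresholded, background-subtracted Brp projection inside the mask;
  density is count per µm² of mask area; integrated intensity is
  area × mean.  A unit is Brp-positive iff it contains at least one
  object centroid, and Pak-apposed iff at least `min_pak_px` (default 1)
  thresholded Pak pixels fall inside it.  Objects in edge-excluded units
  still count toward whole-NMJ density.

## Statistics

Shapiro-Wilk per group and Levene (center = mean, the classical form)
across groups, both gated at α = 0.05, select the parametric
(t-test / one-way ANOVA with Tukey-Kramer) or nonparametric
(Mann-Whitney U / Kruskal-Wallis with pairwise Mann-Whitney + Holm)
branch, all two-sided.  Because each gate consumes ~5% of truly
compliant samples, the parametric branch is chosen on clearly normal
n = 30 pairs about 86% of the time — an inherent property of gated
procedures, not a defect; the gated procedure's overall type-I error
stays near nominal (≤ 7% measured at α = 0.05 over 2,000 null
simulations).  Observations are per-synapse / per-NMJ; no hierarchical
modeling is attempted.

## Synthetic scenes: what they emulate, and what they do not

**STED fields** (22.7 nm pixels, default 256 px ≈ 5.8 µm): side-view
synapses are a marker bar (300 nm long, 25 nm cross-section sd), a
protein band of sd 45 nm at a signed offset Δ along the profile axis,
and a vesicle cloud (default 400 nm) on the presynaptic (+Δ) side;
en-face synapses are a marker disk (90 nm) with protein clusters
(sd 40 nm) at given radii (default 250 nm) and a covering vesicle disk.
Channels are blurred with an isotropic Gaussian PSF (FWHM 60 nm) and
degraded with Poisson noise (1 photon per intensity unit) plus Gaussian
read noise (sd 3), giving the protein band a peak SNR of ~12.  Scenes
are rendered one or a few synapses per small field; the originals were
2048 px mosaics of hundreds of synapses, but every measurement is local
to one synapse, so replication across seeds substitutes for field size.

**NMJ volumes** (50 nm lateral / 150 nm axial, default 9×160×160; ~2.2
or 3.5 µm bouton radius): an ellipsoidal bouton carries a Voronoi tiling
of K PAZ units (default 20) on one upper-half slice, painted
piecewise-constant: core level 100, mesh band at R × 100 for each
measured channel, using the same band geometry the analyzer measures.
FasII is painted differently — a narrow Gaussian ridge (sd 100 nm) on
the unit borders — reflecting its role as the boundary-outlining
adhesion marker and giving the segmentation sharp crests.  Brp puncta
(Gaussian, sd 80 nm, amplitude 300) sit at the centers of an exactly
`round(p·K)` subset of units; Pak disks sit under every unit when
apposition is enabled.  A constant extracellular background (20) and the
same Poisson+read-noise model complete the scene.  By default no PSF
blur is applied to these volumes: the painted surface map is the ground
truth for band statistics, and optical blur (available via
`psf_fwhm_nm`) mixes mesh and core bands by construction, which would
make exact band-statistic recovery meaningless rather than merely noisy.

Consequently, passing recovery tests demonstrate that the measurement
chain is unbiased and correctly implemented on geometrically ideal
specimens; they do not show robustness to out-of-focus light, PSF
anisotropy, chromatic misregistration, bleaching, or biological shape
variation, none of which the generator models.

**Scene sizes used in validation** (chosen once, as the package's study
conditions): side-view recovery uses 100 single-synapse fields (SNR
≥ 10); polarization recovery uses two volumes of 16 units at 70 px
bouton radius per enrichment level (≥ 20 analyzed interior units), where
unit cores are large enough (≥ ~400 px) that the ±1 px flood-boundary
wander contributes < 0.05 log₂ units of bias; classification uses the
default 20-unit scene; the type-I simulation uses 2,000 two-group draws
of n = 30.

## Known limitations

* The flood boundary between units wanders by ~1 px along crests; mesh
  means are insensitive to this but small cores (< ~100 px) pick up a
  few mis-assigned band pixels, biasing per-unit polarization by up to
  ~0.1 log₂ units on 20-unit scenes.  Averages over units are reported
  for exactly this reason.
* Rolling-ball background subtraction is not scale-invariant in
  intensity and penetrates wide plateaus; measured means carry a small
  method-intrinsic bias quantified in the tests.
* The screen for side-view synapses is geometric only; it does not
  attempt the judgment calls a trained experimenter makes on real
  micrographs.
* Real acquisitions must supply pixel calibration in the config; TIFF
  metadata, when present, is only cross-checked.
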