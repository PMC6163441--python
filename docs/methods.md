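# Methods

## The segmentation model and its assumptions

The pipeline assumes a specific imaging situation: fruits photographed from
directly above on a bright, weakly saturated mat, with no two fruits
touching.  Under those conditions two monotone contrasts hold
simultaneously — fruits are darker (lower HSV value V) and more saturated
(higher S) than every background pixel, *including shadow pixels*, because
a shadow darkens the mat without saturating it.  The fused image
`I_SV = S + (255 − V)` therefore separates fruit from background better
than either channel alone: background (and shadows) map near 0, fruits map
high.  S and V are kept on the 8-bit scale (0–255) so the inversion
`255 − V` and the fusion are dimensionally coherent; the fusion saturates
at 255 and the background subtraction floors at 0, mirroring 8-bit image
arithmetic.  A `wide_range` configuration flag switches both to full-range
integer arithmetic with a linear rescale before thresholding; it is off by
default and makes no practical difference on well-exposed scenes.

Background flattening is a grayscale opening with a disk of radius 50 px at
working resolution.  The radius choice is structural: the disk must be too
large to fit inside any fruit (so fruits are removed from the background
estimate) yet small relative to the wavelength of the mat's brightness
folds (so the estimate tracks them).  The default geometry keeps fruit
major axes below ~100 working px, satisfying both.

Otsu's threshold presumes the histogram of `I_HC` is effectively bimodal —
a dark background mass plus a bright fruit mass.  This holds whenever at
least one fruit is present.  **Known limitation:** on a *fruit-free* scene
the histogram is a narrow quantization residue near zero; Otsu then splits
noise, and large spurious foreground can survive the 3-px opening.  A
perfectly clean fruit-free mat produces a constant residual and is handled
explicitly (degenerate-histogram path → empty mask + warning), but noisy
fruit-free scenes are outside the method's operating range, exactly as
touching fruits are.

## Numerical and discrete choices

* Structuring elements are Euclidean disks `{(dr,dc): dr²+dc² ≤ r²}`; the
  big-radius opening is computed exactly by decomposing the disk into
  horizontal runs and applying 1-D running min/max filters (O(r) 1-D
  passes instead of O(r²) neighbours per pixel); tests verify exact
  agreement with brute-force erosion/dilation.
* All filters and morphology use edge-inclusive reflect padding
  (`np.pad(mode="symmetric")`), which avoids border artifacts on the mat
  and keeps the pipeline exactly mirror-equivariant.
* The Gaussian is the 5×5 truncation of the rotationally symmetric kernel,
  renormalized to sum 1.  Down-scaling uses Pillow's bicubic resampling
  (area-weighted on reduction).
* Otsu uses the 256-bin integer histogram; between-class variances are
  integer-exact in float64, and ties break toward the smallest threshold,
  so the result is deterministic and platform-independent.  Binarization
  is strict (`pixel > t`).
* Hole filling treats background as 4-connected (the complement of
  8-connected foreground), preventing diagonal leaks; it is implemented as
  reconstruction by erosion from a border-valued marker and cross-checked
  against an independent border flood-fill oracle.
* Ellipse axes: coordinate covariance (population normalization) with
  +1/12 added to both diagonal entries so a pixel contributes the second
  moment of a unit square; axis length is 4√λ.  This makes the single
  pixel well-defined (axes 4·√(1/12) ≈ 1.155 px) and returns the true axes
  of a filled continuous ellipse.  Orientation is the angle of the
  principal eigenvector relative to the column axis, in (−π/2, π/2].
* Component labels are assigned in row-major first-pixel order, so tables
  are reproducible across platforms.

## Calibration and evaluation

Calibration models are ordinary least squares with an intercept (a
force-through-origin flag exists but is off by default).  The training
set is drawn by a seeded stratified split — quantile bins of the image
feature, largest-remainder allocation — so it spans the feature's range;
the default protocol is 50 training fruits and the remainder (150 under
the default dataset size) for validation.  A "variety-independent" model
is simply one fitted on pooled training sets; there is no separate code
path.

Of the three error measures, note that `|E|` applies the absolute value to
the *sum* of signed errors: over- and under-estimates cancel, so `|E|`
measures aggregate bias and can be 0 while RMSE is large.  The per-fruit
relative errors `e_i = ŷ_i/y_i` are exported for external population
comparisons (e.g. ANOVA between varieties); no such test is performed
in-package.

Segmentation scores pool TP/FP/FN counts across images before computing
precision/recall/F (each image weighted by its pixel count); an unweighted
per-image mean is available as an option.  True negatives are never
counted.  Ground truths supplied at capture resolution are down-scaled to
the working resolution by nearest-neighbour, which preserves binarity.

## What the synthetic scenes emulate — and what they do not

`synthgen` renders: a bright near-achromatic mat (level 235) with smooth
folds (three random low-frequency cosines, amplitude 12, wavelength
1500–3000 px at capture resolution — broad relative to the 50-px disk, as
the background-subtraction design assumes); elliptical fruits of two
colour families (dark-purple and green-brown) with per-fruit colour
jitter; cast shadows produced by *uniform RGB scaling* offset along a
per-scene light direction — uniform scaling leaves hexcone saturation
invariant, which is precisely the shadow property the channel fusion
exploits; 2 small specular highlights per fruit (bright, low-saturation
blobs that punch holes for the reconstruction step to fill); and Gaussian
pixel noise (σ = 2).

Geometry defaults model a ~10 px/mm capture resolution: scenes are
1280×1920 px with 10 fruits, major axes 12–22 mm, minor axes 8–15 mm
(minor ≤ major per fruit), and a minimum centre separation of 280 px so
fruits never touch — the method's stated operating range.  Mass follows
`mass = 0.015 g/mm² · (π/4 · major · minor) + N(0, 0.05 g)`, i.e. affine
in projected ellipse area, giving 1.5–4 g fruits; this matches the
linearization the area→mass model assumes.  A `mass_law_kind="volume"`
option (mass ∝ major·minor², rescaled to the same typical mass) exists to
probe how the linear model degrades when that assumption is broken.

The generator does **not** emulate: JPEG compression artifacts, lens
distortion or vignetting, within-fruit shading gradients, fruit stems and
surface defects, touching or overlapping fruits, or inter-image lighting
drift.  Passing tests therefore demonstrate the algorithm's correctness
and its behaviour under the idealized contrast structure of the intended
scene, not its robustness to every nuisance of real photographs; on real
data the pixel-level scores should be expected to be somewhat lower.

Fruit-to-reference pairing uses greedy nearest-centroid matching with a
gate (default 1.5× the median minor axis); real deployments record fruit
positions only approximately, and this rule is a documented stand-in for
whatever bookkeeping a laboratory uses.  Exact distance ties raise an
error rather than pairing arbitrarily.

## Problem sizes

The test suite and the acceptance script use 20 scenes of 10 fruits
(200 fruits: 50 train / 150 validation) for segmentation and calibration
checks, 50 images for the Otsu oracle, 20 digital ellipses for sizing
accuracy, 200 replicates for confidence-interval coverage, and 3-scene
datasets for pipeline determinism — sizes at which every quantity is
stable to well within the tolerances asserted.
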