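# Methods

This note documents the models, conventions and numerical choices behind
each pipeline stage, what the synthetic generators do and do not emulate,
and the design decisions taken where more than one reasonable
implementation existed.

## Angle conventions

All orientations are axial: a fiber at θ and at θ+180° is the same fiber.
Angles are in degrees, measured counter-clockwise from the image x-axis,
reduced modulo 180. In array coordinates (row index increasing downward)
a direction θ maps to (Δx, Δrow) = (cos θ, −sin θ); the generators and
every analysis stage share this convention, so recovered axes compare
directly to generator ground truth.

## Synthetic data

**Fiber fields.** Orientations are drawn by the doubled-angle
construction: φ ~ von Mises(2·mean, κ) on the full circle, θ = φ/2 mod
180°. This is the standard treatment of axial data; κ = 0 reduces exactly
to the uniform distribution and κ keeps its usual interpretation as
angular concentration. Each fiber is an anti-aliased straight segment
(per-pixel coverage = clipped linear falloff over one pixel at the
edges); overlaps add. Defaults model a dense 1.8 mg/mL collagen network
imaged at 1 µm/px in a 256 µm field: 400 segments of 60 px length, 2 px
apparent width, intensity 100 over Gaussian noise of SD 5, clipped at
zero. Values were fixed once on realism grounds (a confocal reflectance
field of gel collagen is crowded, with fibers spanning tens of
micrometres) and are fully configurable.

**Spot stacks.** Digestion spots are solid balls of constant intensity
(uniform in [120, 200]) on a uniform background (10), rejection-placed
with centers at least one diameter plus a guard voxel apart and at least
a ball radius inside the boundary; 1000 failed placements for any spot
raise a capacity error. Constant intensity is a deliberate trade of
realism for oracle precision: each spot's exact voxel membership, volume
and mean intensity are recorded, so segmentation and the activity
statistic can be checked *exactly*, not approximately. The recorded mean
intensity is recomputed from the rendered voxels so it is exact under
floating-point arithmetic.

**Cell masks.** A disk body (radius 20 px) plus n equally spaced
rectangular arms reaching `arm_length_px` from the center (width 6 px).
`n_arms = 0` is the round control. Arms shorter than the body radius or
shapes exceeding the frame are rejected.

**Gel silhouettes.** Baseline is an anti-aliased disk; the follow-up
radius is r·√(1 − f) so the *area* shrinks by exactly the configured
fraction f. The pair is noise-free and deterministic: the assay being
emulated is a macroscopic silhouette photograph where segmentation is
trivial, and determinism gives an exact end-to-end oracle.

**Count tables.** positive ~ Binomial(total, p) per image, eight images
per group by default, mirroring per-image manual counts divided by total
nuclei.

**What the generators do not emulate:** optical PSF blur, depth
attenuation, spectral crosstalk, the nylon support grid (the real
analysis happens within grid openings, so grid-free frames are
equivalent), fiber curvature, cell motility. Passing tests therefore
demonstrate the *estimators* are correct on images whose ground truth is
known — not that segmentation thresholds or window sizes are optimal for
any particular microscope's noise and blur characteristics.

## Fiber alignment

The chain is spectrum → angular profile → control normalization → peak →
index.

**Spectral estimate.** The primitive `compute_power_spectrum` returns the
centered magnitude spectrum of the mean-subtracted, Hann-windowed image
(windowing is on by default: without it, frame-edge discontinuities put a
cross artifact through the spectrum that dominates the profile). A single
periodogram, however, carries fully developed speckle — the magnitude at
neighbouring spectral pixels of a random texture fluctuates by tens of
percent — and prototyping showed the resulting angular profile of an
*isotropic* field is far from flat (max/min ≈ 2.7), swamping the flatness
a random network should exhibit. Enlarging the radial band makes this
worse (the high-frequency tail is pure speckle). The pipeline therefore
uses Welch estimation by default: magnitude spectra of 64 px Hann tiles
at 50 % overlap are averaged (49 tiles on a 256 px frame, ≈ √49-fold
speckle reduction), followed by a Gaussian σ = 1 px spectral smoothing.
With this estimator the isotropic max/min ratio drops to ≈ 1.2, κ
monotonicity is preserved, and axis recovery at κ = 8 is within 3–4°.
The single-FFT route remains available (`tile=None`).

**Angular profile.** For each angle at the configured step (default 1°),
spectrum values are sampled by bilinear interpolation at 1 px radial
spacing over the band [2 %, 45 %] of the half-frame and summed along the
rays at θ and θ+180° together (the magnitude spectrum of a real image is
point-symmetric, making the curve exactly 180°-periodic). The band
excludes the DC neighbourhood and the spectrum corners; both fractions
are configurable.

**Normalization.** Pointwise ratio to the control profile, rescaled to
unit mean — which makes the curve invariant to any positive intensity
scaling of either image. Subtraction is available behind a flag; ratio is
the default because the no-cell control captures the multiplicative
radial envelope of the spectrum. The alignment index is *refused* on
unnormalized profiles: the index's baseline (flat curve → 2 × window) is
only meaningful on the control-normalized scale.

**Peak and index.** The peak is the grid argmax, ties broken toward the
smallest angle; an all-equal curve yields 0° with a warning rather than
an error. The index is the trapezoidal area over the closed interval
peak ± window (default 10°), wrapping across 0°/180°; a constant unit
curve gives exactly 20. The 90° fiber-axis correction (spectral energy is
orthogonal to image structure) is applied exactly once, in the pipeline
wrapper, so profile-level operations stay in spectral coordinates.

## Zymography

Voxels strictly above the threshold (Otsu by default, fixed value
optional) are grouped by 26-connectivity; components smaller than
`min_voxels` (default 5) are discarded. Objects carry exact voxel counts,
physical volumes, per-object mean intensity, and intensity-weighted
centroids. MFI is the **unweighted mean of per-object means** — each
object counts equally, following the definition of averaging "the
fluorescence intensity of all the green fluorescent objects"; a
voxel-weighted variant is available behind a flag and differs whenever
object sizes differ. A fixed threshold outside the stack's intensity
range returns an empty result with a warning (a misconfigured threshold
is a usable no-detection outcome, not a crash). Gel-level values across
multiple fields are combined as their arithmetic mean.

## Morphology

**Roundness** is the isoperimetric shape factor 4πA/P², capped at 1.0.
The perimeter uses the 4-direction Crofton estimator: the naive
boundary-pixel count systematically overestimates perimeter on diagonal
contours (a discrete disk scores ≈ 0.92), while Crofton gives ≈ 1.00,
matching the shape factor's semantics (1 = circle).

**Extension lengths.** The mask is skeletonized (Zhang); endpoints are
skeleton pixels with exactly one skeleton neighbour. Endpoints within the
cell body — closer to the body center than the largest-inscribed-disk
radius — are discarded. Two refinements matter in practice:

- *Tip extension.* Skeletonization retracts endpoints from blunt tips by
  about half the local width (≈ 2.5 px for a 6 px arm). Each endpoint is
  pushed outward along the body-center→endpoint ray to the last
  foreground pixel before measuring, restoring sub-pixel tip accuracy.
- *Tip deduplication.* A blunt or slanted arm end skeletonizes into a Y
  whose corner endpoints both point at the same tip, and junction spurs
  add more. Tips closer together than the local extension width (twice
  the neighbourhood maximum of the distance transform at the endpoint,
  plus one) are merged, keeping the longest. Across arm counts 1–6,
  lengths 40–100 px and widths 4–8 px this recovers the constructed count
  exactly and each length within 2 px.

Lengths are measured from the **body center** (center of the largest
inscribed disk, computed as the mean of the distance-transform argmax
plateau), not the whole-mask area centroid: for an asymmetric stellate
cell the area centroid is dragged toward the arms (≈ 9 px for a single
80 px arm), which would bias every length. The reported `centroid` field
of `CellMorphology` still gives the area centroid. Both mean and maximum
extension length are emitted.

**Positive fractions** consume per-image (positive, total) counts —
positivity calling itself is manual/upstream — and report per-image
percents plus their unweighted mean.

## Contraction

Silhouettes are thresholded (Otsu default; a polarity flag handles gels
darker than background), the largest 8-connected component is kept and
hole-filled, and its pixel count is the area. Percent contraction is
100·(1 − A_follow-up/A_baseline); a follow-up larger than baseline is
reported as negative contraction with a warning. Group values are
normalized as **fold of the control-group mean** (control mean ≡ 1.0);
residual area fraction is reported alongside the area-lost percentage.

## Statistics

Groups are summarized as mean ± SD (sample SD, n−1; SD = 0 for n = 1).
Two groups: two-sided unpaired Student's t-test with pooled variance
(Welch behind a flag). Three or more: one-way ANOVA, then Tukey HSD over
all pairs (Dunnett many-to-one against a named control behind a flag, as
the common alternative post hoc). For two groups ANOVA and the t-test are
the same test (F = t²), which the suite verifies. Null calibration is
checked by simulation: the empirical type-I error over 2000 null
two-group datasets (n = 10 each) falls in [0.035, 0.065] at α = 0.05.

## Pipeline and reproducibility

`run_pipeline` executes any subset of the stages from a YAML/dict config.
Every generator seed is derived from the single master seed through
`numpy` `SeedSequence` with a fixed (stage, group, image) key path, so
reruns are bit-identical and adding a stage does not shift the seeds of
another. Config errors (no stages, unknown stage, stage without its input
section) are raised before any computation. Per-image values are written
as CSV, the combined report as JSON, and all parameters and seeds are
logged.

Problem sizes used by the validation sweeps and the acceptance script —
256×256 fiber fields with 20–30 images per condition, ten 64×256×256
zymography stacks, 2000 simulated null datasets — were chosen as the
smallest sizes at which the stochastic checks are stable well away from
their bounds.

## Known limitations

- The alignment index depends on the spectral estimator's variance; on
  single raw periodograms (``tile=None``) the isotropic baseline is not
  flat and index values are not comparable to the Welch-default values.
- Peak finding is grid-quantized (1° default); axis recovery error at
  κ = 8 is typically ≤ 4° but individual fields can reach ~7°.
- Roundness is resolution-dependent below ~20 px radius, where
  discretization dominates the perimeter.
- The tip-deduplication radius assumes extensions are locally convex and
  wider than ~2 px; filigree protrusions below the pixel scale would be
  merged or missed.
- Otsu thresholds assume bimodal intensity histograms; real confocal
  stacks with strong background gradients need the fixed-threshold path
  and flat-field correction upstream (out of scope here).
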