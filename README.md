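# ecmquant

Quantitative image analysis of human cardiac myofibroblast activation and
extracellular-matrix (ECM) remodeling in 3D collagen gels.

Cardiac myofibroblasts activated by TGFβ1 contract collagen gels, degrade
the matrix, realign collagen fibers along their extensions, become
stellate, and express α-smooth muscle actin; low-molecular-weight FGF-2
attenuates all of these. This package implements the image-analysis
readouts such a study rests on, as a tested, reusable pipeline:

- **Fiber alignment** — 2D FFT magnitude spectrum of a confocal
  reflectance image, angular intensity profile by ray summation
  (oval-profile style), normalization to a no-cell control, and the
  *alignment index*: the area under the normalized intensity-vs-angle
  curve within ±10° of its peak. A random network gives a flat curve
  (index ≈ 20 for the 10° window); co-oriented fibers give a peak and a
  larger index. The reported peak angle includes the 90° correction for
  the spectrum being orthogonal to image structure.
- **In situ zymography** — fluorescent digestion spots in a DQ-gelatin
  z-stack segmented by thresholding + 26-connected components, summarized
  as

  `total protease activity = MFI × total fluorescent volume / total image volume`

  with MFI the mean of the per-object mean intensities.
- **Cell morphology** — roundness (the shape factor 4πA/P², 1 = round,
  → 0 = stellate) and extension lengths from the cell-body center to each
  skeleton-derived extension tip; plus α-SMA positive fractions from
  per-image positive/total counts.
- **Gel contraction** — silhouette area at release and at follow-up;
  percent contraction `100·(1 − A_t/A_0)`, optionally as fold of the
  control-group mean.
- **Statistics** — mean ± SD summaries; Student's t-test for two groups,
  one-way ANOVA with Tukey HSD post hoc for more.

Because no imaging data are deposited with the study design this package
follows, every analysis stage is exercised on **synthetic images with
known ground truth**: fiber fields with von Mises–distributed axial
orientations (concentration κ and mean angle are the truth knobs),
constant-intensity spherical digestion spots, star-shaped cell masks,
shrinking gel-silhouette disks, and binomial count tables. The generators
are first-class, seeded, and bit-reproducible.

## Worked example

```python
import ecmquant as eq

# a TGFb1-like aligned field (kappa=8 about 30 deg) vs a no-cell control
img, truth = eq.generate_fiber_image(
    eq.FiberFieldParams(kappa=8.0, mean_angle_deg=30.0, seed=1))
ctrl, _ = eq.generate_fiber_image(eq.FiberFieldParams(kappa=0.0, seed=2))

res = eq.fiber_alignment_pipeline(img, ctrl)
print(f"peak axis {res.peak_angle_deg:.1f} deg, "
      f"alignment index {res.alignment_index:.2f}")
```

prints

```
peak axis 30.0 deg, alignment index 44.13
```

i.e. the dominant fiber axis is recovered at the generator's 30° mean,
and the index (44.1) sits far above the flat-curve baseline of 20 that an
isotropic network produces.

The `analysis/` scripts run the full simulated experiments and write
tables under `results/`: `02_fiber_alignment.py`, for instance, builds a
three-arm study (control-like κ=1, TGFβ1-like κ=8, TGFβ1+FGF2-like κ=2,
20 images per arm) and reports

```
        TGFb1:  45.04 +/- 1.49
   TGFb1+FGF2:  33.90 +/- 1.14
      control:  27.40 +/- 1.71
one-way ANOVA: F=740.6, p=1.63e-41
```

— the activated arm aligns fibers the most and the FGF-2 arm falls back
toward control, the qualitative pattern the assay is designed to detect.

A CLI mirrors the stages (`ecmquant simulate/align/zymo/morph/smafrac/
contract/stats/run`); `ecmquant run --config experiment.yaml` executes a
whole seeded experiment from one YAML file.

## Limitations

The synthetic images are deliberately idealized (no optical PSF, no
nylon-grid structure, constant-intensity spots); see `docs/methods.md`
for what that does and does not validate about real confocal data.
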