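# Methods

## Acquisition geometry

A motorised linear sweep is described by four numbers: probe travel
`d` (mm), scan time `T` (s), frame rate `f` (Hz) and in-plane pixel size
(row, col) in mm. Frame count is `N = round(T·f)` with rounding half away
from zero — the reference acquisition (21 s × 20 Hz) is exact, so the
convention only matters for non-integer products. Slice spacing is
`Δz = d/N`; slice `k` sits at the voxel-centre position `z_k = k·Δz`, so
the reconstructed extent is `N·Δz = d`. Axes: *axial* is the acquisition
plane (`voxels[:, :, k]`), *sagittal* the plane containing the elevational
and row axes, *coronal* the elevational and column axes. Intensities are
floating [0, 1] in memory; integer storage (uint16 TIFF/PNG) maps the full
dtype range to [0, 1], which makes write/read round-trips exact on the
integer grid. Volumes and label volumes are NIfTI with voxel sizes in the
header zooms; frame stacks carry a `geometry.json` sidecar.

## Synthetic phantom

The phantom states the world every stage is tested in: a straight,
water-distended urethra along the elevational axis.

* **Lumen**: tube of radius `r(z) = r₀·(1 − depth·w(z))`, with `w` a
  raised-cosine window of full width `L` centred on the stricture
  (`w = 1` at centre, 0 outside). The smooth profile makes
  ratio-threshold crossings well defined at sub-slice resolution, so
  recovery tolerances can be stated analytically: the span where the
  area ratio exceeds threshold `t` is `(L/π)·arccos(2w* − 1)` with
  `w* = (1 − √(1 − t/100))/depth`.
* **Corpus spongiosum**: annulus out to a fixed outer radius.
* **Fibrosis**: placed inside the spongiosum within the stricture zone
  until a target voxel fraction is reached — either *dotted* (spheres of
  2–4 voxel radius at centres kept ≥ 1.2 mm apart, emulating scattered
  scar foci) or *massive* (one contiguous ellipsoidal blob, sized by an
  exact quantile of the ellipsoidal distance). Both are seeded.
* **B-mode model**: per-class mean echogenicity (defaults 0.05 lumen,
  0.25 background, 0.50 spongiosum, 0.85 fibrosis — fluid anechoic, scar
  hyperechoic; the ordering is enforced, the values are a synthetic
  convention since real fibrosis echogenicity is not quantitatively
  characterised), an in-plane Gaussian PSF (default σ = 1 px), and
  multiplicative fully-developed speckle modelled as unit-mean Gamma noise
  with shape `1/σ_s²` (default σ_s = 0.3), clipped to [0, 1].

Deliberately **not** modelled: attenuation, refraction, shadowing and
reverberation artifacts, anatomical curvature, probe pressure deformation.
A green test therefore establishes that the pipeline's arithmetic and
segmentation logic recover known geometry under speckle — not that it
would survive every artifact of clinical imaging.

Phantom defaults describe the reference sweep (35 mm, 21 s, 20 Hz,
0.1 mm pixels) around a 3 mm lumen / 6 mm spongiosum radius with a 14 mm,
70 %-depth stricture — the clinical scale of reported mean stricture
lengths. Tests and the validation study use the same kinematics at 6 Hz
and 96×96 frames at 0.15 mm (126 slices at 0.278 mm spacing) so the full
suite runs in minutes on one CPU; the coarser spacing bounds per-edge
length quantisation at ~0.3 mm, well inside the 1 mm recovery tolerance.

## Segmentation backends

**Classical (default).** Per frame, after optional Gaussian denoising
(σ = 1 px): three-band multi-Otsu thresholding; the lumen is the most
central dark-band connected component that does not touch the frame border
(the water column is interior by acquisition design, while dark background
regions reach the border). The wall band is whichever band dominates an
annulus 6–12 px outside the lumen — an annulus, not a thin ring, because
the PSF-blurred lumen/wall transition spans several pixels. The lumen
boundary is then refined to the midpoint-intensity contour between lumen
and wall medians: the PSF is symmetric, so the half-height contour sits on
the true edge, whereas Otsu's band cut is generally offset and would bias
areas (and hence lengths) systematically. The spongiosum is the geodesic
reconstruction of wall-band-or-brighter tissue from the annulus;
brighter-band pixels inside it become fibrosis; the rest is background.
Fully deterministic and pure per frame. In frames without a brighter band
(no visible scar) fibrosis is simply absent — fibrosis detection is
best-effort, and its Dice is accordingly lower than lumen/spongiosum.

**Trainable (`unet` backend).** No deep-learning framework is available
in the build environment, so the trainable backend is a deliberately small
encoder–decoder: a Gaussian-pyramid encoder (4 levels of blur + 2×
downsampling), a decoder that bilinearly upsamples every level back to
full resolution and concatenates them with native-resolution skip features
(intensity, gradient magnitude, two difference-of-Gaussian bandpass maps
that make small bright foci separable) plus a radial-position prior, and a
learned per-pixel softmax head trained by seeded gradient descent on a
class-balanced pixel sample with cross-entropy + soft-Dice loss. It is
exactly reproducible from its seed and reaches lumen Dice ≈ 0.95 on
speckled phantoms in seconds; it is a pipeline-contract stand-in, not a
reproduction of a clinical-grade network, and its all-class validation
mean Dice sits within 0.05 of the classical baseline on the same data.
Frames enter either backend as 256×256 min-max-normalised grayscale;
predicted masks return to native shape by nearest-neighbour resizing so no
fractional class codes arise.

**Dataset split.** Validation and test sizes are `round(p·n)` (half away
from zero), training the remainder — the only convention consistent with
442/148/148 from 738 at 6:2:2. An optional group id keeps all frames of
one subject in one split.

## Quantification conventions

* Per-slice lumen area = lumen voxel count × pixel area.
* **Reference area**: not prescribed by the measurement's definition, so
  it is explicit configuration. Default `p90` (90th percentile of
  per-slice areas): robust to the stricture occupying up to ~10 % of the
  scan and avoids hand-picking a "healthy" segment; `median`, `max` and a
  fixed value are selectable and always reported in outputs.
* Ratios are clipped to [0, 100] (a slice wider than the reference is 0 %
  narrowed).
* **Detection threshold**: default 50 % (half-calibre loss, a conventional
  stenosis landmark), configurable and always reported.
* **Length**: longest contiguous supra-threshold run × Δz; ties take the
  earliest run; all runs are reported as secondary findings for multifocal
  disease. Length is monotone non-increasing in the threshold.

## Segmentation metrics

Dice `2|A∩B|/(|A|+|B|)`; two empty masks score 1 (perfect-agreement
convention). HD95 pools both directed boundary nearest-neighbour distance
sets and takes the 95th percentile of the pooled set with linear
interpolation between order statistics — the symmetric convention of most
medical-imaging toolkits; the max-of-directed-percentiles variant differs
and is deliberately not used. Boundary voxels are mask voxels 4-adjacent
(2D) / 6-adjacent (3D) to a non-mask voxel, counting the array edge. An
empty mask makes HD95 undefined (NaN), never 0, so empty predictions are
not rewarded. Both metrics are checked against exhaustive all-pairs
oracles in the tests.

## Rendering

Orthographic emission–absorption raycasting: front-to-back compositing
with trilinear intensity sampling, nearest-neighbour label sampling and
per-sample alpha `1 − (1 − opacity)^step`, so an n-sample unit-step slab
accumulates exactly `1 − (1 − opacity)^n`. The lumen's opacity is 0 by
default and zero-opacity classes are additionally zeroed in the intensity
volume before interpolation — this both suppresses reflection/reverberation
echoes inside the water column and guarantees that rendering is bit-wise
independent of lumen intensities. Fibrosis defaults to an opaque green
against a warm semi-transparent gray spongiosum. Physically based light
transport is out of scope; the emission–absorption model preserves the
visual contract (transparent lumen, distinct fibrosis) deterministically.

## Agreement statistics

Spearman's ρ (tie-corrected, undefined for constant vectors) and
Bland–Altman analysis with sample-SD (n−1) limits `bias ± 1.96·SD`
(multiplier configurable). Incomplete pairs are dropped with a reported
count.

## Known limitations

* The classical backend assumes the lumen is the interior dark structure;
  collapsed (fully obliterated) segments yield zero lumen area, which the
  ratio curve handles, but the spongiosum is not tracked through them.
* The trainable backend is linear per pixel given its multi-scale
  features; fibrosis Dice under heavy speckle plateaus around 0.4.
* Length is measured along the elevational axis of a straightened
  urethra; no centerline curvature correction.
* The phantom's stricture profile is single and symmetric; multifocal
  disease is exercised only at the curve level, not in the generator.
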