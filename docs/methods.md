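# Methods

## The measurement

Expansion microscopy (ExM) physically enlarges a hydrogel-embedded
specimen ~4–5×; its resolution claim rests on the expansion being
*isotropic*. `exm-ruler` quantifies this in 3D using a photobleached
cubical fiducial: a dark cube carved by targeted photobleaching into a
nucleus with roughly uniform fluorophore labelling, imaged as a confocal
z-stack before and after expansion.

For each axis, an analysis plane through the middle of the cube is
selected — the xy-plane at the cube's mid-height for x and y, and an
orthogonally resliced xz (and yz) plane through the cube's mid-row for
z.  Within that plane, every pixel line crossing the segmented square
has a physical length

    L = (number of bleached pixels) × (pixel size along the line, µm)

and the local expansion factor of line *i* is

    EF_i = L_post,i / L_pre,i

with post line *j* matched to pre line *i* by proportional index mapping
`j = round(i·(n_post−1)/(n_pre−1))` (the pre-expansion grid is the
reference; one EF per pre line).  Per axis the distribution {EF_i} is
summarised by its **median** (robust to the ragged border rows every
segmented square shows) and its **unscaled MAD**,
`median(|EF_i − median|)` — no 1.4826 normal-consistency factor.

Two diagnostics catch distortions the medians miss:

* **Slope statistic.** The OLS slope of post-expansion line lengths
  versus line index, divided by the mean length — the fractional width
  change per line.  Because a raster-bleached square is intrinsically
  straight in the imaging plane, this should approach zero; shear-like
  local distortions drive it away from zero.  For classification the
  per-line slope is multiplied by (n−1), giving the **total fractional
  width change across the square**; this is what `slope_tol` bounds, so
  the test does not depend on how finely the square is sampled.  The
  slope is fitted on *interior* retained lines only: the square's
  corners yield partial rows whose counts ramp up from zero, and their
  leverage would swamp the straightness signal.  The verdict uses the
  in-plane (x, y) slopes; the z slope is reported as a diagnostic only,
  since the axial extent of the bleach cone carries focus jitter and no
  straightness guarantee.
* **Two-regime detection.** A deterministic exhaustive two-cluster
  split of the sorted EF values (minimum within-cluster sum of squares).
  The distribution is called bimodal iff (i) the cluster centers are
  more than `regime_sep` (default 3) pooled within-cluster standard
  deviations apart, (ii) each cluster holds ≥ 20% of the lines, and
  (iii) the centers differ by ≥ `regime_min_rel_sep` (default 25%) of
  their mean.  Condition (iii) is a materiality floor: EF values are
  ratios of integer pixel counts and live on a lattice with steps of a
  few percent, so a split across one quantization step can show
  near-zero within-cluster spread without representing distinct physical
  regimes, which differ by tens of percent (e.g. ~5× vs ~2×).

**Verdict.**  `anisotropic` if any axis is bimodal; otherwise
`local_distortion` if any in-plane total slope exceeds `slope_tol`
(default 0.02) or the per-axis medians spread by more than `median_tol`
(default 0.3); otherwise `isotropic`.  Both tolerances are tool
defaults, prominently configurable, not literature constants.

## Preprocessing

The post-expansion stack is rotationally aligned to the pre-expansion
one (per-plane bilinear rotation; out-of-frame fill with the plane's
modal border intensity).  The angle is estimated from the mid-cube mask
planes: second-central-moment orientation when the component is clearly
elongated, and a coarse-to-fine minimum-area rotated-bounding-box search
(mod 90°) when it is near-square — for a 4-fold-symmetric mask the
second moments are degenerate (µ20 ≈ µ02, µ11 ≈ 0) and the moment angle
is meaningless.  Angles are mapped into (−45°, 45°] with the ±45° tie
resolved to +45°; estimates below `min_rotation` (0.25°) are not
applied, since sub-degree interpolation only blurs edges.  A manual
`angle` override preserves the interactive workflow.

Intensities are linearly rescaled so the 0.5/99.5 percentiles of the
nonzero voxels span the full range (the post-expansion histogram is
compressed by dye dilution; percentile anchors resist hot pixels), then
median-filtered per plane (3×3 by default — planes are filtered
independently because the z-step is much coarser than the pixel size).
The cube is segmented as the largest 6-connected at-or-below-threshold
component that does not touch the stack's xy border (the dark
extracellular background always touches it); `threshold="auto"` applies
Otsu's method within the nucleus region, taken as voxels above 10% of
the dtype maximum.  A binary opening (`open_radius`, default 1) severs
voxel-thin dark bridges that chromatin texture can form between cube and
background, at the cost of slightly rounded cube edges.  The cube's
middle plane indices are rounded medians of mask-voxel coordinates, not
bbox midpoints, for robustness to ragged faces.

The z axis is analysed on both the xz and yz reslices; they are
reported separately and pooled (the pooled distribution feeds the z
violin, median/MAD, and two-regime detection; slopes stay per-view,
because concatenating views would fabricate a slope at their junction).
Reslicing is a pure axis permutation — no interpolation, since the EF
formula works in micrometers and resampling would only add error.

## The simulator

`SceneSpec` + `DeformSpec` render pre/post pairs with exact ground
truth.  The scene is an ellipsoidal nucleus (default semiaxes
11 × 10 × 7.5 µm) of mean intensity 20 000 (16-bit) containing a bleached
box (default 8 × 8 × 6 µm, bleach depth 0.85, centred).  Deformations act
on geometry in continuous micrometer coordinates *before* rendering, so
per-line ground-truth EFs come in closed form and carry no interpolation
bias: isotropic/affine scaling, shear (width varying linearly with
height), and piecewise axial scaling (one part of the cube expanding
~5× in z, the rest ~2×, blended over `z_twidth` = 0.5 µm because a gel
deforms continuously).  Rendering samples the deformed scene at
Nyquist-like voxel sizes (pre 0.3 × 0.1 × 0.1 µm, post 1.5 × 0.5 × 0.5 µm,
`(dz, dy, dx)`), applies an anisotropic Gaussian PSF (σ = 0.12 µm
lateral, 0.45 µm axial, identical in image-space micrometers pre and
post), Poisson shot noise at a target SNR of 10 plus 1% Gaussian read
noise, and quantizes to 16 bits.  Post-expansion intensity is diluted by
the volumetric expansion factor, reproducing the compressed histograms
real post-expansion acquisitions show.

Two departures from an ideal geometric cube are essential for realism:

* **Chromatin texture** — a smooth multiplicative random field
  (amplitude 0.10, correlation 1 µm) on the nucleus density, expressed in
  pre-expansion coordinates so it deforms with the specimen.  The
  nucleus is only *roughly* uniform, and this is what perturbs
  threshold crossings the way real data does.
* **Bleach-boundary waviness** — each cube face wanders by a smooth,
  detrended random displacement field (σ = 0.015 µm lateral, 0.30 µm
  axial, correlation 1 µm).  The raster keeps the square straight at
  large scales (hence detrending: no net tilt that would mimic shear),
  lateral placement is galvo-limited and tight, while the axial face
  position is limited by the focal extent and wanders more.  The fields
  live in pre-expansion coordinates, so the waviness expands with the
  gel and leaves per-line ground-truth EFs exact.

The axial bleach-edge softness (`axial_edge_sigma`, default 1.0 µm)
emulates two-photon bleaching with its focal confinement; values of
several µm emulate the extended one-photon bleach cone.  Together with
the coarser axial sampling, the soft axial edge is what makes the
measured z-EF distribution characteristically wider than x/y — with
these defaults the simulator yields MAD(x, y) below 0.1 and MAD(z)
around 0.2, the regime reported for real acquisitions of this kind.

Determinism: a `SceneSpec` renders bit-identically for a given seed;
`simulate_pair` gives the pre and post renders independent noise
(seed, seed+1) while sharing the specimen texture and waviness fields.

What the simulator does **not** model: vectorial PSFs, refractive-index
mismatch, gelation chemistry, fluorophore-recovery artifacts,
multi-channel imaging.  Passing tests therefore demonstrate the
pipeline's correctness and sensitivity under idealised confocal physics
with realistic texture and sampling — not robustness to optical
aberrations or chemistry-specific artifacts.

## Numerical choices and degenerate inputs

* EF for a zero-length pre line is NaN and excluded — never infinity.
* Index rounding is half-up everywhere (`floor(x + 0.5)`), including
  line matching and middle-plane selection.
* "Bleached" means at-or-below threshold, matching the Otsu convention
  that foreground is strictly above it.
* `rescale_intensity` uses nonzero voxels for its percentiles except
  the exact 0/100 percentiles, which use all voxels (so a full-range
  image is a fixed point).
* Single-line profiles match 0 → 0; two-regime detection requires ≥ 6
  retained lines, slopes ≥ 3; degenerate cases raise informative errors
  tagged with the failing pipeline stage.
* Problem sizes used by the test suite and the acceptance script: the
  default scene (≈ 55 × 240 × 260 voxels pre-expansion), 20–50 replicates
  per property, chosen as the smallest sizes at which the per-line
  statistics are quantization-limited rather than sample-limited.

## Known limitations

* The expansion factor is measured only where the fiducial is — one
  cube per nucleus; the method characterises the expansion locally, not
  as a dense deformation field.
* Squares rotated close to ±45° have an orientation ambiguity (the
  estimate is defined mod 90°); gross rotations should be handled with
  the manual `--angle` override.
* The two-regime test is a two-cluster split: three or more genuine
  regimes would be reported as two.
* Border-outlier rules assume the square's borders are the first/last
  `border_width` lines at each end; heavily fragmented masks (failed
  segmentation) raise rather than silently returning numbers.
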