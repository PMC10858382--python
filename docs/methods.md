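# Methods

## Dosimetry model

Absorbed dose is computed per voxel with the MIRD formalism,

    D_v = Ã_v · Δ · φ / m_v ,

under the maximally local set of assumptions appropriate for α emitters at
the 43-μm voxel scale: every decay of ²²³Ra and of its short-lived
α-emitting daughters (²¹⁹Rn, t½ ≈ 4 s; ²¹⁵Po, t½ ≈ 1.8 ms; ²¹¹Bi,
t½ ≈ 2.1 min, including its 0.28% β branch through ²¹¹Po) occurs in the
voxel where the parent sits, and all α energy is absorbed there (φ = 1).
Cross-voxel kernel transport is deliberately out of scope: with α path
lengths of 50–90 μm the same-voxel assumption overestimates the peak and
underestimates the tails, and the package documents rather than hides that
choice.

**Δ (mean α energy per transformation).** With the chain in secular
equilibrium, one transformation of each daughter accompanies each parent
decay, so Δ sums the intensity-weighted mean α energies per transformation
(ICRP Publication 107 values): 5.667 (²²³Ra) + 6.750 (²¹⁹Rn) + 7.386
(²¹⁵Po) + 6.568 (²¹¹Bi, branch-weighted) = 26.371 MeV = 4.2251 × 10⁻¹²
J/(Bq·s).

**Cumulated activity.** Ã = A(t_biopsy)/λ, the integral of A·e^(−λt) to
infinity with the physical ²²³Ra decay constant only (t½ = 11.43 d). No
biological clearance term is included — the ion is treated as fixed in
bone from the biopsy time point — making Ã a deliberately conservative
(maximal) estimate. For 1 Bq this gives 1.4247 × 10⁶ Bq·s.

**Voxel mass.** The dosimetry voxel is 43.2 × 43.2 × 8 μm (the DAR readout
pitch × the cryosection thickness) = 1.4930 × 10⁴ μm³; densities are
1.92 g/cm³ for bone core and 1.03 g/cm³ for soft tissue *and* the
interface band. A 1-Bq soft-tissue voxel therefore accumulates
Ã·Δ/m ≈ 3.91 × 10⁵ Gy.

**Decay correction.** Calibrated activities are referred to biopsy time by
A_bx = A_ref · e^(λ·Δt) with the readout reference taken at exposure
start. The reference instant matters only through the standards: because
the standards share the section's exposure, any common exposure-duration
factor cancels in the ratio, and exposure start is the self-consistent
choice. Δt = 24 h gives a factor of 1.0625.

## Compartments

The bone–tissue interface is the compartment of interest: a band
extending 50 μm into each of bone and soft tissue from their shared
boundary. A bone pixel joins the band iff its center lies within 50 μm of
the nearest soft-tissue pixel center, and symmetrically — with this
convention a straight boundary at 10-μm pitch yields exactly five band
pixels per side (center distances 10…50 μm), and the band, the two cores
and the background form a disjoint cover of the raster. The band is built
at histology pitch (8 μm), where 50 μm spans >6 pixels, and only then
downsampled to the DAR grid by per-class occupancy majority (ties to the
lower class code), so the ~43-μm DAR pixel cannot quantize the band away.

## Segmentation

Two stages, mirroring a trained-segmenter + clustering workflow:

* **Background vs non-osseous tissue** — the image is partitioned into
  16-px subtiles (ragged edge tiles kept when ≥ half-size); each tile is
  described by the population mean, SD, skewness and excess kurtosis of
  each CIE-L\*a\*b\* channel (12 features, z-scored; higher moments defined
  as 0 for constant tiles); k-means (k = 3, n_init = 10, fixed seed)
  clusters the tiles and the brightest cluster — plus any cluster within
  ΔL\* = 5 of it — is mapped to slide background. Pure-bone tiles are
  outside this dichotomy (pale, low-texture bone sits nearer background
  than tissue in moment space); they are resolved by the next stage, which
  takes precedence.
* **Bone** — a pluggable per-pixel classifier over nine local features
  (L\*, a\*, b\* and their 5×5-window mean and SD). The reference model is
  logistic regression, trained on labeled sections (the reference suite
  uses 20 synthetic sections); the interface accepts any estimator with
  `fit`/`predict`, so a convolutional model can be substituted without
  touching the pipeline.

Labels combine with precedence bone > soft tissue > background, followed
by morphological cleanup that reassigns connected components smaller than
50 px to the majority label of their border.

## Registration

A similarity transform (isotropic scale, rotation, translation about a
center, in DAR pixels) maps histology-aligned coordinates to the acquired
DAR frame. The coarse estimate takes scale from the ratio of foreground
bounding-box diagonals, translation from foreground centroids, and
rotation from the principal axis of the foreground second moments; the
180° axis ambiguity is resolved by mutual information (MI). DAR foreground
is detected at a tenth of the Otsu threshold, closed and hole-filled —
plain Otsu keys on the hot interface voxels and crops the faint
soft-tissue background out of the footprint, biasing the scale estimate.

Refinement maximizes the joint-histogram MI (64 equal-width bins, nats,
empty bins skipped) with multi-start derivative-free Powell search over
(scale, rotation, tx, ty): the coarse estimate, its 180° flip, and ±2 px /
±2° perturbations, within a 2000-evaluation budget; the best-evaluated
transform is always retained, so the final MI can never fall below the
initial one. Two numerical choices matter:

* **Pre-smoothing (σ = 1 px) of both images before MI.** Poisson counting
  noise in the DAR makes the raw MI optimum drift toward transforms that
  shrink the moving image (by 2–4% in scale on landscape scans); the mild
  blur removes the bias without measurably widening the optimum.
* **Overlap-masked evaluation.** MI is computed over in-frame pixels only,
  with bilinear interpolation and constant fill elsewhere.

On 20 seeded phantom pairs (scale ≤ 1.05, rotation ≤ 10°, translation
≤ 8 px) recovery errors are median ≈ 0.07 px, 0.05°, 0.1% — and max
≈ 0.4 px — comfortably sub-voxel.

## Quantification

Co-imaged standards of known per-voxel activity are fit by ordinary least
squares (DLU = slope·Bq + intercept); fewer than three standards or a
non-positive slope is an error, a sub-decade span or an intercept above 5%
of the maximum DLU a warning. Calibrated activities below zero
(background noise) are floored and counted; the detection limit is 3 SD of
background voxels passed through the curve (the dimmest quartile stands in
when no background mask is given).

Activity is quantified **on the acquired DAR grid**, with the compartment
masks warped into that frame by nearest-neighbor resampling, rather than
warping the DAR intensities into the histology frame: bilinear
interpolation of the 1–2-px-wide interface band smears ~8% of its signal
into neighbouring compartments, while mask warping conserves the measured
counts exactly. The histology-aligned DAR image is still produced for
fusion display.

## Synthetic phantom

The phantom emulates the acquisition conditions of a treated bone
metastasis biopsy and is the package's test bed; its defaults are fixed
study conditions, not tuning knobs.

* **Geometry.** A 7.2 × 3.1 mm field at 8 μm/px holding a 6.4 × 2.0 mm
  elliptical core — a 2-mm-diameter biopsy core sectioned lengthwise.
  Trabecular bone is a Gaussian random field low-passed at a 150-μm
  correlation length and thresholded at the quantile giving the requested
  bone volume fraction (default 0.3) inside the core.
* **Activity.** Concentration 25·e^(−d/50 μm) Bq/mm³ at distance d from
  the bone–tissue boundary, plus diffuse backgrounds of 1.5 Bq/mm³ in
  mineralized bone and 0.3 Bq/mm³ in soft tissue, with three ~100-μm
  interface hot spots at 3× gain. The surface value sits at the top of the
  0–27 Bq/mm³ bulk-concentration range reported for real cores; the
  soft-tissue background is set well below the bone value because soft
  tissue is observed as a low-activity background (blood carries only
  ~0.005–0.013 Bq/mm³ at 24 h) while the bone-seeking ion also deposits
  diffusely in mineral — without that asymmetry the soft-tissue core could
  never rank lowest in dose, contradicting the observed compartment
  ordering.
* **Image formation.** Expected decays = activity × exposure (24 h ≪ the
  11.43-d half-life, so activity is constant during exposure and decay
  during exposure is ignored); the misalignment (default scale 1.02, 5°,
  (6, −3) px) is applied to the *fine-grid* activity field before
  integrating onto 43.2-μm detector voxels — warping the already
  voxel-aggregated map would smear the thin interface band by the
  interpolation-kernel width; Gaussian PSF of σ = 17 μm (40-μm FWHM,
  matching the nominal 600-dpi readout resolution); Poisson counting;
  linear gain of 1 DLU/decay. Standards are uniform 12×12-voxel patches
  (2×10⁻⁴…2×10⁻³ Bq/voxel, ≥ 2.5×10³ expected counts each) rendered
  through the same PSF/noise/gain path in a reserved strip.
* **Determinism.** Every stochastic stage draws from its own stream
  seeded by (stage, seed), so identical configs are bit-identical and
  stages can be regenerated independently.

What the phantom does **not** emulate — and hence what passing tests do
not show about real data: nuclear-track statistics and plate-fading of
real storage phosphors, staining variability and nucleus-scale H&E
texture, marrow cellularity, deformable (non-rigid) section distortion,
and 3-D continuity across serial sections. The segmentation scores on
phantoms (Dice ≈ 0.999) reflect the crisp three-color rendering and upper-
bound what any real section would give; the registration and dosimetry
results depend only on geometry, counting statistics and calibration and
transfer more directly.

## Problem sizes and runtimes

The reference suite and the acceptance script run sections of 896 × 384
histology px (~165 × 71 DAR px), 20 registration pairs, a 20-section
training corpus, and 3 end-to-end seeds — sizes chosen so the full chain
exercises every stage in about a minute on one CPU while keeping ≥ 10⁴
pixels per tissue class for the statistical checks.

## Known limitations

* Same-voxel energy deposition (φ = 1) is an upper bound at the interface
  and ignores dose to voxels with no activity; an α-kernel convolution
  would redistribute 10–30% of interface energy outward.
* The end-to-end mean interface dose is recovered to ~5–10% low, a real
  measurement property (PSF loss out of the band, partial-volume effects
  of a rotated 100-μm band on a 43-μm grid, slight segmentation widening
  of the band), not a correctable bug; the acceptance suite measures it.
* Daughter redistribution (²¹⁹Rn diffusion), relative biological
  effectiveness weighting, and marrow-toxicity modeling are out of scope.
* The k-means tile stage resolves only the background/non-osseous
  dichotomy; bone identification rests entirely on the trained classifier.
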