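# Methods

`glottikit` implements a fully automatic pipeline for detecting and tracking
the glottal gap — the opening between the vocal folds — in high-speed
videoendoscopy (HSDI, thousands of frames per second, typically 256×256
pixels), and for synthesising motion- and rotation-compensated
videokymograms (VKG) along the estimated glottal main axis. This note
documents the model behind each stage, the parameters that matter, the
synthetic phantom used for validation, and the numerical choices made where
the design was genuinely open.

## Pre-processing: row-wise non-linear enhancement

Laryngeal frames have low contrast, inhomogeneous illumination, and
occasional whole-frame light flashes. Each row *i* is normalised against its
own lighting level

    L_i = (1 / (m·β)) Σ_j I(x_j, y_i),

i.e. the row mean divided by the contrast factor β. Pixels above L_i
saturate to 255; pixels at or below it are remapped by
`255·(I/L_i)^ζ`. Because L_i scales with the row mean, a multiplicative
flash raises L_i proportionally and the transform cancels most of its
effect; because the glottis is the darkest structure, the power law (ζ =
1.8) pushes it towards 0 while tissue saturates.

Two β conventions circulate for this transform: the row-divisor factor
itself (worked value 1.3) and a ×100 scale on which 100–300 are swept and
200 preferred. `EnhanceParams` stores the divisor (default 2.0 ≡ 200 on the
×100 scale); `EnhanceParams.from_results_scale` converts. Outputs are
rounded half-up and clipped to [0, 255]; an all-zero row maps to 0 (no
division by zero).

## Adaptive ROI from temporal intensity variation

The glottis is the structure with the largest *temporal* intensity change,
so it can be located before any segmentation. Per block of N frames the
column profile `S_c(x,t)` (mean over rows), its time average `AIV_c(x)`,
and the mean absolute deviation `TIV_c(x)` are computed; `TIV_c` is
Gaussian-shaped with its mode on the glottal main axis. A non-linear
least-squares Gaussian fit (initialised at the profile maximum, σ₀ from the
full width at half maximum, σ bounded to [1, profile length]) gives μ_x,
σ_x; the window is `μ ± κσ` with κ = 2 (the useful range is 2–3), rounded
outward (floor/ceil) so the ROI never shrinks by rounding. Rows are fitted
the same way *inside* the column window — columns first because the glottal
axis is quasi-vertical (> 30° from horizontal). TIV is computed on the
*enhanced* cube: enhancement demonstrably sharpens the Gaussian shape of
the profile.

The block length N trades cycle coverage against endoscope drift: one
glottal cycle is `gc_o = round(frame_rate/f0)` frames, one endoscope-motion
cycle `mc_e = round(frame_rate/f_e)` with f_e ≈ 15 Hz, and N must lie in
[gc_o, mc_e]. The default is `min(3·gc_o, mc_e)`: three cycles smooth the
TIV profile while staying far from drift corruption. When f0 is unknown it
is estimated from the dominant autocorrelation lag of the frame-mean
intensity over the first endoscope cycle. Blocks with no temporal signal
inherit the previous window (or the full frame for a first block); the
trailing partial block reuses the last full-block window. The block length
is additionally capped at the recording length.

Within each block, the *max-opening* frame is the one minimising the summed
ROI intensity (the open glottis contributes the most dark pixels); ties
break to the earliest frame. The glottal center G₀ = (μ_x, μ_y) is the
intersection of the two fitted means.

## Segmentation: watershed + JND merging + template correlation

The Sobel gradient magnitude of the enhanced ROI frame is normalised to
[0, 255] and floored at 10 (sub-threshold micro-edges become basin
interiors), then flooded by an unseeded 8-connected watershed. The
resulting over-segmentation is repaired in two merging stages.

**Perceptual (JND) merging.** Adjacent regions merge when a human could not
tell their mean grey levels apart. The just-noticeable-difference curve

    JND(k) = 17·(1 − √(k/127)) + 3   (k ≤ 127)
    JND(k) = (3/128)·(k − 127) + 3   (k > 127)

is continuous at k = 127 (value 3), with JND(0) = 20 and JND(255) = 6. The
merging cost `F_c = |mR₁ − mR₂| − min(JND(mR₁), JND(mR₂)) + 255` is
compared with Thr = 265, i.e. regions merge when their mean difference is
within JND + 10 grey levels. Before that, every region brighter than the
Otsu threshold of the block's max-opening ROI frame is collapsed into a
single background region, which removes most tissue clutter. Agglomeration
proceeds lowest-cost-first with means recomputed after every merge (a
deterministic order; verified against exhaustive agglomeration on small
maps).

**Template-correlation merging.** A canonical glottis-shaped stencil — a
vertically elongated lens bounded by two circular arcs, black interior on a
white surround with a 1-px white margin — is resized to
`(round(0.30·w) × round(0.284·h))` of the active ROI (12×42 at the 40×148
reference ROI) and slid over the frame with the zero-normalised
cross-correlation coefficient (invariant to affine intensity changes;
zero-variance patches score 0). If the best score is below 0.45 the glottis
is declared *fully closed* and the frame's mask is empty. Otherwise the
correlation zone is the union of lens footprints at all above-threshold
placements, and every non-background region overlapping the zone survives —
which is what keeps a glottis split into two dark blobs intact. The stencil
is rendered with a 1-px anti-aliased edge: a strictly binary stencil was
measured to correlate far worse after automatic resizing.

## Refinement: localized region-based active contour

The candidate mask initialises a level set evolving under the localized
uniform-modelling (Chan–Vese) energy: at each pixel the interior and
exterior are modelled by their means inside a disk of radius 5, computed by
FFT convolution, so inhomogeneous illumination does not pull the contour
off the glottal edge. The speed is the difference of squared residuals
against the local means (normalised to unit maximum), plus curvature
regularisation with weight 0.2 and CFL-stable step 0.45; the level set is
rebuilt as a signed distance every 20 iterations and run for a fixed 100
iterations. Components not connected to the initialisation are discarded;
two initial components closer than twice the radius may merge — the
expected behaviour when a "split" glottis is one gap. An empty
initialisation (closed frame) passes through untouched. Evolution is
full-domain rather than narrow-band: ROI frames are small (~60×150) and the
simpler scheme is well within budget.

## Glottal main axis and videokymogram synthesis

The axis g is the darkest straight line through G₀: orientations are
searched every 0.5° over the quasi-vertical range 30°–150°, each scored by
the mean bilinear-sampled intensity inside the ROI, with ties broken toward
vertical (a uniform ROI returns vertical with a warning). The line model
y = θ₀ + θ₁x cannot represent vertical axes, so the search is
parameterised by angle with θ₁ = tan(α) available for reference.

The posterior (P, g = 1%) and anterior (A, g = 100%) endpoints are the two
outermost abrupt intensity transitions along the axis profile: candidates
exceed half the maximum absolute gradient, candidates within 2 samples of
the ROI border are excluded, and interior bright peaks (a split glottis)
are ignored. The profile is sampled at half-pixel steps so a sharp
transition spans several samples and survives the border exclusion even in
a tight κ = 2 window. If all candidates lie on a single transition (one
sharp edge, or a uniform-gradient ramp) detection fails explicitly and the
pipeline falls back to the extremes of the segmented mask along the axis.

Kymograms sample, in every frame, the segment perpendicular to g at a
station g% of the P→A span (length 1.5× the ROI width). Motion
compensation shifts the segment by the active block's ROI-center offset
relative to the first block — endpoints are re-anchored to the first
block's center so the offsets compose correctly — and the perpendicular
orientation provides rotation compensation. Samples outside the frame are
edge-padded with a warning. On a drifting phantom, per-cycle blocks
(N = gc_o) reduce kymogram mid-line jitter by ~80% versus an uncompensated
scan.

## Evaluation metrics

* **Pratt figure of merit**: `(1/max(N_ref,N_det)) Σ 1/(1 + d²/9)` over
  detected boundary pixels, d the distance to the nearest reference pixel
  (scaling constant a = 1/9). Both empty → 1, one empty → 0.
* **OCE similarity**: 1 − object-level consistency error; objects are
  8-connected components, each reference object scores a size-weighted sum
  of Jaccard overlaps with the objects it touches, objects are averaged by
  area, and the two directional errors are symmetrised by their minimum.
  Splitting one object into fragments is penalised beyond the plain
  Jaccard of the union.
* **PSNR / EOR / MSOR** for enhancement: peak signal-to-noise ratio capped
  at 99 dB for identical images; edge overlap ratio of Canny edge sets
  (σ = 2, invariant to constant offsets); mean segment overlap ratio of
  watershed segments matched by best Jaccard. EOR/MSOR sub-parameters
  (edge-detector sigma, gradient floor) are frozen defaults.

## The phantom

Real recordings are not required anywhere: the seeded phantom renders a
lens-shaped gap with half-width profile
`w(s,t) = max(chink(s), w_max·osc(t)·sin(πs))` on a textured tissue field
(level ~170, low-frequency cosine shading plus frozen Gaussian grain — the
grain deliberately makes the watershed over-segment, which is the failure
mode the merging stages exist to fix). `osc` is a clipped sinusoid whose
clip level is chosen analytically so the fully closed part of each cycle
occupies exactly `closed_fraction` of the period. Optional artifacts, each
behind a flag: posterior chink (permanent tapering half-width), a bright
bridge splitting the gap, anterior arytenoid occlusion, camera-fixed black
corner artifacts, per-frame multiplicative flashes, 15 Hz sinusoidal camera
drift, additive Gaussian noise. All randomness flows from a single seeded
generator; identical specs give bitwise-identical videos, and the ground
truth (masks, area waveform, axis, drift trace, per-cycle max-opening
frames, flash frames) is returned alongside.

Defaults emulate a typical recording: 4000 fps, f0 = 120 Hz (33
frames/cycle), 256×256 frames, 90-px glottis, 9-px maximal half-width, 30%
closed phase, drift 15 Hz. Six frozen presets (`clean`, `chink`, `split`,
`occluded`, `drift`, `full`) ship as YAML in the package.

What the phantom does *not* model: mucosal-wave kinematics, left/right
asymmetry, specular highlights, depth/zoom changes, MPEG compression
artifacts, or real tissue texture statistics. Passing tests therefore
demonstrate the pipeline's mechanics (ROI tracking, merging logic, closure
detection, axis/VKG geometry) under controlled difficulty, not clinical
accuracy on patient recordings.

## Problem sizes and known limitations

Validation runs use 150–267-frame phantoms at 256×256 — a few glottal
cycles and up to one full drift cycle — which exercises every code path
while keeping the whole suite around two minutes on one CPU.

Known limitations:

* **Thin posterior chinks.** A chink rendered 1–2 px wide correlates at
  0.31–0.43 with the lens template, below the 0.45 matching threshold, so
  chink-only frames are declared fully closed. This mirrors the method's
  own stated weakness for posterior chinks; on the stress preset those
  frames cap the mean open-frame Dice near 0.70 while clearly open frames
  score ≈ 0.95.
* **Non-vibrating glottis.** The ROI is defined by temporal variation; a
  static (paralytic) glottis produces no TIV signal and the tracker falls
  back to the full frame.
* **Straight-axis assumption.** Curved glottal axes are approximated by
  their best straight line; kymogram stations inherit the approximation.
* **Per-block compensation.** Motion compensation is piecewise constant
  per block; residual within-block drift survives, shrinking with N.
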