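# glottikit

Automatic detection and tracking of the glottal gap in high-speed
videoendoscopy (HSDI), with automatic multi-line videokymogram synthesis.

Clinical analysis of vocal-fold vibration — periodicity, closure defects,
glottal area waveform (GAW), videokymograms (VKG) — rests on an accurate,
frame-by-frame delineation of the glottis, the dark opening between the
vocal folds. At thousands of frames per second, manual delineation is
impossible and naive thresholding fails on low-contrast, drifting,
flash-ridden recordings. `glottikit` implements a fully automatic pipeline
for researchers and engineers working with laryngeal high-speed imaging:

1. **Enhancement** — row-wise non-linear transform
   `I → 255·(I/L_i)^ζ` (saturating above the row lighting level
   `L_i = mean/β`), darkening the glottis and suppressing flashes
   (β divisor 2.0, ζ 1.8).
2. **Adaptive ROI** — per block of N frames, the total intensity variation
   profiles `TIV_c(x)`, `TIV_r(y)` (mean absolute deviation of
   column/row means over time) are fitted with Gaussians; the window is
   `μ ± κσ` (κ = 2), re-estimated every N frames to follow ~15 Hz
   endoscope drift. N defaults to three glottal cycles,
   `gc_o = round(frame_rate/f0)` each.
3. **Segmentation** — floored Sobel-gradient watershed, then two merges:
   perceptual merging with the just-noticeable-difference cost
   `F_c = |mR₁−mR₂| − minJND + 255 < 265` plus Otsu background
   suppression, and correlation merging against a resizable lens-shaped
   glottis template (normalized cross-correlation; best score < 0.45 ⇒
   glottis fully closed).
4. **Refinement** — localized Chan–Vese active contour (disk radius 5,
   100 iterations) smoothing and completing the boundary.
5. **VKG synthesis** — the glottal main axis is the darkest line through
   the glottal center G₀ = (μ_x, μ_y); kymograms are sampled perpendicular
   to it at stations g = 1..100% of the posterior→anterior span, with
   endoscope-motion and rotation compensation.

A seeded phantom generator renders synthetic HSDI with ground truth
(oscillating lens-shaped gap, posterior chink, split glottis, occlusion,
flashes, camera drift, corner artifacts), so the whole pipeline is testable
without any patient data.

## Worked example

```python
import glottikit as gk
from glottikit.pipeline import RunConfig, segment_video, run_vkg

spec = gk.load_preset("clean", n_frames=200, seed=1)   # 4000 fps, f0 120 Hz
cube, truth = gk.generate(spec)

cfg = RunConfig(roi_f0_hz=spec.f0)
track = segment_video(cube, cfg)

import numpy as np
from glottikit.eval_metrics import dice
open_f = truth.areas > 0
print("mean Dice (open frames):",
      round(float(np.mean([dice(track.masks[t], truth.masks[t])
                           for t in np.nonzero(open_f)[0]])), 3))
print("closed-frame specificity:",
      round(float(np.mean([track.masks[t].sum() == 0
                           for t in np.nonzero(~open_f)[0]])), 3))
print("GAW head:", track.areas[:8])
```

prints

```
mean Dice (open frames): 0.862
closed-frame specificity: 1.0
GAW head: [330 458 576 684 759 851 925 966]
```

The Dice coefficient compares each predicted mask with the phantom's ground
truth over the frames where the glottis is actually open; the specificity is
the fraction of truly closed frames for which the pipeline correctly emits
an empty mask; the GAW is the glottal area in pixels per frame — the
waveform clinicians read for closure behaviour.

From a shell, the same pipeline (plus kymograms and metrics) runs as:

```
glottikit phantom --preset clean -o ph --seed 1
glottikit segment ph/frames -o out --f0 120
glottikit vkg ph/frames -o out_vkg --g 50
glottikit eval --pred out --truth ph/truth_masks
```

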