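# Methods

## Problem and approach

Exocytosis of large dense-core vesicles, imaged by TIRF microscopy, shows
up as a punctum whose fluorescence rises transiently and then disappears
abruptly and completely.  `exotrack` detects the puncta frame by frame,
links them over time, and calls events from the intensity traces.  Every
stage is validated against synthetic scenes whose ground truth (circle
positions, counts, event frames) is stored at generation time, never
re-derived from pixels.

## Synthetic scenes

A scene is a list of discs — pixel (y, x) is foreground iff
(y − y₁)² + (x − x₁)² ≤ r² for some circle — on a uniform background.
Layouts are classified from pairwise center distances as distinct
(all pairs separated by more than the sum of radii), tangent (some pair
touching exactly), or intersecting.  Circles partially outside the frame
are clipped; fully outside is a specification error.

Noise is composed as `final = w₁·N₁ + w₂·N₂ + (1 − w₁ − w₂)·raw` with each
noise field min-max normalized to [0, 1] before weighting, so the output
stays in [0, 1].  Defaults, chosen once as a plausible emulation of a
low-SNR TIRF frame and used as the study conditions throughout:

| parameter | default | meaning |
|---|---|---|
| w₁, w₂ | 0.2, 0.2 | noise weights (40% of each pixel is noise) |
| N₁ | Gaussian | zero-mean, σ = 0.1 of dynamic range, then normalized |
| N₂ | Poisson | per-pixel rate = 50 × raw intensity (shot noise), then normalized |
| foreground / background | 1.0 / 0.0 | disc and background intensity of static scenes |

Time-lapse stacks add a per-particle event schedule: the disc's contrast
above background is multiplied by a factor that rises linearly from 1 at
`rise_start` to `peak_amplitude` at `peak`, holds, and drops to pure
background at `loss` — a stylized fusion signature.  Event stacks use
foreground 0.6, background 0.05 and peak_amplitude 1.7, picked so the peak
stays below saturation (0.05 + 0.55·1.7 ≈ 0.98) while clearing the event
caller's 1.4× rise threshold with margin.  Each frame gets an independent
noise draw from one seeded generator, so a stack is reproducible from its
scene seed.

What the generator does **not** emulate: a realistic point-spread function
(discs are hard-edged, real puncta are PSF-blurred), camera gain/offset and
EM-CCD excess noise, photobleaching, drift, or sub-pixel motion.  Tests
passing on these scenes show the algorithmic contracts hold (counts,
maxima, event logic); they do not certify performance on real microscope
data, whose noise is messier and whose puncta are dimmer and blurrier.

## Detection

**Wiener preprocessing.**  The adaptive local mean/variance estimator with
a 5×5 window and reflect border padding; the noise power defaults to the
mean of the local variances.  Filtering is float64 internally regardless of
input dtype.  The filter is a contraction, not a projection: because the
noise power is re-estimated on each application, a second pass still
changes pixels by a few percent (it shrinks by ~5× per pass on a denoised
frame).  With a fixed noise power of zero it is exactly the identity.

**Blockwise Otsu.**  Histograms use 256 bins spanning the *frame's*
[min, max] so per-block thresholds are comparable; the threshold level
maximizes the between-class variance from the zeroth/first cumulative
moments, ties broken toward the lowest level for determinism.  Foreground
is `≥ threshold`.  Blocks whose intensity range is below 10⁻⁶ of the frame
range, or whose histogram has a single populated bin, are classified as
background: a featureless block must not hallucinate foreground (manual
per-block overrides cover the rare pure-foreground block).  Edge blocks are
thresholded as-is rather than padded, which would import foreign
statistics.  Per-block thresholds are applied hard, with no smoothing
across block boundaries; blocking artifacts in the mask are possible but
are absorbed by the subsequent morphology.

**Mask refinement.**  Closing with a disc of radius 100 px, dilation with
radius 5, opening with radius 3 (the dilation and opening radii accept
±3 / ±1 tuning with a warning outside that range).  Erosion and dilation
are computed by thresholding the Euclidean distance transform, which is
exact for disc elements and tractable at radius 100; the closing pads the
canvas by the radius first so the erosion sees the full dilated set —
without this, a radius-100 closing of a 128 px image would erase
everything, since no pixel is 100 px from the border.  Borders are
background-padded: objects touching the edge are neither artificially
preserved nor destroyed.  The closing radius is a config key; 100 px is
the default regardless of magnification.

**Punctum detection.**  The refined mask zeroes the background, the masked
frame is rescaled to [0, 1], and a Wiener → unsharp (amount 1.0, σ = 1.0)
→ Gaussian (σ = 1.0) filter bank smooths the surface.  Puncta are regional
maxima under 8-connectivity — connected equal-value plateaus strictly
brighter than their surroundings — each represented by its plateau centroid
rounded half-down, so one maximum yields exactly one deterministic
detection.  The H-Max transform (reconstruction-by-dilation of f − h under
f) removes maxima of prominence ≤ h before extraction.  Whether
"over-segmentation occurs" cannot be decided mechanically, so H-Max is
applied always, with h = 0.05 of the normalized range; on well-separated
puncta it is a no-op, while on fragmented ones it collapses shallow
sub-peaks (on a 25%-noise scene it reduces ~160 spurious maxima to the
true 5).  The preprocessing-stage and detection-stage Wiener windows are
independent config keys (`pre_wiener_window`, `wiener_window`), both
defaulting to 5.

## Tracking and event calling

Linking is greedy mutual-nearest-neighbor within 3 px, with no gap
closing: a disappearance is biologically meaningful here, so a vanished
punctum ends its track.  Global-optimization trackers are deliberately
out of scope — the method targets nearly stationary docked vesicles, and
on such data mutual-nearest linking agrees with the optimal assignment
(verified against exhaustive min-cost matching in tests).  Rapidly moving
vesicles exceed the link gate and fragment into short tracks; that is a
stated limitation, not a failure mode to be patched with motion models.

If the median frame-to-frame displacement across all tracks is below 1 px,
the stack is static: anchors are the first frame's detections and traces
are read at fixed positions (this also keeps a trace alive through the
fusion flash, when detection-based tracking would lose the punctum).

A trace value is the mean of the anchor pixel and its 4-connected
neighbors; border anchors average the in-bounds subset and are flagged.
Event calling scans the trace with a running baseline equal to the median
of the preceding 10 frames (median, so an in-progress rise does not inflate
the baseline).  Onset: first frame above 1.4× baseline.  Loss: first later
frame below 0.25× baseline with the next 5 frames also below.  Peak: the
trace maximum between onset and loss.  A rise that never loses signal — a
docked granule that fails to fuse — is not an event.  All thresholds are
config; the defaults suit 20 fps acquisition where an abrupt loss completes
within a few frames.

## Validation workbench

The Find-Maxima baseline counts maxima whose prominence (height above the
highest saddle toward a higher maximum) exceeds a tolerance, implemented as
persistence of 8-connected super-level-set components via union-find over
pixels sorted by brightness.  It is a reimplementation of the counting
semantics, not a wrapper around ImageJ, and byte-level concordance with the
plugin is a non-goal.

`run_benchmark` renders a scene suite, counts puncta with the pipeline and
the baseline, and compares algorithm counts to the reference (generated
truth, or optional manual counts from CSV) with a two-sided paired t-test.
Identical count vectors leave the t statistic undefined (0/0); they are
reported as an exact match with p = 1, the strongest possible support for
equivalence.  A constant nonzero difference (pure bias, zero variance) is
reported as p = 0.  Per-stage runtimes are not benchmarked: they are
hardware-dependent.

## Problem sizes and numerical choices

The validation studies run on 128×128 frames: 10-scene count benchmarks
(5–20 puncta, radii 3–6 px, w₁ = w₂ = 0.2), a noiseless exactness sweep
over radii 2–10, and event-recovery studies of 50 thirty-frame stacks with
0–5 scheduled events each (w₁ = w₂ = 0.1) plus 20 event-free stacks of
docked particles — sizes at which the full pipeline still runs in seconds
per stack while exercising every stage.  Degenerate inputs are handled
conservatively: constant frames normalize to zeros with a warning, empty
masks yield zero detections with a warning rather than an error, and an
h ≥ dynamic range warns that all peaks will be suppressed.  Detection
counts are invariant to affine intensity rescaling of the input (the
normalization steps see only ranks); detection *positions* can shift by a
pixel under rescaling, from floating-point ties at plateau boundaries.

## Known limitations

- No sub-pixel localization or PSF fitting; positions are lattice points.
- Hard per-block thresholds can produce mask seams under extreme
  gradients within a single block.
- The event criterion is a declared parameterization of a qualitative
  signature; thresholds will need retuning for probes with different
  intensity dynamics.
- Synthetic validation bounds what can be claimed: real-cell and bead
  performance must be established on real data with manual annotation
  supplied via the manual-counts CSV path.
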