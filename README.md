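# exotrack

Automated detection of large dense-core vesicle (LDCV) exocytosis in TIRF
time-lapse movies.

In total internal reflection fluorescence (TIRF) microscopy of secretory
cells — for example insulin-granule markers in pancreatic islet cells —
docked vesicles appear as small bright puncta near the plasma membrane.
An exocytosis event has a distinctive fluorescence signature: a transient
rise in the punctum's intensity followed by complete, abrupt loss of signal
as the cargo diffuses away after fusion.  Counting puncta and calling these
events by eye is slow and irreproducible; `exotrack` automates both, and
validates itself against synthetic images whose ground truth is known
exactly because it is generated, not annotated.

## Pipeline

For each frame of a stack `I_t`:

1. **Denoise** — adaptive Wiener filter
   `Î = m + max(v − n, 0)/v · (I − m)` with local mean `m`, local variance
   `v` over a 5×5 window, and noise power `n` (mean of local variances).
2. **Binarize** — Otsu's threshold (argmax of the between-class variance
   `σ_B²(k) = [μ_T ω(k) − μ(k)]² / [ω(k)(1 − ω(k))]` over the zeroth/first
   cumulative histogram moments), applied per 32×32 sub-image so uneven
   illumination cannot hide dim puncta (16×16 and manual per-block
   thresholds available).
3. **Refine mask** — morphological closing (disc r = 100 px, bridging gaps
   within a cell cluster), dilation (disc r = 5), opening (disc r = 3).
4. **Detect puncta** — zero the background, rescale to [0, 1], apply
   Wiener → unsharp sharpening → Gaussian filters, then take the
   **regional maxima** of the intensity surface; the **H-Max transform**
   (grayscale reconstruction of `f − h` under `f`, default h = 0.05)
   removes maxima of prominence ≤ h to control over-segmentation.
5. **Track & call events** — mutual-nearest-neighbor linking (≤ 3 px);
   if the median frame-to-frame displacement is below 1 px the stack is
   treated as static and first-frame positions are used throughout.  Each
   punctum's trace is the mean of its pixel and 4-connected neighbors; an
   exocytosis event is called when the trace exceeds 1.4× its running
   median baseline and subsequently stays below 0.25× baseline for ≥ 5
   frames.

A synthetic-scene module generates the validation inputs: discs
`(x − x₁)² + (y − y₁)² ≤ r²` in distinct/tangent/intersecting layouts,
noise composed as `w₁·N₁ + w₂·N₂ + (1 − w₁ − w₂)·Raw` with each noise
field normalized to [0, 1], and time-lapse stacks with scheduled
rise-then-loss signatures.  An ImageJ-style Find-Maxima baseline
(prominence counting) is included for comparison.

## Worked example

```
$ python examples/benchmark_counts.py
 image_id  truth_count  algo_count  baseline_count
        0           12          12              12
        1           18          18              18
        ...
        9           17          17              17

mean |count error| = 0.000 ± 0.000 (SEM)
paired t-test algorithm vs truth: p = 1  (counts identical on every image)
p > 0.1: no significant difference between detected and true counts
```

Ten artificial scenes (5–20 puncta of radius 3–6 px, 40% of each pixel's
value replaced by normalized Gaussian + Poisson noise) are generated with
stored truth and counted by the full pipeline.  The detected count matches
the truth on every image, so the paired t-test finds no difference — the
count-equivalence claim the package exists to support.  The other examples
(`simulate_scene.py`, `detect_puncta.py`, `call_events.py`) walk through
scene generation, single-frame detection, and event calling:

```
$ python examples/call_events.py
motion mode: static_first_frame (3 tracks from per-frame detections)
scheduled events: 1 (particle 1, loss at frame 20)
called event: track 1, onset 16, peak 17, loss 20, peak/baseline = 1.53
```

## Command-line interface

The same pipeline is scriptable from a shell; every command is a thin
wrapper over the library:

```
exotrack simulate --config scene.yaml --out-prefix demo     # TIFF + truth CSVs
exotrack detect   --input demo.tif --out detections.csv
exotrack events   --input demo.tif --out-prefix results     # tracks/traces/events CSVs
exotrack evaluate --config suite.yaml --out-prefix bench    # counts + summary
```

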