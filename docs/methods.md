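# Methods

This note documents the model, the choices made where the published method
is under-specified, the synthetic data the package is validated on, and what
that validation does and does not show.

## Pipeline model and assumptions

The cascade assumes a single hypoechoic (dark) cyst in an echogenic,
speckle-textured field, imaged as an 8-bit grayscale frame. All clustering
operates on intensity alone; no spatial regularization, shape prior or
speckle filtering is applied. Inputs deeper than 8 bits are min-max rescaled
to 0–255 before anything else, because the histogram stage's reference
density `d = (W·H)/255` presumes 256 bins. Multi-frame (cine) DICOM is
rejected rather than silently truncated.

### Fuzzy stretching

The published trapezoid leaves its center and shoulders undefined. This
package sets the plateau center `I_mid` to the mean intensity and the
shoulders to `I_mid ± s` with `s = shoulder_scale · std` (default
`shoulder_scale = 1`), clipped inside `(I_min, I_max)`. Rationale: the
plateau then sits on the dominant echo level and widens with intensity
spread, which is the regime fuzzy stretching is meant for (irregular,
non-uniform distributions). The right-hand ramp denominator is
`I_max − I_midR` (the standard trapezoid). The α-cut is
`min(δ + 0.5, 1)` with `δ = (I_mid + (I_max + I_min)/2)/255`; because δ is
≥ 0.5 for all but very dark frames, the α-cut saturates at 1 and the
stretched band is exactly the plateau.

The *dark-noise mask* flags stretched pixels below a threshold, excluded at
object formation. The default threshold is the band's lower edge expressed
in output units — which is 0 by construction, so the default mask is empty
and the filter is activated only by an operator (`--dark-threshold`, in
stretched units). On clinical frames a small positive value removes
anechoic sector borders and shadowing; on the synthetic phantoms there is
no such structure, so nothing is lost by the inert default.

Constant frames raise a degenerate-image error: every later stage assumes
non-zero dynamic range.

### Histogram-domain density clustering

Density clustering runs on the histogram of the **input region**, not the
stretched frame. Integer stretching with gain above 1 maps the input gray
levels onto a periodic subset of 0–255 (a comb), in which no two populated
bins are adjacent; run detection at radius `ε = 1` is then degenerate. The
stretched frame feeds only the FCM back-end and the noise mask.

Bins `k, k'` are neighbors iff `|k − k'| ≤ ε`; with `ε = 1` clustering
reduces to maximal-run detection, but the implementation accepts any ε. On
the side of the histogram above the mean, runs of bins denser than `d`
qualify; below the mean, runs of bins **no denser** than `d` qualify — the
published rule, kept as the default even though it is asymmetric
(`low_side_high_density` switches to the symmetric predicate). Runs shorter
than `Pts_min` bins are disqualified and their pixels marked as removable
noise. A qualified run may cover only empty bins (its pixel count is zero);
`DBSCAN_pmax` is therefore the maximum intensity over pixels of all
qualified clusters and may be undefined.

One property worth noting: the qualified-cluster count is **not** monotone
in ε — two sub-`Pts_min` runs can merge into one qualifying run as ε grows.
Only the candidate-run count (before the length filter) is monotone; the
test suite freezes a counterexample.

### The cluster-count rule

`FCM_ct` = 0 / 2 / 4 as in the README. Two interpretation choices:

* **Which clusters are counted.** The count feeding the rule defaults to the
  *low-side* qualified clusters (`count_side` config). The front-end's
  clusters are described as candidates of the (dark) cyst, and counting both
  sides makes the unimodal branch `ct = 1 → c = 4` unreachable in practice:
  on any smooth unimodal frame the low-intensity tail contributes one run
  and the background mode another, so the combined count is never 1 — yet
  the unimodal frame is exactly the case the fine four-way split exists
  for. Both alternatives remain available via configuration.
* **Degenerate guards.** With no qualified clusters, or with `DBSCAN_pmax`
  undefined (qualified clusters covering only empty bins), the pmax guard
  cannot fire and the rule falls through; `ct = 0` lands on the default
  `FCM_ct = 2` (rationale recorded as `default-no-clusters`).

The boundary `pmax = mean` fires the skip-FCM branch (`≤` as published).

### Fuzzy C-means

Standard Bezdek alternating optimization in 1-D; fuzzifier `m = 2`;
termination when the max absolute membership change drops below `tol`
(default 1e−5 — the published method names a threshold but not its value);
`U(0)` is a seeded random column-stochastic matrix. The membership update
uses the standard ratio `(d_ik/d_jk)^{2/(m−1)}`; the reciprocal form that
appears in some statements of the algorithm does not decrease the stated
objective. Zero-distance points get crisp membership. Fitting is
histogram-accelerated: distinct intensities weighted by pixel count, which
is algebraically identical to per-pixel fitting (all updates depend on a
pixel only through its value) and bounds the data size at 256. Centroids
are returned sorted ascending, so cluster 0 is always the darkest;
label-map ties resolve toward the darker cluster.

When the rule requests more clusters than the stretched frame has distinct
intensities (e.g. a two-level frame with `FCM_ct = 4`), `c` is clamped to
the distinct-value count and recorded as `c_effective` in the run report;
fitting fewer than 2 would be meaningless and raises instead.

### Object formation

The candidate is the darkest FCM cluster (configurably the `n` darkest), or
on the FCM-skipped path the pixels of low-side qualified histogram clusters.
After subtracting the noise mask, connected components (8-connectivity by
default) smaller than `min_area_frac` of the region (default 0.05%) are
dropped and the largest survivor is returned. Empty output is a *failed
extraction*, reported, never an exception. No hole filling by default;
`--fill-holes` is available.

## Evaluation protocol

TP/FP/FN pixel counts only — the true-negative background is meaningless
for a small object in a large frame. "Accuracy" is `TP/(TP+FP+FN)·100`,
i.e. the Jaccard index on pixel sets. Undefined metrics (zero denominators)
are flagged and excluded from means, never zero-filled. Metrics are
macro-averaged per frame over **accepted** extractions.

The largest protocol substitution in this package: the study's acceptance
judgment is made by radiologists; here an extraction is accepted iff it is
non-empty and (IoU ≥ 0.5 **or** predicted centroid inside the truth). The
threshold is configurable. Reported extraction rates are therefore proxy
rates and not comparable in absolute terms with human-judged rates.

The benchmark's significance column (paired Wilcoxon signed-rank on
per-frame accuracy, proposed vs FCM baseline, over jointly accepted frames)
is an artifact choice — the comparison protocol it mirrors marks
significance without naming a test.

The standalone-FCM baseline shares stretching, noise handling and labeling
with the cascade and differs only in using a fixed `c`
(`standalone_fcm_c`, default 2 — the classic object/background split). A
fixed coarse `c` yields a wider, less precise dark cluster than the
adaptive cascade, which is the behavioral contrast the three-method
comparison probes; the baseline with `c = 4` would be identical to the
cascade's dominant branch and probe nothing.

## Synthetic phantoms

`cystseg.phantom` renders an echogenic background with one dark elliptical
or lobulated (union of 2–3 ellipses) cyst:
`image = clip(round(base · noise))`, `base` interpolating background→cyst
level across a Gaussian-blurred boundary (`border_sigma`, px), `noise`
unit-mean multiplicative gamma speckle with dispersion `speckle_scale`
(variance = scale²; 0.5 approaches fully developed speckle). The truth mask
is the pre-blur support, so geometry is decoupled from noise; tier areas are
calibrated to their sampled target by one sqrt-rescale of the ellipse union.

Tier defaults (fixed once, from the target population: cyst areas 220–31,514
px, median 4,647):

| tier   | truth area (px) | contrast (levels) | speckle scale | border σ (px) |
|--------|-----------------|-------------------|---------------|---------------|
| easy   | 5,000–28,000    | 60–110            | 0.05–0.20     | 0.0–1.5       |
| medium | 1,000–10,000    | 30–60             | 0.20–0.30     | 0.5–2.0       |
| hard   | 220–4,647       | 15–30             | 0.30–0.50     | 1.0–2.5       |

Background level is uniform in 120–180 for all tiers; frames are 256×256.

**What the phantoms do not emulate:** sector geometry and anechoic frame
borders, posterior acoustic enhancement (optional in the generator, off by
default, matching the observation that small cysts often lack it), depth-
dependent gain, refraction shadows, neighboring anatomy (tendons, vessels)
and operator annotations. Passing the synthetic recovery tests therefore
shows the cascade's stages compose correctly and degrade gracefully with
contrast and speckle — not clinical performance. The hard tier
(contrast-to-noise ratio mostly below 1) is deliberately harder than
typical clinical frames, to expose the failure direction of each method.

## Numerical choices and degenerate inputs

* Stretch band collapse (single supported intensity) and constant frames →
  degenerate-image errors.
* FCM non-convergence at `max_iter` (default 300) → flagged, not raised.
* Component-size ties → the earlier component in raster order.
* All randomness (phantom sampling, speckle, FCM init) flows from explicit
  seeds; identical (input, config, seed) reproduce bit-identical masks
  across processes.

## Problem sizes used in the checks

The test suite runs on 256×256 phantoms, 30 frames per tier for the
recovery checks, 1,000 random histograms for the clustering oracle and 100
seeded FCM fits; `scripts/acceptance.py` uses 120 frames (60 easy + 60
hard). These sizes match the scale of the target population while keeping a
full run in well under a minute of compute per suite.

## Known limitations

* The low-side "no denser than d" predicate means large dense dark modes
  (big anechoic cysts) are not themselves low-side clusters; the cascade
  relies on the FCM path for them. The published rule is kept as printed.
* Single-object output: multiple plausible cysts are not reported
  (largest-component rule).
* The acceptance proxy saturates: any centered prediction is accepted, so
  proxy extraction rates are optimistic relative to human judgment.
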