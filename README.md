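# cystseg

Fully automatic segmentation of wrist **ganglion cysts** in B-mode ultrasound
images. Ganglion cysts are benign mucoid masses, commonest at the wrist, that
appear **anechoic-to-hypoechoic** (dark) on ultrasound; small ones are often
faint, and manual delineation is strongly examiner-dependent. `cystseg`
implements a cascade of two unsupervised clustering algorithms that locates
the cyst without any operator input, plus the pixel-count evaluation
protocol and a synthetic phantom generator used to exercise it.

## Method

For a grayscale frame (or rectangular ROI) `P(x, y)` with intensities in
0–255:

1. **Fuzzy stretching.** A trapezoidal membership function
   `μ(G)` (feet at the observed `I_min`, `I_max`; plateau `[I_midL, I_midR]`
   centered on the mean intensity, shoulders one standard deviation wide)
   grades every gray level. With
   `δ = (I_mid + (I_max + I_min)/2)/255` and `α-cut = min(δ + 0.5, 1)`,
   the contiguous band where `μ(G) ≥ α-cut` is linearly expanded onto
   [0, 255]. Pixels darker than an operator threshold in the stretched frame
   form a *dark-noise mask* withheld from the final object.
2. **Density clustering of the histogram** (DBSCAN-style, parameters
   `Pts_min = 3`, `ε = 1`). The 256-bin histogram of the input region is
   split at its mean; with reference density `d = (W·H)/255`, maximal runs of
   consecutive bins that are denser than `d` (bright side) or no denser than
   `d` (dark side) and at least `Pts_min` bins long are *qualified clusters*.
   The count of dark-side qualified clusters is `DBSCAN_ct`; the brightest
   pixel in any qualified cluster is `DBSCAN_pmax`.
3. **Cluster-count rule.** The number of fuzzy C-means clusters is chosen
   adaptively:

       FCM_ct = 0   if DBSCAN_pmax ≤ mean intensity  or  DBSCAN_ct ≥ 4
       FCM_ct = 4   else if DBSCAN_ct = 1
       FCM_ct = 2   otherwise

   `FCM_ct = 0` means the histogram clusters already isolate the dark
   target and FCM is skipped.
4. **Fuzzy C-means quantization** (`m = 2`, 1-D Euclidean distance) of the
   stretched intensities with `c = FCM_ct`, iterating
   `v_i = Σ u_ik^m x_k / Σ u_ik^m` and
   `u_ik = 1 / Σ_j (d_ik/d_jk)^{2/(m−1)}` until the membership matrix is
   stable. Cysts are hypoechoic, so the cluster with the lowest centroid is
   the candidate.
5. **Object formation.** The candidate pixels minus the dark-noise mask are
   labeled into connected components (8-connectivity); the largest component
   above a minimum area is the extracted cyst.

Evaluation uses pixel counts against a binary ground-truth mask:
`accuracy = 100·TP/(TP+FN+FP)` (the Jaccard index ×100),
`recall = 100·TP/(TP+FN)`, `precision = 100·TP/(TP+FP)`, and F1. An
extraction is *accepted* when the predicted object is non-empty and either
IoU ≥ 0.5 or its centroid falls inside the truth — a computational stand-in
for the radiologist's congruence judgment (see `docs/methods.md`).

## Worked example

```sh
$ cystseg simulate --n 2 --difficulty easy --seed 7 --out demo
wrote 2 easy phantom pairs to demo

$ cystseg segment --in demo/phantom_000.png --out demo/mask_000.png \
      --report demo/report.json --seed 1
demo/phantom_000.png: branch=default fcm_ct=2 area=18986px -> demo/mask_000.png

$ cystseg evaluate --pred demo/mask_000.png --truth demo/phantom_000_mask.png
{"tp": 18958, "fp": 28, "fn": 0, "accuracy": 99.85, "recall": 100.0,
 "precision": 99.85, "f1": 99.93, "accepted": true}
```

The segment line says the histogram front-end left more than one dark
cluster (`branch=default`), so FCM ran with `c = 2` and extracted a
18,986-pixel object; the evaluation shows it covers the 18,958-pixel
ground-truth cyst completely (recall 100%) with only 28 false-positive
pixels. The JSON report records every stage (stretch model, cluster counts,
`DBSCAN_pmax`, decision branch, FCM convergence, component statistics), which
together with the seed replays the run exactly.

The three-method comparison protocol is also scriptable:

```sh
$ cystseg benchmark --n 20 --seed 1
dbscan    ext_rate=35.0% accuracy=15.92% recall=16.02% precision=86.81% f1=21.71%
fcm       ext_rate=50.0% accuracy=95.90% recall=99.98% precision=95.91% f1=97.83%
proposed  ext_rate=95.0% accuracy=64.11% recall=67.49% precision=88.42% f1=71.98%
```

Rates are over all frames; metrics are macro-averages over accepted
extractions only, so a method that succeeds only on easy frames (here the
fixed-c FCM baseline, accepted on 50% of frames) can show high means on the
frames it does extract while the adaptive cascade extracts 95% of them.

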