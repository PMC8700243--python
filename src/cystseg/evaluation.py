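"""Pixel-count evaluation metrics and the three-method benchmark protocol.

Ground truth is a binary cyst mask, so only TP/FP/FN pixel counts are
meaningful (the true-negative background dominates any frame and is excluded
by construction).  Metrics, on the percentage scale:

    accuracy  = 100 * TP / (TP + FN + FP)     (the Jaccard index x 100)
    recall    = 100 * TP / (TP + FN)
    precision = 100 * TP / (TP + FP)
    F1        = 2 * precision * recall / (precision + recall)

The study protocol accepts an extraction when a radiologist judges the
located object congruent with the true cyst; this package substitutes a
computational proxy — accepted iff the prediction is non-empty and either
IoU >= ``iou_threshold`` (default 0.5) or the prediction's centroid lies
inside the truth.  This substitution is the largest protocol deviation and
is documented in docs/methods.md.  Mean metrics are macro-averaged over
accepted extractions only; undefined metrics are excluded from means, never
zero-filled.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, stats

__all__ = [
    "EvalCounts",
    "Metrics",
    "count_pixels",
    "compute_metrics",
    "jaccard",
    "extraction_accepted",
    "benchmark",
]

METRIC_NAMES = ("accuracy", "recall", "precision", "f1")


@dataclass(frozen=True)
class EvalCounts:
    tp: int
    fp: int
    fn: int

    @property
    def truth_area(self) -> int:
        return self.tp + self.fn

    @property
    def pred_area(self) -> int:
        return self.tp + self.fp


@dataclass(frozen=True)
class Metrics:
    accuracy: float | None
    recall: float | None
    precision: float | None
    f1: float | None
    undefined: tuple[str, ...] = ()

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "recall": self.recall,
            "precision": self.precision,
            "f1": self.f1,
        }


def _check_shapes(pred: np.ndarray, truth: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    pred = np.asarray(pred, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs truth {truth.shape}")
    return pred, truth


def count_pixels(pred: np.ndarray, truth: np.ndarray) -> EvalCounts:
    """TP/FP/FN pixel counts of a predicted mask against ground truth."""
    pred, truth = _check_shapes(pred, truth)
    tp = int((pred & truth).sum())
    return EvalCounts(tp=tp, fp=int(pred.sum()) - tp, fn=int(truth.sum()) - tp)


def compute_metrics(c: EvalCounts) -> Metrics:
    """Percentage-scale metrics; undefined denominators yield None + flag."""
    undef: list[str] = []
    acc = rec = prec = f1 = None
    if c.tp + c.fn + c.fp > 0:
        acc = 100.0 * c.tp / (c.tp + c.fn + c.fp)
    else:
        undef.append("accuracy")
    if c.tp + c.fn > 0:
        rec = 100.0 * c.tp / (c.tp + c.fn)
    else:
        undef.append("recall")
    if c.tp + c.fp > 0:
        prec = 100.0 * c.tp / (c.tp + c.fp)
    else:
        undef.append("precision")
    if rec is not None and prec is not None:
        f1 = 0.0 if prec + rec == 0 else 2.0 * prec * rec / (prec + rec)
    else:
        undef.append("f1")
    return Metrics(accuracy=acc, recall=rec, precision=prec, f1=f1, undefined=tuple(undef))


def jaccard(pred: np.ndarray, truth: np.ndarray) -> float:
    pred, truth = _check_shapes(pred, truth)
    union = int((pred | truth).sum())
    if union == 0:
        return 1.0  # two empty masks are identical
    return int((pred & truth).sum()) / union


def extraction_accepted(
    pred: np.ndarray, truth: np.ndarray, iou_threshold: float = 0.5
) -> bool:
    """Computational proxy for the radiologist's congruence judgment."""
    pred, truth = _check_shapes(pred, truth)
    if not pred.any():
        return False
    if jaccard(pred, truth) >= iou_threshold:
        return True
    cy, cx = ndimage.center_of_mass(pred)
    r, c = int(round(cy)), int(round(cx))
    r = min(max(r, 0), truth.shape[0] - 1)
    c = min(max(c, 0), truth.shape[1] - 1)
    return bool(truth[r, c])


def _mean_defined(vals: Sequence[float | None]) -> float | None:
    vv = [v for v in vals if v is not None and not np.isnan(v)]
    return float(np.mean(vv)) if vv else None


def _summarize(rows: pd.DataFrame) -> dict:
    out: dict = {"n": int(len(rows))}
    acc_rows = rows[rows["accepted"]]
    out["extractions"] = int(len(acc_rows))
    out["ext_rate_pct"] = 100.0 * out["extractions"] / out["n"] if out["n"] else None
    for name in METRIC_NAMES:
        out[f"mean_{name}_pct"] = _mean_defined(acc_rows[name].tolist())
    out["mean_jaccard"] = (
        float(acc_rows["jaccard"].mean()) if len(acc_rows) else None
    )
    return out


def benchmark(
    pairs: Sequence[tuple[np.ndarray, np.ndarray]],
    methods: Sequence[str] | Mapping[str, Callable[[np.ndarray], np.ndarray]] = (
        "dbscan",
        "fcm",
        "proposed",
    ),
    config=None,
    iou_threshold: float = 0.5,
    size_split: bool = True,
) -> tuple[pd.DataFrame, dict]:
    """Run segmentation methods over (image, truth) pairs and tabulate.

    *methods* may be method names dispatched to the pipeline, or a mapping
    name -> callable(image) -> mask (used e.g. to evaluate planted
    predictions).  Returns a per-image/per-method DataFrame and a summary
    dict with overall and (optionally) median-truth-area large/small group
    statistics, plus a paired Wilcoxon signed-rank p-value on per-image
    accuracy for proposed vs FCM when both are present (an artifact choice;
    the study names no test).
    """
    if len(pairs) < 2:
        raise ValueError("benchmark needs at least 2 images")
    if not isinstance(methods, Mapping):
        from .pipeline import segment  # deferred: avoid import cycle

        def _runner(name: str) -> Callable[[np.ndarray], np.ndarray]:
            return lambda im: segment(im, config=config, method=name)[0]

        methods = {name: _runner(name) for name in methods}

    truth_areas = [int(np.asarray(t, bool).sum()) for _, t in pairs]
    median_area = float(np.median(truth_areas))

    rows = []
    for i, (img, truth) in enumerate(pairs):
        group = "large" if truth_areas[i] > median_area else "small"
        for name, fn in methods.items():
            pred = np.asarray(fn(img), dtype=bool)
            cts = count_pixels(pred, truth)
            met = compute_metrics(cts)
            rows.append(
                {
                    "image": i,
                    "method": name,
                    "group": group,
                    "truth_area": truth_areas[i],
                    "pred_area": cts.pred_area,
                    "tp": cts.tp,
                    "fp": cts.fp,
                    "fn": cts.fn,
                    "jaccard": jaccard(pred, truth),
                    "accepted": extraction_accepted(pred, truth, iou_threshold),
                    **{k: (np.nan if v is None else v) for k, v in met.as_dict().items()},
                }
            )
    df = pd.DataFrame(rows)

    summary: dict = {"median_truth_area": median_area, "methods": {}}
    for name in methods:
        sub = df[df["method"] == name]
        entry = _summarize(sub)
        if size_split:
            entry["by_group"] = {
                g: _summarize(sub[sub["group"] == g]) for g in ("large", "small")
            }
        summary["methods"][name] = entry

    if {"fcm", "proposed"} <= set(methods):
        both = df.pivot_table(
            index="image", columns="method", values="accuracy", aggfunc="first"
        )
        acc_mask = (
            df.pivot_table(index="image", columns="method", values="accepted", aggfunc="first")
            .astype(bool)
        )
        joint = both[acc_mask["fcm"] & acc_mask["proposed"]][["fcm", "proposed"]].dropna()
        p = None
        if len(joint) >= 5 and not np.allclose(joint["fcm"], joint["proposed"]):
            p = float(stats.wilcoxon(joint["proposed"], joint["fcm"]).pvalue)
        summary["wilcoxon_accuracy_proposed_vs_fcm_p"] = p
        summary["jointly_accepted"] = int(len(joint))
    return df, summary
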