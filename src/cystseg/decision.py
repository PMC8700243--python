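"""Rule converting the histogram-clustering outcome into the FCM cluster count.

The cascade chooses between a clustering-only path and an FCM back-end:

    if   dbscan_pmax <= mean_intensity  or  dbscan_ct >= 4:   fcm_ct = 0
    elif dbscan_ct == 1:                                      fcm_ct = 4
    else:                                                     fcm_ct = 2

``fcm_ct = 0`` means FCM is skipped: either the brightest qualified-cluster
pixel is no brighter than the regional mean (the dark target is already well
separated), or the front-end found 4+ clusters and is considered to have
effective low-intensity clusters on its own.  A single front-end cluster
means the histogram is unimodal and FCM needs a fine split (c = 4); anything
else gets the minimal split (c = 2).

Edge cases outside the published rule: when no qualified cluster exists, or
qualified clusters cover only empty bins so ``dbscan_pmax`` is undefined, the
pmax guard cannot fire and the rule falls through as if it were false.
"""

from __future__ import annotations

from dataclasses import dataclass

from .histogram import DbscanResult

__all__ = ["Decision", "decide"]


@dataclass(frozen=True)
class Decision:
    fcm_ct: int  # 0 | 2 | 4
    rationale: str  # which branch fired


def decide(
    result: DbscanResult,
    mean_intensity: float | None = None,
    count_side: str = "both",
) -> Decision:
    """Apply the cluster-count rule to a front-end result.

    ``count_side`` selects which side's qualified clusters enter the count
    ("both" is the default reading; "low" restricts to low-intensity
    clusters).  Pure function of its inputs.
    """
    if count_side == "both":
        ct = result.dbscan_ct
    elif count_side == "low":
        ct = result.low_ct
    elif count_side == "high":
        ct = result.high_ct
    else:
        raise ValueError(f"count_side must be both|low|high, got {count_side!r}")
    mean = result.mean_intensity if mean_intensity is None else mean_intensity
    pmax = result.dbscan_pmax

    if pmax is not None and pmax <= mean:
        return Decision(fcm_ct=0, rationale="pmax-below-mean")
    if ct >= 4:
        return Decision(fcm_ct=0, rationale="ct-ge-4")
    if ct == 1:
        return Decision(fcm_ct=4, rationale="ct-eq-1")
    if ct == 0 and pmax is None:
        return Decision(fcm_ct=2, rationale="default-no-clusters")
    return Decision(fcm_ct=2, rationale="default")
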