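"""Independent brute-force oracles used only by the tests.

Deliberately written as explicit per-bin / per-pixel scans, sharing no code
with the package implementation.
"""

from __future__ import annotations


def scan_histogram_clusters(
    counts,
    mean: float,
    density: float,
    pts_min: int = 3,
    eps: int = 1,
    low_side_high_density: bool = False,
):
    """Linear state-machine scan of the 256-bin histogram.

    Returns (qualified, removed, pmax) where qualified is a list of
    (side, tuple_of_bins) and removed a sorted list of disqualified bins.
    """
    qualified = []
    removed = []

    def predicate(k: int, side: str) -> bool:
        if side == "high":
            return counts[k] > density
        if low_side_high_density:
            return counts[k] > density
        return counts[k] <= density

    for side in ("low", "high"):
        current: list[int] = []
        for k in range(256):
            on_side = (k <= mean) if side == "low" else (k > mean)
            if on_side and predicate(k, side):
                if current and k - current[-1] > eps:
                    if len(current) >= pts_min:
                        qualified.append((side, tuple(current)))
                    else:
                        removed.extend(current)
                    current = []
                current.append(k)
        if current:
            if len(current) >= pts_min:
                qualified.append((side, tuple(current)))
            else:
                removed.extend(current)

    pmax = None
    for _, run in qualified:
        for k in run:
            if counts[k] > 0 and (pmax is None or k > pmax):
                pmax = k
    return qualified, sorted(removed), pmax


def eq3_rule(ct: int, pmax, mean: float) -> int:
    """The published cluster-count rule, restated independently."""
    if (pmax is not None and pmax <= mean) or ct >= 4:
        return 0
    if ct == 1:
        return 4
    return 2


def pixel_confusion(pred, truth):
    """Per-pixel exhaustive TP/FP/FN tally."""
    tp = fp = fn = 0
    for i in range(pred.shape[0]):
        for j in range(pred.shape[1]):
            p, t = bool(pred[i, j]), bool(truth[i, j])
            tp += p and t
            fp += p and not t
            fn += t and not p
    return tp, fp, fn
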