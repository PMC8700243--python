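"""Density-based clustering (DBSCAN-style) over the 256-bin intensity histogram.

The front-end of the cascade does not cluster pixels in the 2-D plane; it
clusters *intensity bins*.  The histogram of the (stretched) region is split
at its mean intensity.  With reference density ``d = (W*H)/255`` (pixels per
bin if the histogram were flat):

* on the HIGH-intensity side, maximal runs of bins with frequency > d are
  cluster candidates;
* on the LOW-intensity side, maximal runs of bins with frequency <= d are
  cluster candidates (the published rule; ``low_side_high_density=True``
  switches to the symmetric > d predicate);

where bins k, k' belong to the same run iff ``|k - k'| <= eps``.  Candidates
with at least ``pts_min`` member bins qualify and increment the cluster count
``dbscan_ct``; the pixels of disqualified candidates are marked removed as
probable noise.  ``dbscan_pmax`` is the maximum intensity attained by any
pixel belonging to a qualified cluster (``None`` when qualified clusters
cover only empty bins).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .image_io import Roi

__all__ = [
    "IntensityHistogram",
    "HistogramCluster",
    "DbscanResult",
    "build_histogram",
    "cluster_histogram",
    "pixels_of_clusters",
]

N_BINS = 256


@dataclass(frozen=True)
class IntensityHistogram:
    counts: np.ndarray  # (256,) pixel counts per intensity
    mean_intensity: float
    density: float  # (W*H)/255, pixels per bin

    @property
    def n_pixels(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class HistogramCluster:
    """A qualified run of intensity bins on one side of the mean."""

    intensities: tuple[int, ...]
    side: str  # "low" | "high"
    member_count: int
    pixel_count: int
    pmax: int | None  # max intensity with at least one pixel, None if empty


@dataclass(frozen=True)
class DbscanResult:
    clusters: tuple[HistogramCluster, ...]
    dbscan_ct: int
    low_ct: int
    high_ct: int
    dbscan_pmax: int | None
    removed_intensities: tuple[int, ...]
    mean_intensity: float

    def qualified_bins(self, side: str = "both") -> np.ndarray:
        """Boolean (256,) lookup of bins in qualified clusters of *side*."""
        lut = np.zeros(N_BINS, dtype=bool)
        for cl in self.clusters:
            if side == "both" or cl.side == side:
                lut[list(cl.intensities)] = True
        return lut


def build_histogram(img: np.ndarray, roi: Roi | None = None) -> IntensityHistogram:
    """Histogram of the region: per-bin counts, pixel mean, reference density."""
    img = np.asarray(img)
    if roi is not None:
        img = roi.crop(img)
    if img.size == 0:
        raise ValueError("empty region")
    counts = np.bincount(img.ravel(), minlength=N_BINS).astype(np.int64)
    k = np.arange(N_BINS)
    n = counts.sum()
    mean = float((k * counts).sum() / n)
    density = float(img.shape[0] * img.shape[1]) / 255.0
    return IntensityHistogram(counts=counts, mean_intensity=mean, density=density)


def _runs(bins: np.ndarray, eps: int) -> list[np.ndarray]:
    """Split sorted bin indices into maximal chains with gaps <= eps."""
    if bins.size == 0:
        return []
    cuts = np.where(np.diff(bins) > eps)[0] + 1
    return np.split(bins, cuts)


def cluster_histogram(
    hist: IntensityHistogram,
    pts_min: int = 3,
    eps: int = 1,
    low_side_high_density: bool = False,
) -> DbscanResult:
    """Run the histogram-domain density clustering.

    Returns qualified clusters, the combined cluster count, per-side counts,
    the maximum intensity over qualified-cluster pixels, and the bins whose
    pixels were removed as disqualified-candidate noise.
    """
    counts = hist.counts
    d = hist.density
    mean = hist.mean_intensity
    k = np.arange(N_BINS)
    low_side = k <= mean
    high_pred = counts > d
    low_pred = high_pred if low_side_high_density else (counts <= d)

    clusters: list[HistogramCluster] = []
    removed: list[int] = []
    side_ct = {"low": 0, "high": 0}
    for side, cand in (
        ("low", k[low_side & low_pred]),
        ("high", k[~low_side & high_pred]),
    ):
        for run in _runs(cand, eps):
            if run.size >= pts_min:
                present = run[counts[run] > 0]
                clusters.append(
                    HistogramCluster(
                        intensities=tuple(int(b) for b in run),
                        side=side,
                        member_count=int(run.size),
                        pixel_count=int(counts[run].sum()),
                        pmax=int(present.max()) if present.size else None,
                    )
                )
                side_ct[side] += 1
            else:
                removed.extend(int(b) for b in run)

    pmaxes = [c.pmax for c in clusters if c.pmax is not None]
    return DbscanResult(
        clusters=tuple(clusters),
        dbscan_ct=len(clusters),
        low_ct=side_ct["low"],
        high_ct=side_ct["high"],
        dbscan_pmax=max(pmaxes) if pmaxes else None,
        removed_intensities=tuple(removed),
        mean_intensity=mean,
    )


def pixels_of_clusters(
    img: np.ndarray, result: DbscanResult, side: str = "both"
) -> np.ndarray:
    """Boolean mask of pixels whose intensity lies in a qualified cluster."""
    if side not in ("low", "high", "both"):
        raise ValueError(f"side must be low|high|both, got {side!r}")
    lut = result.qualified_bins(side)
    return lut[np.asarray(img)]
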