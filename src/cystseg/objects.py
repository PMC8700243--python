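"""Final object formation: candidate selection, noise removal, labeling.

Ganglion cysts are anechoic-to-hypoechoic, so the candidate pixels are those
of the DARKEST cluster: on the FCM path the cluster(s) with the lowest
centroid intensity (centroids are sorted ascending by the fitter, so these
are the lowest label indices); on the clustering-only path the pixels of the
low-intensity-side qualified histogram clusters.  The dark-noise mask from
fuzzy stretching is then subtracted, and the surviving pixels are partitioned
into connected components; components below a minimum area are dropped and
the largest remaining one is the extracted object.  An empty result is a
failed extraction, not an error.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy import ndimage
from skimage import measure

from .fcm import FcmState
from .histogram import DbscanResult, pixels_of_clusters

__all__ = [
    "Component",
    "ComponentSet",
    "CandidateResult",
    "select_candidate_pixels",
    "apply_noise_mask",
    "label_and_extract",
]

_CONN = {4: 1, 8: 2}  # connectivity -> skimage neighborhood order


@dataclass(frozen=True)
class Component:
    label: int
    area: int
    bbox: tuple[int, int, int, int]  # (min_row, min_col, max_row, max_col)
    centroid: tuple[float, float]  # (row, col)


@dataclass(frozen=True)
class ComponentSet:
    components: tuple[Component, ...]
    connectivity: int


class CandidateResult(NamedTuple):
    mask: np.ndarray
    warning: bool  # True when no candidate pixel exists


def select_candidate_pixels(
    labelmap: np.ndarray | None,
    source: FcmState | DbscanResult,
    path: str = "fcm",
    img: np.ndarray | None = None,
    n_darkest: int = 1,
) -> CandidateResult:
    """Pick the hypoechoic candidate pixels for object formation.

    ``path="fcm"``: pixels whose label is among the *n_darkest* lowest-centroid
    clusters of *labelmap* (requires an :class:`FcmState` source).
    ``path="dbscan"``: pixels of low-side qualified histogram clusters of
    *img* (requires a :class:`DbscanResult` source).
    """
    if path == "fcm":
        if labelmap is None or not isinstance(source, FcmState):
            raise ValueError("fcm path needs a labelmap and an FcmState")
        mask = np.asarray(labelmap) < n_darkest
    elif path == "dbscan":
        if img is None or not isinstance(source, DbscanResult):
            raise ValueError("dbscan path needs the image and a DbscanResult")
        mask = pixels_of_clusters(img, source, side="low")
    else:
        raise ValueError(f"path must be fcm|dbscan, got {path!r}")
    return CandidateResult(mask=mask, warning=not bool(mask.any()))


def apply_noise_mask(candidate: np.ndarray, noise: np.ndarray) -> np.ndarray:
    """Set difference candidate \\ noise; shapes must match."""
    candidate = np.asarray(candidate, dtype=bool)
    noise = np.asarray(noise, dtype=bool)
    if candidate.shape != noise.shape:
        raise ValueError(
            f"shape mismatch: candidate {candidate.shape} vs noise {noise.shape}"
        )
    return candidate & ~noise


def label_and_extract(
    mask: np.ndarray,
    connectivity: int = 8,
    min_area: int = 0,
    fill_holes: bool = False,
) -> tuple[np.ndarray, ComponentSet]:
    """Connected-component labeling and largest-object extraction.

    Components with area < *min_area* are dropped; the largest survivor (ties
    broken toward the smaller label, i.e. the earlier component in raster
    order) is returned as the final mask, empty if nothing survives.
    """
    if connectivity not in _CONN:
        raise ValueError("connectivity must be 4 or 8")
    mask = np.asarray(mask, dtype=bool)
    lab = measure.label(mask, connectivity=_CONN[connectivity])
    comps = [
        Component(
            label=int(p.label),
            area=int(p.area),
            bbox=tuple(int(b) for b in p.bbox),
            centroid=tuple(float(c) for c in p.centroid),
        )
        for p in measure.regionprops(lab)
        if p.area >= min_area
    ]
    cset = ComponentSet(components=tuple(comps), connectivity=connectivity)
    if not comps:
        return np.zeros_like(mask), cset
    best = max(comps, key=lambda c: (c.area, -c.label))
    final = lab == best.label
    if fill_holes:
        final = ndimage.binary_fill_holes(final)
    return final, cset
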