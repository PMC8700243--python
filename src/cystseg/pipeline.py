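"""End-to-end segmentation cascade and its run report.

Flow (method "proposed"): fuzzy stretching -> dark-noise mask -> 256-bin
histogram -> density clustering of the histogram -> cluster-count decision ->
either the clustering-only low-side pixel mask (fcm_ct = 0) or FCM
quantization with c = fcm_ct followed by darkest-cluster selection -> noise
subtraction -> connected-component labeling, keeping the largest component
above the minimum area.

Two standalone baselines implement the comparison protocol: "dbscan" always
takes the clustering-only path, "fcm" always quantizes with a fixed cluster
count (default 4).  Both share the stretching, noise and labeling stages so
the comparison isolates the clustering front-end.

Every stage's parameters and outcomes are recorded in a :class:`RunReport`;
together with the seed they replay the run deterministically.
"""

from __future__ import annotations

import logging
import time
from dataclasses import asdict, dataclass, field, fields

import numpy as np

from . import fcm as _fcm
from .decision import Decision, decide
from .errors import DegenerateImageError
from .histogram import build_histogram, cluster_histogram
from .image_io import Roi
from .objects import apply_noise_mask, label_and_extract, select_candidate_pixels
from .stretch import dark_noise_mask, fit_stretch_model, stretch

__all__ = ["PipelineConfig", "RunReport", "segment", "METHODS"]

log = logging.getLogger("cystseg")

METHODS = ("dbscan", "fcm", "proposed")


@dataclass(frozen=True)
class PipelineConfig:
    """Every tunable of the cascade; defaults follow the published setup."""

    # fuzzy stretching
    shoulder_scale: float = 1.0
    dark_threshold: int = 0  # stretched-intensity units; 0 = band lower edge
    # histogram density clustering
    pts_min: int = 3
    eps: int = 1
    low_side_high_density: bool = False
    # Which side's qualified clusters feed the cluster-count rule.  "low" is
    # the default: the front-end counts "candidates of the ganglion cyst",
    # i.e. dark clusters; counting both sides would make ct = 1 (the
    # unimodal-histogram branch that triggers c = 4) unreachable on smooth
    # frames, since the low-intensity tail always contributes a run of its
    # own next to the background mode.
    count_side: str = "low"
    # FCM back-end
    fuzzifier: float = 2.0
    fcm_tol: float = 1e-5
    fcm_max_iter: int = 300
    seed: int = 0
    # c of the FCM-only baseline: the classic object/background split.  A
    # fixed coarse c makes the baseline segment a wider dark area than the
    # adaptive cascade, the behaviour the comparison protocol probes.
    standalone_fcm_c: int = 2
    # object formation
    connectivity: int = 8
    min_area_frac: float = 0.0005  # of the region area
    fill_holes: bool = False
    n_darkest: int = 1

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_mapping(cls, mapping: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**mapping)


@dataclass
class RunReport:
    """Per-run record sufficient to replay the run given the seed."""

    method: str
    input_path: str | None
    roi: tuple[int, int, int, int] | None
    config: dict
    stretch_model: dict
    noise_pixels: int
    mean_intensity: float
    density: float
    dbscan_ct: int | None = None
    dbscan_low_ct: int | None = None
    dbscan_high_ct: int | None = None
    dbscan_pmax: int | None = None
    removed_bins: int | None = None
    decision_branch: str | None = None
    fcm_ct: int | None = None
    c_effective: int | None = None
    fcm_iterations: int | None = None
    fcm_converged: bool | None = None
    fcm_centroids: list[float] | None = None
    candidate_pixels: int = 0
    n_components: int = 0
    final_area: int = 0
    final_bbox: tuple[int, int, int, int] | None = None
    final_centroid: tuple[float, float] | None = None
    extraction_failed: bool = True
    wall_time_s: float = 0.0

    def to_dict(self) -> dict:
        return asdict(self)


def segment(
    img: np.ndarray,
    config: PipelineConfig | None = None,
    roi: Roi | None = None,
    method: str = "proposed",
    input_path: str | None = None,
) -> tuple[np.ndarray, RunReport]:
    """Segment one frame; returns the final cyst mask and the run report."""
    if method not in METHODS:
        raise ValueError(f"method must be one of {METHODS}, got {method!r}")
    cfg = config or PipelineConfig()
    t0 = time.perf_counter()

    img = np.asarray(img)
    if roi is not None:
        img = roi.crop(img)

    model = fit_stretch_model(img, shoulder_scale=cfg.shoulder_scale)
    stretched = stretch(img, model)
    noise = dark_noise_mask(stretched, cfg.dark_threshold)

    # Histogram analysis runs on the input region, not the stretched frame:
    # integer stretching with gain > 1 leaves periodic empty bins (a comb),
    # which breaks run detection at radius eps.  Stretching feeds only the
    # FCM back-end and the dark-noise mask.
    hist = build_histogram(img)
    report = RunReport(
        method=method,
        input_path=input_path,
        roi=(roi.x0, roi.y0, roi.w, roi.h) if roi else None,
        config=cfg.to_dict(),
        stretch_model=model.to_dict(),
        noise_pixels=int(noise.sum()),
        mean_intensity=hist.mean_intensity,
        density=hist.density,
    )

    dbres = cluster_histogram(
        hist,
        pts_min=cfg.pts_min,
        eps=cfg.eps,
        low_side_high_density=cfg.low_side_high_density,
    )
    report.dbscan_ct = dbres.dbscan_ct
    report.dbscan_low_ct = dbres.low_ct
    report.dbscan_high_ct = dbres.high_ct
    report.dbscan_pmax = dbres.dbscan_pmax
    report.removed_bins = len(dbres.removed_intensities)

    if method == "proposed":
        dec = decide(dbres, hist.mean_intensity, count_side=cfg.count_side)
    elif method == "fcm":
        dec = Decision(fcm_ct=cfg.standalone_fcm_c, rationale="standalone-fcm")
    else:  # dbscan-only baseline
        dec = Decision(fcm_ct=0, rationale="standalone-dbscan")
    report.decision_branch = dec.rationale
    report.fcm_ct = dec.fcm_ct

    if dec.fcm_ct == 0:
        candidate = select_candidate_pixels(None, dbres, path="dbscan", img=img)
    else:
        n_unique = int(np.count_nonzero(np.bincount(stretched.ravel(), minlength=256)))
        c_eff = min(dec.fcm_ct, n_unique)
        report.c_effective = c_eff
        fcm_cfg = _fcm.FcmConfig(
            c=c_eff,
            m=cfg.fuzzifier,
            tol=cfg.fcm_tol,
            max_iter=cfg.fcm_max_iter,
            seed=cfg.seed,
        )
        state, labelmap = _fcm.fcm_fit_image(stretched, fcm_cfg)
        report.fcm_iterations = state.iterations
        report.fcm_converged = state.converged
        report.fcm_centroids = [float(v) for v in state.centroids]
        candidate = select_candidate_pixels(
            labelmap, state, path="fcm", n_darkest=cfg.n_darkest
        )
    if candidate.warning:
        log.warning("no candidate pixels (%s path)", dec.rationale)
    report.candidate_pixels = int(candidate.mask.sum())

    cleaned = apply_noise_mask(candidate.mask, noise)
    min_area = int(round(cfg.min_area_frac * img.size))
    final, comps = label_and_extract(
        cleaned,
        connectivity=cfg.connectivity,
        min_area=min_area,
        fill_holes=cfg.fill_holes,
    )
    report.n_components = len(comps.components)
    report.final_area = int(final.sum())
    report.extraction_failed = report.final_area == 0
    if not report.extraction_failed:
        best = max(comps.components, key=lambda c: (c.area, -c.label))
        report.final_bbox = best.bbox
        report.final_centroid = best.centroid
    report.wall_time_s = time.perf_counter() - t0
    log.info(
        "%s: dbscan_ct=%s pmax=%s branch=%s fcm_ct=%s area=%d",
        method,
        report.dbscan_ct,
        report.dbscan_pmax,
        report.decision_branch,
        report.fcm_ct,
        report.final_area,
    )
    return final, report
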