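"""Synthetic B-mode ultrasound phantoms with a hypoechoic cyst.

The study's clinical images are private, so the pipeline is exercised on
first-order phantoms: an echogenic speckled background containing one dark
oval-to-lobulated cyst.  The appearance model is

    image = clip_0..255( round( base * noise ) )

where ``base`` interpolates ``background_level -> cyst_level`` across the
(optionally Gaussian-blurred) cyst boundary, and ``noise`` is unit-mean
multiplicative gamma speckle with dispersion ``speckle_scale`` (standard
first-order surrogate for fully developed B-mode speckle; no wave
propagation is simulated).  The ground-truth mask is the cyst support
*before* blur, so truth geometry is decoupled from noise and blur.

Difficulty tiers mirror the study population: cyst areas span 220-31,514
pixels with median 4,647; "easy" phantoms are large, high-contrast and
low-speckle, "hard" ones small, low-contrast (hypoechoic rather than
anechoic) and heavily speckled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = ["Ellipse", "PhantomSpec", "generate_phantom", "generate_suite"]

# Study-population size anchors (ground-truth pixel counts).
AREA_MIN, AREA_MEDIAN, AREA_MAX = 220, 4647, 31514

DIFFICULTY_RANGES = {
    #            area            contrast    speckle       border sigma
    "easy": ((5000.0, 28000.0), (60.0, 110.0), (0.05, 0.20), (0.0, 1.5)),
    "medium": ((1000.0, 10000.0), (30.0, 60.0), (0.20, 0.30), (0.5, 2.0)),
    "hard": ((220.0, 4647.0), (15.0, 30.0), (0.30, 0.50), (1.0, 2.5)),
}


@dataclass(frozen=True)
class Ellipse:
    cy: float
    cx: float
    a: float  # semi-axis along the (rotated) x direction, pixels
    b: float  # semi-axis along the (rotated) y direction, pixels
    theta: float = 0.0  # rotation, radians


@dataclass(frozen=True)
class PhantomSpec:
    width: int = 256
    height: int = 256
    background_level: float = 150.0
    cyst_level: float = 80.0
    ellipses: tuple[Ellipse, ...] = (Ellipse(128.0, 128.0, 40.0, 28.0),)
    border_sigma: float = 1.0
    speckle_scale: float = 0.1
    seed: int = 0


def _ellipse_mask(shape: tuple[int, int], e: Ellipse) -> np.ndarray:
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    dy = yy - e.cy
    dx = xx - e.cx
    u = dx * math.cos(e.theta) + dy * math.sin(e.theta)
    v = -dx * math.sin(e.theta) + dy * math.cos(e.theta)
    return (u / e.a) ** 2 + (v / e.b) ** 2 <= 1.0


def generate_phantom(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """Render one (image, truth mask) pair, deterministic per spec.seed."""
    if spec.cyst_level >= spec.background_level:
        raise ValueError("cyst_level must be below background_level (hypoechoic)")
    if spec.width < 1 or spec.height < 1 or not spec.ellipses:
        raise ValueError("invalid phantom geometry")
    if any(e.a <= 0 or e.b <= 0 for e in spec.ellipses):
        raise ValueError("ellipse semi-axes must be positive")
    shape = (spec.height, spec.width)
    mask = np.zeros(shape, dtype=bool)
    for e in spec.ellipses:
        mask |= _ellipse_mask(shape, e)
    if not mask.any():
        raise ValueError("cyst support is empty")
    if mask[0, :].any() or mask[-1, :].any() or mask[:, 0].any() or mask[:, -1].any():
        raise ValueError("cyst must lie fully inside the frame")

    profile = mask.astype(np.float64)
    if spec.border_sigma > 0:
        profile = gaussian_filter(profile, spec.border_sigma)
    base = spec.background_level + (spec.cyst_level - spec.background_level) * profile

    if spec.speckle_scale > 0:
        rng = np.random.default_rng(spec.seed)
        k = 1.0 / spec.speckle_scale**2  # unit mean, variance = scale^2
        noise = rng.gamma(k, 1.0 / k, size=shape)
        base = base * noise
    img = np.rint(np.clip(base, 0.0, 255.0)).astype(np.uint8)
    return img, mask


def _sample_spec(
    rng: np.random.Generator, difficulty: str, size: int = 256
) -> tuple[PhantomSpec, float]:
    area_r, contrast_r, speckle_r, sigma_r = DIFFICULTY_RANGES[difficulty]
    area = rng.uniform(*area_r)
    contrast = rng.uniform(*contrast_r)
    speckle = rng.uniform(*speckle_r)
    sigma = rng.uniform(*sigma_r)
    bg = rng.uniform(120.0, 180.0)
    cyst = max(bg - contrast, 5.0)

    aspect = rng.uniform(0.55, 1.0)
    lobulated = rng.random() < 0.3
    main_area = area * (0.8 if lobulated else 1.0)
    a = math.sqrt(main_area / (math.pi * aspect))
    a = min(a, size / 2.0 - 6.0)
    b = max(main_area / (math.pi * a), 2.0)
    theta = rng.uniform(0.0, math.pi)
    r_max = max(a, b)
    margin = r_max + 4.0
    cy = rng.uniform(margin, size - margin)
    cx = rng.uniform(margin, size - margin)
    ellipses = [Ellipse(cy, cx, a, b, theta)]
    if lobulated:
        for _ in range(rng.integers(1, 3)):
            frac = rng.uniform(0.35, 0.55)
            ang = rng.uniform(0.0, 2.0 * math.pi)
            off = 0.7 * min(a, b)
            lcy = float(np.clip(cy + off * math.sin(ang), frac * r_max + 3, size - frac * r_max - 3))
            lcx = float(np.clip(cx + off * math.cos(ang), frac * r_max + 3, size - frac * r_max - 3))
            ellipses.append(
                Ellipse(lcy, lcx, frac * a, frac * b, rng.uniform(0.0, math.pi))
            )
    spec = PhantomSpec(
        width=size,
        height=size,
        background_level=bg,
        cyst_level=cyst,
        ellipses=tuple(ellipses),
        border_sigma=sigma,
        speckle_scale=speckle,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    return spec, area


def generate_suite(
    n: int, difficulty: str = "medium", seed: int = 0, size: int = 256
) -> list[tuple[np.ndarray, np.ndarray, PhantomSpec]]:
    """Generate *n* seeded (image, mask, spec) triples of one difficulty tier."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if difficulty not in DIFFICULTY_RANGES:
        raise ValueError(f"difficulty must be one of {sorted(DIFFICULTY_RANGES)}")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        spec, target_area = _sample_spec(rng, difficulty, size=size)
        spec = _calibrate_area(spec, target_area)
        img, mask = generate_phantom(spec)
        out.append((img, mask, spec))
    return out


def _calibrate_area(spec: PhantomSpec, target: float) -> PhantomSpec:
    """Rescale the ellipse union once so the truth area matches its target.

    Lobulated shapes are ellipse unions whose area differs from the sampled
    target; a single sqrt-scale correction brings it within a few percent.
    Skipped when scaling would push the cyst against the frame border.
    """
    shape = (spec.height, spec.width)
    mask = np.zeros(shape, dtype=bool)
    for e in spec.ellipses:
        mask |= _ellipse_mask(shape, e)
    actual = int(mask.sum())
    if actual == 0:
        return spec
    scale = math.sqrt(target / actual)
    scaled = tuple(replace(e, a=e.a * scale, b=e.b * scale) for e in spec.ellipses)
    for e in scaled:
        r = max(e.a, e.b)
        if not (r + 2 <= e.cy <= spec.height - r - 2 and r + 2 <= e.cx <= spec.width - r - 2):
            return spec  # keep the uncalibrated geometry rather than clip it
    return replace(spec, ellipses=scaled)
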