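"""Fuzzy contrast stretching with a trapezoidal membership function.

Ultrasound frames of cystic lesions are often low-contrast with an irregular
intensity distribution, so a crisp min-max stretch driven by a fixed threshold
is unreliable.  Fuzzy stretching instead grades every intensity ``G`` by a
trapezoidal membership

    mu(G) = 0                                   G <= I_min or G >= I_max
            (G - I_min) / (I_midL - I_min)      I_min < G < I_midL
            1                                   I_midL <= G <= I_midR
            (I_max - G) / (I_max - I_midR)      I_midR < G < I_max

and expands the contiguous intensity band whose membership reaches the
alpha-cut

    delta     = (I_mid + (I_max + I_min)/2) / 255
    alpha_cut = min(delta + 0.5, 1)

linearly onto [0, 255]; intensities below the band clamp to 0 and above it to
255.  The trapezoid center/shoulders are not prescribed by the method itself;
this implementation centers the plateau on the mean intensity ``I_mid`` with
shoulders one (scaled) standard deviation away, which keeps the plateau on
the dominant echo level and widens it with intensity spread.

After stretching, very dark pixels (below an operator threshold) may be
flagged as noise and withheld from final object formation; by default the
threshold equals the stretched band's lower edge, i.e. 0, so no pixel is
flagged until the operator raises it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateImageError

__all__ = [
    "StretchModel",
    "compute_alpha_cut",
    "fit_stretch_model",
    "membership",
    "stretch",
    "dark_noise_mask",
]


@dataclass(frozen=True)
class StretchModel:
    """Fitted trapezoid parameters and the alpha-supported intensity band."""

    i_min: int
    i_max: int
    i_mid: float
    i_mid_l: float
    i_mid_r: float
    delta: float
    alpha_cut: float
    band_lo: float
    band_hi: float

    def to_dict(self) -> dict:
        return {
            "i_min": self.i_min,
            "i_max": self.i_max,
            "i_mid": self.i_mid,
            "i_mid_l": self.i_mid_l,
            "i_mid_r": self.i_mid_r,
            "delta": self.delta,
            "alpha_cut": self.alpha_cut,
            "band_lo": self.band_lo,
            "band_hi": self.band_hi,
        }


def compute_alpha_cut(i_mid: float, i_min: float, i_max: float) -> tuple[float, float]:
    """Return ``(delta, alpha_cut)`` for the given center and intensity range.

    ``delta = (I_mid + (I_max + I_min)/2) / 255`` and the alpha-cut is the
    fuzzy minimum ``min(delta + 0.5, 1)``.
    """
    delta = (i_mid + (i_max + i_min) / 2.0) / 255.0
    return delta, min(delta + 0.5, 1.0)


def fit_stretch_model(img: np.ndarray, shoulder_scale: float = 1.0) -> StretchModel:
    """Fit the trapezoid to *img*.

    The plateau is ``[I_mid - s, I_mid + s]`` with ``I_mid`` the mean
    intensity and ``s = shoulder_scale * std``, clipped so that
    ``I_min < I_midL <= I_midR < I_max``.  Raises
    :class:`DegenerateImageError` on constant images.
    """
    img = np.asarray(img)
    if img.size == 0:
        raise DegenerateImageError("empty image")
    i_min = int(img.min())
    i_max = int(img.max())
    if i_min == i_max:
        raise DegenerateImageError(
            f"constant image (intensity {i_min}): stretching undefined"
        )
    i_mid = float(img.mean())
    s = float(img.std()) * float(shoulder_scale)
    mid_l = float(np.clip(i_mid - s, i_min + 1, i_max - 1))
    mid_r = float(np.clip(i_mid + s, mid_l, i_max - 1))
    delta, alpha = compute_alpha_cut(i_mid, i_min, i_max)
    # Band where membership >= alpha: solve both ramps for equality.
    band_lo = i_min + alpha * (mid_l - i_min)
    band_hi = i_max - alpha * (i_max - mid_r)
    return StretchModel(
        i_min=i_min,
        i_max=i_max,
        i_mid=i_mid,
        i_mid_l=mid_l,
        i_mid_r=mid_r,
        delta=delta,
        alpha_cut=alpha,
        band_lo=band_lo,
        band_hi=band_hi,
    )


def membership(G, model: StretchModel):
    """Trapezoidal membership degree of intensity *G* (scalar or array)."""
    G = np.asarray(G, dtype=np.float64)
    out = np.zeros_like(G)
    lo, hi = float(model.i_min), float(model.i_max)
    ml, mr = model.i_mid_l, model.i_mid_r
    left = (G > lo) & (G < ml)
    out[left] = (G[left] - lo) / (ml - lo)
    plateau = (G >= ml) & (G <= mr)
    out[plateau] = 1.0
    right = (G > mr) & (G < hi)
    out[right] = (hi - G[right]) / (hi - mr)
    return out if out.ndim else float(out)


def stretch(img: np.ndarray, model: StretchModel) -> np.ndarray:
    """Linearly expand the alpha-supported band onto [0, 255].

    Monotone non-decreasing in input intensity; pixels below the band map to
    0 and above it to 255.
    """
    lo, hi = model.band_lo, model.band_hi
    if hi - lo <= 1e-9:
        raise DegenerateImageError(
            "alpha-supported band collapsed to a single intensity"
        )
    out = (np.asarray(img, dtype=np.float64) - lo) * (255.0 / (hi - lo))
    return np.rint(np.clip(out, 0.0, 255.0)).astype(np.uint8)


def dark_noise_mask(img: np.ndarray, threshold: int) -> np.ndarray:
    """Flag pixels of the stretched image darker than *threshold*.

    Flagged pixels are excluded from final object formation.  ``threshold``
    is in stretched-output units; 0 flags nothing, 256 flags everything.
    """
    return np.asarray(img) < threshold
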