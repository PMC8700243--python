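"""Reading and writing of ultrasound frames and binary masks.

Canonical in-memory form: a 2-D ``numpy`` array of ``uint8`` intensities,
row-major, 0-based, indexed ``(row, col)``.  Binary masks are boolean arrays
of the same shape.  A :class:`Roi` selects the half-open window
``[y0, y0+h) x [x0, x0+w)``.

Supported inputs: single-frame grayscale DICOM (detected by the ``DICM``
magic), plus anything ``imageio`` decodes (PNG, TIFF, ...).  Multi-channel
frames are collapsed by luminance average; inputs deeper than 8 bits are
min-max rescaled to 0-255 so that the 256-bin histogram stages downstream
stay meaningful.  Multi-frame (cine) DICOM is rejected rather than silently
truncated to frame 0.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pydicom

from .errors import UnsupportedFormatError

__all__ = ["Roi", "read_image", "read_mask", "write_mask", "write_report"]


@dataclass(frozen=True)
class Roi:
    """Rectangular region of interest, inclusive-exclusive in both axes."""

    x0: int
    y0: int
    w: int
    h: int

    def __post_init__(self) -> None:
        if self.x0 < 0 or self.y0 < 0:
            raise ValueError("Roi corner must be non-negative")
        if self.w < 1 or self.h < 1:
            raise ValueError("Roi extent must be at least 1x1")

    def crop(self, img: np.ndarray) -> np.ndarray:
        H, W = img.shape[:2]
        if self.x0 + self.w > W or self.y0 + self.h > H:
            raise ValueError(
                f"Roi {self} not contained in image of shape {H}x{W}"
            )
        return img[self.y0 : self.y0 + self.h, self.x0 : self.x0 + self.w]


def _is_dicom(path: Path) -> bool:
    try:
        with open(path, "rb") as fh:
            fh.seek(128)
            return fh.read(4) == b"DICM"
    except OSError:
        return False


def _to_canonical(arr: np.ndarray) -> np.ndarray:
    """Collapse channels and rescale bit depth to the canonical uint8 grid."""
    if arr.ndim == 3 and arr.shape[-1] in (2, 3, 4):
        # Luminance average over color channels (alpha dropped if present).
        nch = 3 if arr.shape[-1] >= 3 else 1
        was_uint8 = arr.dtype == np.uint8
        arr = arr[..., :nch].astype(np.float64).mean(axis=-1)
        if was_uint8:
            return np.rint(arr).astype(np.uint8)
    if arr.ndim != 2:
        raise UnsupportedFormatError(
            f"expected a single 2-D grayscale frame, got shape {arr.shape}"
        )
    if arr.dtype == np.uint8:
        return arr
    arr = arr.astype(np.float64)
    mn, mx = float(arr.min()), float(arr.max())
    if mx > mn:
        arr = (arr - mn) * (255.0 / (mx - mn))
    else:
        arr = np.zeros_like(arr)
    return np.rint(arr).astype(np.uint8)


def read_image(path: str | Path, roi: Roi | None = None) -> np.ndarray:
    """Read *path* into the canonical uint8 grid, optionally cropped to *roi*."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such image file: {path}")
    if _is_dicom(path):
        ds = pydicom.dcmread(path)
        arr = np.asarray(ds.pixel_array)
        if arr.ndim == 3 and arr.shape[-1] not in (2, 3, 4):
            raise UnsupportedFormatError(
                f"multi-frame/cine DICOM not supported: {path}"
            )
    else:
        try:
            arr = np.asarray(iio.imread(path))
        except Exception as exc:  # noqa: BLE001 - normalise decoder errors
            raise OSError(f"cannot decode image file: {path}") from exc
    img = _to_canonical(arr)
    if roi is not None:
        img = roi.crop(img)
    return img


def write_mask(mask: np.ndarray, path: str | Path) -> None:
    """Write a binary mask as a lossless 0/255 PNG (or TIFF by suffix)."""
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError("mask must be 2-D")
    iio.imwrite(Path(path), (mask.astype(bool).astype(np.uint8) * 255))


def read_mask(path: str | Path) -> np.ndarray:
    """Read a mask written by :func:`write_mask` back to a boolean grid."""
    return read_image(path) > 0


def write_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, default=str) + "\n")
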