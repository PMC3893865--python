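"""Shared data types, physical-unit calibration and raster/contour primitives.

Conventions used throughout the package:

* images are ``numpy`` arrays indexed ``[row, col]``, 0-based, origin at the
  top-left corner;
* RGB images are ``uint8`` arrays of shape ``(H, W, 3)``;
* binary masks are boolean arrays with ``True`` marking the object named by
  the operation (brown membrane pixels, lumen pixels, ...);
* a :class:`Contour` stores an ordered ``(N, 2)`` array of ``(row, col)``
  points forming a closed polygon; any ``(x, y)`` pair exported in reports is
  ``(col, row)``;
* bounding boxes are half-open: ``(row0, col0, row1, col1)`` spans rows
  ``row0 .. row1-1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage

__all__ = [
    "Calibration",
    "Contour",
    "SegmentationParams",
    "STAIN_PRESETS",
    "px_to_um",
    "um_to_px",
    "area_px_to_um2",
    "read_rgb_image",
    "as_rgb8",
    "rasterize_contour",
    "contour_interior",
    "SQUARE_3x3",
]

#: 3x3 square structuring element (8-connectivity); the kernel used by every
#: erosion/dilation in the pipeline.
SQUARE_3x3 = np.ones((3, 3), dtype=bool)

#: Default saturation threshold per stain preset: weak / medium / strong.
STAIN_PRESETS = {"WS": 10, "MS": 20, "SS": 30}


@dataclass(frozen=True)
class Calibration:
    """Physical scale of the image.

    Parameters
    ----------
    um_per_px
        Micrometres per pixel. The default 0.23 corresponds to an Aperio
        ScanScope T2 at 40x; override it for other scanners.
    """

    um_per_px: float = 0.23

    def __post_init__(self) -> None:
        if not self.um_per_px > 0:
            raise ValueError(f"um_per_px must be positive, got {self.um_per_px}")


def px_to_um(length_px: float, calib: Calibration) -> float:
    """Convert a length in pixels to micrometres."""
    if length_px < 0:
        raise ValueError(f"length_px must be non-negative, got {length_px}")
    return length_px * calib.um_per_px


def um_to_px(length_um: float, calib: Calibration) -> float:
    """Convert a length in micrometres to (real-valued) pixels."""
    if length_um < 0:
        raise ValueError(f"length_um must be non-negative, got {length_um}")
    return length_um / calib.um_per_px


def area_px_to_um2(area_px: float, calib: Calibration) -> float:
    """Convert an area in square pixels to square micrometres."""
    if area_px < 0:
        raise ValueError(f"area_px must be non-negative, got {area_px}")
    return area_px * calib.um_per_px**2


@dataclass(eq=False)
class Contour:
    """Closed, ordered polygon of pixel coordinates bounding one vessel.

    ``points`` is an ``(N, 2)`` array of ``(row, col)`` coordinates.  Border
    following produces sequences whose consecutive points are 8-connected
    neighbours; polygons built by the radial closing stage may have longer
    straight edges (they are rasterised on demand).
    """

    points: np.ndarray
    closed: bool = True

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points))
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("contour points must be an (N, 2) array")

    def __len__(self) -> int:
        return len(self.points)

    @property
    def bbox(self) -> tuple[int, int, int, int]:
        """Half-open bounding box ``(row0, col0, row1, col1)``."""
        mins = np.floor(self.points.min(axis=0)).astype(int)
        maxs = np.floor(self.points.max(axis=0)).astype(int)
        return (mins[0], mins[1], maxs[0] + 1, maxs[1] + 1)

    @property
    def width_px(self) -> float:
        """Column extent of the polygon (max col − min col)."""
        return float(self.points[:, 1].max() - self.points[:, 1].min())

    @property
    def height_px(self) -> float:
        """Row extent of the polygon (max row − min row)."""
        return float(self.points[:, 0].max() - self.points[:, 0].min())

    def perimeter_px(self) -> float:
        """Sum of Euclidean distances between consecutive points (closed)."""
        pts = self.points.astype(float)
        diffs = np.diff(np.vstack([pts, pts[:1]]), axis=0)
        return float(np.hypot(diffs[:, 0], diffs[:, 1]).sum())


@dataclass
class SegmentationParams:
    """Execution parameters of the segmentation pipeline.

    ``T_H``/``T_S`` are the hue and saturation thresholds of the brown
    predicate on the 8-bit HSV scale; ``T_S`` defaults from the stain preset
    (10 weak / 20 medium / 30 strong).  ``min_stained_fraction`` /
    ``max_stained_fraction`` optionally override the per-size-class required
    hit ratios of the radial analysis.
    """

    T_H: int = 20
    T_S: int | None = None
    stain_preset: str = "MS"
    min_stained_fraction: float = 0.1
    max_stained_fraction: float = 0.9
    lumen_threshold: int = 236
    probe_radius_um: float = 3.0
    mode: str = "automatic"

    def __post_init__(self) -> None:
        preset = self.stain_preset.upper()
        if preset not in (*STAIN_PRESETS, "OTHER"):
            raise ValueError(f"unknown stain preset {self.stain_preset!r}")
        self.stain_preset = preset
        if self.T_S is None:
            if preset == "OTHER":
                raise ValueError("stain_preset 'other' requires explicit T_S")
            self.T_S = STAIN_PRESETS[preset]
        for name in ("T_H", "T_S", "lumen_threshold"):
            v = getattr(self, name)
            if not 0 <= v <= 255:
                raise ValueError(f"{name} must be in [0, 255], got {v}")
        if not 0.1 <= self.min_stained_fraction <= self.max_stained_fraction <= 0.9:
            raise ValueError(
                "stained fractions must satisfy 0.1 <= min <= max <= 0.9, got "
                f"{self.min_stained_fraction}..{self.max_stained_fraction}"
            )
        if self.mode not in ("automatic", "manual"):
            raise ValueError(f"mode must be 'automatic' or 'manual', got {self.mode!r}")


# ---------------------------------------------------------------------------
# Raster I/O and contour rasterisation
# ---------------------------------------------------------------------------

def read_rgb_image(path: str | Path) -> np.ndarray:
    """Read a TIFF/PNG/JPEG file as an 8-bit RGB array of shape (H, W, 3)."""
    import imageio.v3 as iio

    arr = iio.imread(Path(path))
    return as_rgb8(arr)


def as_rgb8(arr: np.ndarray) -> np.ndarray:
    """Validate/coerce an array to uint8 RGB with shape (H, W, 3)."""
    arr = np.asarray(arr)
    if arr.ndim == 2:  # greyscale: replicate channels
        arr = np.stack([arr] * 3, axis=-1)
    if arr.ndim == 3 and arr.shape[2] == 4:  # drop alpha
        arr = arr[..., :3]
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"expected an RGB image, got shape {arr.shape}")
    if arr.dtype != np.uint8:
        raise ValueError(f"expected 8-bit channels, got dtype {arr.dtype}")
    return arr


def rasterize_contour(
    contour: Contour | Sequence, shape: tuple[int, int]
) -> np.ndarray:
    """Draw a contour's boundary pixels onto a blank boolean mask.

    Consecutive points are joined with 8-connected digital line segments, so
    both border-following output (unit steps) and radial-closure polygons
    (long chords) rasterise to a connected closed curve.
    """
    from skimage.draw import line

    pts = contour.points if isinstance(contour, Contour) else np.asarray(contour)
    pts = np.round(pts).astype(int)
    mask = np.zeros(shape, dtype=bool)
    n = len(pts)
    if n == 1:
        r, c = pts[0]
        if 0 <= r < shape[0] and 0 <= c < shape[1]:
            mask[r, c] = True
        return mask
    for i in range(n):
        r0, c0 = pts[i]
        r1, c1 = pts[(i + 1) % n]
        rr, cc = line(r0, c0, r1, c1)
        ok = (rr >= 0) & (rr < shape[0]) & (cc >= 0) & (cc < shape[1])
        mask[rr[ok], cc[ok]] = True
    return mask


def contour_interior(
    contour: Contour | Sequence, shape: tuple[int, int]
) -> np.ndarray:
    """Filled pixel region bounded by a closed contour (boundary included).

    The boundary is rasterised 8-connected, so a 4-connected hole fill cannot
    leak through diagonal steps.
    """
    ring = rasterize_contour(contour, shape)
    return ndimage.binary_fill_holes(ring)
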