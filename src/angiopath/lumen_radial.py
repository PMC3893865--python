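"""Lumen detection and radial closing of open vessels.

Open vessels — those whose stained membrane does not form a complete ring —
always enclose a bright vascular lumen.  The lumen is segmented on the green
channel (gray level >= 236), refined morphologically, and each lumen border
point probes outward along its normal for membrane within a 3 μm radius.
The fraction of border points that find membrane (the *hit ratio*) decides
whether the candidate is a vessel; the requirement is stricter for smaller
lumens (60% / 50% / 40% for small / medium / large).  Accepted vessels are
closed by connecting the membrane hit locations, bridging runs of misses
with straight segments (linear interpolation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import (
    SQUARE_3x3,
    Calibration,
    Contour,
    SegmentationParams,
    contour_interior,
    px_to_um,
    um_to_px,
)
from .color_segmentation import filter_artifacts, trace_contours

__all__ = [
    "SizeCategory",
    "RadialProbeResult",
    "lumen_mask",
    "lumen_refine",
    "classify_lumen",
    "radial_probe",
    "close_open_vessel",
    "detect_open_vessels",
    "SMALL_MAX_UM",
    "MEDIUM_MAX_UM",
]

#: Size-class boundaries on the lumen contour length (54 / 135 px at 0.23 μm/px).
SMALL_MAX_UM = 12.42
MEDIUM_MAX_UM = 31.05

_REQUIRED_RATIO = {"small": 0.60, "medium": 0.50, "large": 0.40}


@dataclass(frozen=True)
class SizeCategory:
    """Lumen size class with its required membrane hit ratio."""

    label: str
    required_hit_ratio: float


@dataclass
class RadialProbeResult:
    """Per-point outcome of probing outward from a lumen border.

    ``hits`` flags which border points found membrane within the probe
    radius; ``hit_locations[i]`` is the membrane pixel found for point ``i``
    (row, col), or (-1, -1) where the probe missed.
    """

    points: np.ndarray
    normals: np.ndarray
    hits: np.ndarray
    hit_locations: np.ndarray

    @property
    def hit_ratio(self) -> float:
        return float(self.hits.mean()) if len(self.hits) else 0.0


def lumen_mask(image: np.ndarray, threshold: int = 236) -> np.ndarray:
    """Candidate lumen pixels: green channel >= threshold."""
    if not 0 <= threshold <= 255:
        raise ValueError(f"threshold must be in [0, 255], got {threshold}")
    return np.asarray(image)[..., 1] >= threshold


def lumen_refine(mask: np.ndarray, fill_limit_px: int = 400) -> np.ndarray:
    """Clean the raw lumen mask.

    Erode x3 (removing glare specks), dilate x2, fill internal holes smaller
    than ``fill_limit_px`` of area, then erode once more to open a gap
    between the lumen and the membrane, all with the 3x3 kernel.
    """
    out = np.asarray(mask, dtype=bool)
    out = ndimage.binary_erosion(out, SQUARE_3x3, iterations=3)
    out = ndimage.binary_dilation(out, SQUARE_3x3, iterations=2)
    out = _fill_small_holes(out, fill_limit_px)
    out = ndimage.binary_erosion(out, SQUARE_3x3, iterations=1)
    return out


def _fill_small_holes(mask: np.ndarray, max_area: int) -> np.ndarray:
    # holes = 4-connected background components not touching the image border
    bg_labels, n = ndimage.label(~mask)  # default structure is 4-connected
    if n == 0:
        return mask
    border = np.zeros_like(mask)
    border[0, :] = border[-1, :] = border[:, 0] = border[:, -1] = True
    touching = np.unique(bg_labels[border & ~mask])
    areas = np.bincount(bg_labels.ravel(), minlength=n + 1)
    fill = np.zeros(n + 1, dtype=bool)
    fill[1:] = areas[1:] < max_area
    fill[touching] = False
    return mask | fill[bg_labels]


def classify_lumen(contour_length_um: float) -> SizeCategory:
    """Size class of a lumen from its contour length in μm.

    small: < 12.42 μm; medium: [12.42, 31.05]; large: > 31.05 μm.
    """
    if contour_length_um < 0:
        raise ValueError(f"contour length must be non-negative, got {contour_length_um}")
    if contour_length_um < SMALL_MAX_UM:
        label = "small"
    elif contour_length_um <= MEDIUM_MAX_UM:
        label = "medium"
    else:
        label = "large"
    return SizeCategory(label, _REQUIRED_RATIO[label])


def radial_probe(
    lumen_contour: Contour,
    membrane: np.ndarray,
    calib: Calibration,
    probe_radius_um: float = 3.0,
    chord_k: int = 2,
    membrane_dilate_iters: int = 2,
) -> RadialProbeResult:
    """Probe outward from each lumen border point for nearby membrane.

    The outward normal at point *i* is perpendicular to the chord between
    the ``chord_k``-th predecessor and successor, oriented away from the
    contour centroid, and traced one pixel per step for up to
    ``round(probe_radius_um / um_per_px)`` steps.  The membrane mask is
    dilated ``membrane_dilate_iters`` times first (the lumen refinement
    eroded an equivalent gap open).
    """
    pts = np.asarray(lumen_contour.points, dtype=float)
    n = len(pts)
    if n < 5:
        raise ValueError(f"contour with {n} < 5 points cannot be probed")
    mem = membrane
    if membrane_dilate_iters:
        mem = ndimage.binary_dilation(mem, SQUARE_3x3, iterations=membrane_dilate_iters)
    h, w = mem.shape
    centroid = pts.mean(axis=0)
    n_steps = int(round(um_to_px(probe_radius_um, calib)))

    normals = np.zeros_like(pts)
    hits = np.zeros(n, dtype=bool)
    hit_locations = np.full((n, 2), -1, dtype=int)
    for i in range(n):
        chord = pts[(i + chord_k) % n] - pts[(i - chord_k) % n]
        normal = np.array([-chord[1], chord[0]])
        nrm = np.hypot(*normal)
        if nrm == 0:  # degenerate chord: fall back to the radial direction
            normal = pts[i] - centroid
            nrm = np.hypot(*normal)
            if nrm == 0:
                continue
        normal /= nrm
        if np.dot(normal, pts[i] - centroid) < 0:
            normal = -normal
        normals[i] = normal
        for s in range(1, n_steps + 1):
            q = np.round(pts[i] + s * normal).astype(int)
            if not (0 <= q[0] < h and 0 <= q[1] < w):
                break
            if mem[q[0], q[1]]:
                hits[i] = True
                hit_locations[i] = q
                break
    return RadialProbeResult(pts, normals, hits, hit_locations)


def close_open_vessel(
    probe: RadialProbeResult, category: SizeCategory
) -> Contour | None:
    """Close an open vessel from its probe result, or reject it.

    Returns ``None`` when ``hit_ratio`` falls below the category's required
    ratio.  Otherwise the closed polygon is the sequence of membrane hit
    locations in contour order; runs of missed points are bridged implicitly
    by the straight segment between the flanking hit locations.
    """
    if probe.hit_ratio < category.required_hit_ratio:
        return None
    hit_pts = probe.hit_locations[probe.hits]
    if len(hit_pts) < 3:
        return None
    return Contour(np.array(hit_pts), closed=True)


def detect_open_vessels(
    image: np.ndarray,
    membrane: np.ndarray,
    calib: Calibration,
    params: SegmentationParams | None = None,
) -> list[Contour]:
    """Full radial branch: lumen detection, probing, closing, re-tracing.

    ``membrane`` is the refined mask from the colour branch.  Accepted closed
    polygons are rasterised and filled, their borders re-traced, and
    sub-resolution artifacts removed, mirroring the colour branch's final
    steps.  The optional stained-fraction bounds in ``params`` clamp the
    per-category required hit ratio.
    """
    params = params or SegmentationParams()
    raw = lumen_mask(image, params.lumen_threshold)
    refined = lumen_refine(raw)
    lumen_contours = trace_contours(refined)

    canvas = np.zeros(membrane.shape, dtype=bool)
    found = False
    for lc in lumen_contours:
        if len(lc) < 5:
            continue
        length_um = px_to_um(lc.perimeter_px(), calib)
        category = classify_lumen(length_um)
        required = float(
            np.clip(
                category.required_hit_ratio,
                params.min_stained_fraction,
                params.max_stained_fraction,
            )
        )
        probe = radial_probe(lc, membrane, calib, params.probe_radius_um)
        closed = close_open_vessel(
            probe, SizeCategory(category.label, required)
        )
        if closed is None:
            continue
        canvas |= contour_interior(closed, membrane.shape)
        found = True
    if not found:
        return []
    return filter_artifacts(trace_contours(canvas))
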