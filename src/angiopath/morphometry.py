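"""Per-vessel morphometric measurements.

Twelve measurements are computed on each fused vessel contour: centre
location; area (μm²); width and height (μm); perimeter (μm); orientation
angle (radians); aspect (major/minor best-fit-ellipse axes); roundness
P²/(4πA); perimeter ratio (convex perimeter / perimeter); deformity (convex
area − area, μm²); shape (Hu-moment dissimilarity between the region and
its convex hull); and the Douglas–Peucker vertex count.  Vascular density
(vessels per μm² of core) is a per-core quantity.

Area uses the shoelace formula on the contour polygon, perimeter the sum of
Euclidean inter-point distances (diagonal steps count √2).  Unitless
measures are calibration-invariant; μm/μm² measures follow exact scaling
laws in ``um_per_px``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from shapely.geometry import MultiPoint
from skimage import measure as skmeasure
from skimage.draw import polygon as draw_polygon

from .core import Calibration, Contour, area_px_to_um2, px_to_um

__all__ = [
    "VesselRecord",
    "polygon_metrics",
    "convex_metrics",
    "ellipse_aspect_angle",
    "hu_shape",
    "dp_vertex_count",
    "measure_vessel",
    "vascular_density",
]

logger = logging.getLogger(__name__)


@dataclass
class VesselRecord:
    """The twelve measurements of one vessel.

    ``center`` is exported as (x, y) = (col, row).  ``deformity`` is an area
    difference and is reported in μm².
    """

    center: tuple[float, float]
    area: float
    width: float
    height: float
    perimeter: float
    angle: float
    aspect: float
    roundness: float
    perimeter_ratio: float
    deformity: float
    shape: float
    vertices: int


def _shoelace_area_px(pts: np.ndarray) -> float:
    x = pts[:, 1]
    y = pts[:, 0]
    return 0.5 * abs(
        float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
    )


def polygon_metrics(
    contour: Contour, calib: Calibration
) -> tuple[float, float, float, float, tuple[float, float]]:
    """(area μm², perimeter μm, width μm, height μm, center (x, y) px)."""
    pts = np.asarray(contour.points, dtype=float)
    if len(pts) < 3:
        raise ValueError("polygon metrics need at least 3 points")
    area_px = _shoelace_area_px(pts)
    if area_px == 0:
        raise ValueError("degenerate (collinear) contour has zero area")
    area = area_px_to_um2(area_px, calib)
    perimeter = px_to_um(contour.perimeter_px(), calib)
    width = px_to_um(contour.width_px, calib)
    height = px_to_um(contour.height_px, calib)
    center_rc = _polygon_centroid(pts)
    return area, perimeter, width, height, (center_rc[1], center_rc[0])


def _polygon_centroid(pts: np.ndarray) -> tuple[float, float]:
    # area-weighted centroid of the closed polygon (shoelace form)
    x = pts[:, 1]
    y = pts[:, 0]
    xn = np.roll(x, -1)
    yn = np.roll(y, -1)
    cross = x * yn - xn * y
    a = cross.sum() / 2.0
    if abs(a) < 1e-12:
        return float(y.mean()), float(x.mean())
    cx = float(((x + xn) * cross).sum() / (6.0 * a))
    cy = float(((y + yn) * cross).sum() / (6.0 * a))
    return cy, cx


def convex_metrics(
    contour: Contour, calib: Calibration
) -> tuple[float, float, float, float]:
    """(convex perimeter μm, convex area μm², perimeter ratio, deformity μm²)."""
    pts = np.asarray(contour.points, dtype=float)
    if len(pts) < 3:
        raise ValueError("convex metrics need at least 3 points")
    hull = MultiPoint([(p[1], p[0]) for p in pts]).convex_hull
    if hull.geom_type != "Polygon":
        raise ValueError("degenerate contour: convex hull is not a polygon")
    hull_perim = px_to_um(hull.length, calib)
    hull_area = area_px_to_um2(hull.area, calib)
    perimeter = px_to_um(contour.perimeter_px(), calib)
    area = area_px_to_um2(_shoelace_area_px(pts), calib)
    return hull_perim, hull_area, hull_perim / perimeter, hull_area - area


def _filled_region(contour: Contour) -> np.ndarray:
    """Rasterise the contour polygon as a filled boolean region (local frame)."""
    pts = np.asarray(contour.points, dtype=float)
    offset = np.floor(pts.min(axis=0)).astype(int)
    local = pts - offset
    shape = tuple(np.ceil(local.max(axis=0)).astype(int) + 1)
    rr, cc = draw_polygon(local[:, 0], local[:, 1], shape)
    mask = np.zeros(shape, dtype=bool)
    mask[rr, cc] = True
    # include the boundary pixels themselves
    b = np.round(local).astype(int)
    mask[np.clip(b[:, 0], 0, shape[0] - 1), np.clip(b[:, 1], 0, shape[1] - 1)] = True
    return mask


def ellipse_aspect_angle(contour: Contour) -> tuple[float, float]:
    """Aspect ratio and orientation of the best-fitting ellipse.

    Fitted from second-order central moments of the filled contour region.
    ``aspect`` = major/minor axis length (>= 1); ``angle`` is the major-axis
    orientation versus the image horizontal, counter-clockwise in the usual
    mathematical sense (y up), in (−π/2, π/2].
    """
    if len(contour) < 5:
        raise ValueError("ellipse fit needs at least 5 points")
    region = _filled_region(contour).astype(np.uint8)
    mu = skmeasure.moments_central(region, order=2)
    m00 = mu[0, 0]
    mu20 = mu[0, 2] / m00  # variance along columns (x)
    mu02 = mu[2, 0] / m00  # variance along rows (y)
    mu11 = mu[1, 1] / m00
    common = math.sqrt(4 * mu11**2 + (mu20 - mu02) ** 2)
    lam1 = (mu20 + mu02 + common) / 2
    lam2 = (mu20 + mu02 - common) / 2
    if lam2 <= 0:
        raise ValueError("degenerate region: zero minor axis")
    aspect = math.sqrt(lam1 / lam2)
    # row axis points down, so negate the mixed moment for a y-up angle
    angle = 0.5 * math.atan2(-2 * mu11, mu20 - mu02)
    if angle <= -math.pi / 2:
        angle += math.pi
    return aspect, angle


def hu_shape(contour: Contour, indices: tuple[int, ...] = (1, 2)) -> float:
    """Hu-moment dissimilarity between the vessel region and its convex hull.

    For the filled contour region (A) and its filled convex hull (B),
    ``m_i = sign(h_i)·log|h_i|`` over the Hu invariants ``h_i`` and the value
    is ``max_i |m_i^A − m_i^B| / |m_i^A|``.  ``indices`` are 1-based and
    default to the first two invariants; pass ``(1, ..., 7)`` to widen the
    comparison to all seven.  Indices where an invariant vanishes are
    skipped (logged).  Zero for convex contours (A ≡ B).
    """
    if len(contour) < 3:
        raise ValueError("hu_shape needs at least 3 points")
    region = _filled_region(contour)
    pts = np.asarray(contour.points, dtype=float)
    hull = MultiPoint([(p[1], p[0]) for p in pts]).convex_hull
    hull_pts = np.array([(y, x) for x, y in hull.exterior.coords])
    hull_region = _filled_region(Contour(hull_pts))

    hA = _hu(region)
    hB = _hu(hull_region)
    best = 0.0
    for i in indices:
        a, b = hA[i - 1], hB[i - 1]
        if a == 0 or b == 0:
            logger.info("hu_shape: invariant %d vanished; skipped", i)
            continue
        mA = math.copysign(math.log(abs(a)), a)
        mB = math.copysign(math.log(abs(b)), b)
        best = max(best, abs(mA - mB) / abs(mA))
    return best


def _hu(region: np.ndarray) -> np.ndarray:
    mu = skmeasure.moments_central(region.astype(np.uint8), order=3)
    nu = skmeasure.moments_normalized(mu)
    return skmeasure.moments_hu(nu)


def dp_vertex_count(contour: Contour, epsilon_px: float = 2.0) -> int:
    """Vertex count of the Douglas–Peucker simplification of the contour.

    The closed ring is rotated to start at the point farthest from the
    centroid (a high-curvature point) so the split chord does not cut a
    corner, then simplified at tolerance ``epsilon_px``.
    """
    if epsilon_px <= 0:
        raise ValueError(f"epsilon must be positive, got {epsilon_px}")
    pts = np.asarray(contour.points, dtype=float)
    if len(pts) == 2:
        return 2  # degenerate polyline: endpoints always kept
    if len(pts) < 2:
        raise ValueError("need at least 2 points")
    centroid = pts.mean(axis=0)
    start = int(np.argmax(np.hypot(*(pts - centroid).T)))
    ring = np.roll(pts, -start, axis=0)
    ring = np.vstack([ring, ring[:1]])  # close
    approx = skmeasure.approximate_polygon(ring, tolerance=epsilon_px)
    n = len(approx)
    if np.allclose(approx[0], approx[-1]):
        n -= 1
    return max(n, 3)


def measure_vessel(
    contour: Contour,
    calib: Calibration,
    dp_epsilon_px: float = 2.0,
    hu_indices: tuple[int, ...] = (1, 2),
) -> VesselRecord:
    """Aggregate the twelve measurements for one vessel contour."""
    area, perimeter, width, height, center = polygon_metrics(contour, calib)
    _, _, perimeter_ratio, deformity = convex_metrics(contour, calib)
    aspect, angle = ellipse_aspect_angle(contour)
    shape = hu_shape(contour, hu_indices)
    vertices = dp_vertex_count(contour, dp_epsilon_px)
    roundness = perimeter**2 / (4 * math.pi * area)
    return VesselRecord(
        center=center,
        area=area,
        width=width,
        height=height,
        perimeter=perimeter,
        angle=angle,
        aspect=aspect,
        roundness=roundness,
        perimeter_ratio=perimeter_ratio,
        deformity=deformity,
        shape=shape,
        vertices=vertices,
    )


def vascular_density(n_vessels: int, core_area_um2: float) -> float:
    """Vessels per μm² of core area."""
    if core_area_um2 <= 0:
        raise ValueError(f"core area must be positive, got {core_area_um2}")
    if n_vessels < 0:
        raise ValueError("vessel count must be non-negative")
    return n_vessels / core_area_um2
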