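"""Fusing the colour-branch and radial-branch detections into one vessel set.

Both branches rasterise their contours onto one canvas; the union is
re-traced and filtered, which merges detections whose outlines touch or
cross.  Concentric or partially overlapping duplicates that survive as
separate outlines are collapsed explicitly: a vessel whose interior shares
more than half its pixels with an already-kept (larger) vessel is dropped.
Manual mode removes user-flagged vessels given as centre-point coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import Contour, contour_interior, rasterize_contour
from .color_segmentation import filter_artifacts, trace_contours

__all__ = ["Vessel", "VesselSet", "merge_branches", "exclude_vessels"]

DEDUP_OVERLAP = 0.5  # interior-overlap fraction above which vessels collapse


@dataclass
class Vessel:
    contour: Contour
    provenance: str  # "closed_branch" | "open_branch"
    center: tuple[float, float]  # (row, col)


@dataclass
class VesselSet:
    vessels: list[Vessel] = field(default_factory=list)
    image_shape: tuple[int, int] = (0, 0)
    unmatched_exclusions: list[tuple[int, int]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.vessels)

    def __iter__(self):
        return iter(self.vessels)


def merge_branches(
    closed: list[Contour],
    open: list[Contour],
    image_shape: tuple[int, int],
) -> VesselSet:
    """Join closed- and open-vessel contours into a deduplicated vessel set.

    Commutative in its two inputs up to provenance labels; the result has at
    most ``len(closed) + len(open)`` vessels, with equality exactly when all
    detections are pairwise disjoint.
    """
    for c in closed + open:
        r0, c0, r1, c1 = c.bbox
        if r1 > image_shape[0] or c1 > image_shape[1] or r0 < 0 or c0 < 0:
            raise ValueError("contour exceeds the stated image shape")

    canvas = np.zeros(image_shape, dtype=bool)
    for c in closed + open:
        canvas |= rasterize_contour(c, image_shape)
    traced = filter_artifacts(trace_contours(canvas))

    closed_union = np.zeros(image_shape, dtype=bool)
    for c in closed:
        closed_union |= contour_interior(c, image_shape)

    interiors = [contour_interior(c, image_shape) for c in traced]
    areas = np.array([int(i.sum()) for i in interiors])
    order = np.argsort(-areas, kind="stable")  # larger vessels take precedence

    kept_union = np.zeros(image_shape, dtype=bool)
    vessels: list[Vessel] = []
    for idx in order:
        interior = interiors[idx]
        area = areas[idx]
        if area == 0:
            continue
        if (interior & kept_union).sum() > DEDUP_OVERLAP * area:
            continue
        kept_union |= interior
        overlap_closed = (interior & closed_union).sum()
        provenance = "closed_branch" if overlap_closed > DEDUP_OVERLAP * area else "open_branch"
        rows, cols = np.nonzero(interior)
        center = (float(rows.mean()), float(cols.mean()))
        vessels.append(Vessel(traced[idx], provenance, center))
    # restore raster order (top-left to bottom-right) for stable labelling
    vessels.sort(key=lambda v: (v.center[0], v.center[1]))
    return VesselSet(vessels, image_shape)


def exclude_vessels(
    vessels: VesselSet, exclusion_points: list[tuple[float, float]]
) -> VesselSet:
    """Remove the vessel nearest to each exclusion point (manual mode).

    A point matches the vessel with the nearest centre (Euclidean), provided
    the point falls inside or within 10 px of that vessel's bounding box.
    Unmatched points are recorded on the result, not fatal.  Idempotent for
    a fixed point list.
    """
    remaining = list(vessels.vessels)
    unmatched: list[tuple[int, int]] = []
    for pt in exclusion_points:
        pt = (float(pt[0]), float(pt[1]))
        best = None
        best_d = np.inf
        for v in remaining:
            d = np.hypot(v.center[0] - pt[0], v.center[1] - pt[1])
            if d < best_d:
                best, best_d = v, d
        if best is not None:
            r0, c0, r1, c1 = best.contour.bbox
            if (r0 - 10 <= pt[0] <= r1 + 10) and (c0 - 10 <= pt[1] <= c1 + 10):
                remaining.remove(best)
                continue
        unmatched.append((int(round(pt[0])), int(round(pt[1]))))
    return VesselSet(remaining, vessels.image_shape, unmatched)
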