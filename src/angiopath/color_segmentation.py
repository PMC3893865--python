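"""Brown-membrane segmentation via HSV dual thresholding.

DAB chromogen renders antibody-bound endothelium brown; on an 8-bit HSV
scale (hue 360° mapped to 255) brown occupies low hue at appreciable
saturation, while the hematoxylin counterstain sits at blue hues and the
bright lumens at near-zero saturation.  A pixel is called membrane when
``H <= T_H`` and ``S > T_S`` — the composition of a binary threshold on H,
an inverted threshold on S, a pixelwise OR and a final NOT.  The mask is
then cleaned with 2 erosions and 4 dilations (3×3 kernel), outer borders are
traced, and sub-resolution artifacts are discarded.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage.color import rgb2hsv

from .core import SQUARE_3x3, Contour, SegmentationParams, as_rgb8

__all__ = [
    "rgb_to_hsv8",
    "brown_mask",
    "brown_mask_literal_chain",
    "morph_refine",
    "trace_contours",
    "filter_artifacts",
    "segment_closed_vessels",
]


def rgb_to_hsv8(image: np.ndarray) -> np.ndarray:
    """Convert an 8-bit RGB image to HSV with all channels scaled to [0, 255].

    Hue wraps: 0 and 255 are adjacent (360° maps to 255).
    """
    rgb = as_rgb8(image)
    hsv = rgb2hsv(rgb)  # float in [0, 1]
    return np.clip(np.round(hsv * 255.0), 0, 255).astype(np.uint8)


def brown_mask(hsv: np.ndarray, T_H: int = 20, T_S: int = 20) -> np.ndarray:
    """Membrane predicate: foreground ⇔ ``H <= T_H`` and ``S > T_S``."""
    _check_threshold(T_H, "T_H")
    _check_threshold(T_S, "T_S")
    H = hsv[..., 0]
    S = hsv[..., 1]
    return (H <= T_H) & (S > T_S)


def brown_mask_literal_chain(hsv: np.ndarray, T_H: int = 20, T_S: int = 20) -> np.ndarray:
    """The literal four-step formulation of :func:`brown_mask`.

    Binary threshold on H (``H > T_H`` → 255), inverted threshold on S
    (``S > T_S`` → 0), pixelwise OR, pixelwise NOT.  Kept as an executable
    statement of the contract: it must equal :func:`brown_mask` pixelwise.
    """
    _check_threshold(T_H, "T_H")
    _check_threshold(T_S, "T_S")
    m1 = np.where(hsv[..., 0] > T_H, 255, 0).astype(np.uint8)
    m2 = np.where(hsv[..., 1] > T_S, 0, 255).astype(np.uint8)
    combined = m1 | m2
    return ~combined.astype(bool)


def _check_threshold(t: int, name: str) -> None:
    if not 0 <= t <= 255:
        raise ValueError(f"{name} must be in [0, 255], got {t}")


def morph_refine(
    mask: np.ndarray, erode_iters: int = 2, dilate_iters: int = 4
) -> np.ndarray:
    """Erode then dilate with a 3×3 square kernel.

    Two erosions remove structures thinner than ~5 px (false-positive specks);
    four dilations re-join nearby membrane fragments (gap ≤ 2·dilate_iters px).
    """
    if erode_iters < 0 or dilate_iters < 0:
        raise ValueError("iteration counts must be non-negative")
    out = np.asarray(mask, dtype=bool)
    if erode_iters:
        out = ndimage.binary_erosion(out, SQUARE_3x3, iterations=erode_iters)
    if dilate_iters:
        out = ndimage.binary_dilation(out, SQUARE_3x3, iterations=dilate_iters)
    return out


# Clockwise Moore neighbourhood in (row, col) with row increasing downwards:
# E, SE, S, SW, W, NW, N, NE.
_MOORE = np.array(
    [(0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1), (-1, 0), (-1, 1)]
)


def trace_contours(mask: np.ndarray) -> list[Contour]:
    """Ordered outer border of every 8-connected foreground component.

    Moore-neighbour border following with Jacob's stopping criterion: the
    trace starts at the topmost-leftmost pixel of a component and walks its
    outer boundary clockwise until the start pixel is re-entered from the
    initial backtrack position.  Holes are not reported as separate vessels.
    """
    mask = np.asarray(mask, dtype=bool)
    labels, n = ndimage.label(mask, structure=SQUARE_3x3)
    contours: list[Contour] = []
    if n == 0:
        return contours
    slices = ndimage.find_objects(labels)
    for idx, sl in enumerate(slices, start=1):
        comp = labels[sl] == idx
        pts = _moore_trace(comp)
        pts[:, 0] += sl[0].start
        pts[:, 1] += sl[1].start
        contours.append(Contour(pts))
    return contours


def _moore_trace(comp: np.ndarray) -> np.ndarray:
    """Trace the outer border of a single component (boolean array)."""
    rows, cols = np.nonzero(comp)
    # topmost-leftmost foreground pixel; its W neighbour is background
    order = np.lexsort((cols, rows))
    start = (int(rows[order[0]]), int(cols[order[0]]))
    h, w = comp.shape

    def fg(r: int, c: int) -> bool:
        return 0 <= r < h and 0 <= c < w and comp[r, c]

    if not any(fg(start[0] + dr, start[1] + dc) for dr, dc in _MOORE):
        return np.array([start])  # isolated pixel

    # The trace is a deterministic walk on states (pixel, backtrack direction);
    # starting at the topmost-leftmost pixel with a W backtrack puts the start
    # state on the boundary cycle, so the walk is cut at the first repeated
    # state and any pre-cycle tail discarded.
    cur, prev_dir = start, 4  # backtrack W: guaranteed background
    seen = {(cur, prev_dir): 0}
    pix = [start]
    while True:
        base = (prev_dir + 1) % 8
        for k in range(8):
            d = (base + k) % 8
            nr, nc = cur[0] + _MOORE[d][0], cur[1] + _MOORE[d][1]
            if fg(nr, nc):
                break
        cur = (nr, nc)
        prev_dir = (d + 4) % 8  # points back at the pixel we came from
        state = (cur, prev_dir)
        if state in seen:
            pix = pix[seen[state]:]
            break
        seen[state] = len(pix)
        pix.append(cur)
    return np.array(pix)


def filter_artifacts(
    contours: list[Contour], min_len_px: int = 6, min_box_px: int = 20
) -> list[Contour]:
    """Drop sub-resolution detections.

    A contour is discarded when it has fewer than ``min_len_px`` boundary
    points, or when both its bounding-box width and height fall below
    ``min_box_px`` (4.6 μm at default calibration — below the smallest
    reported vessel group).  Thin elongated fragments survive: only objects
    small in *both* dimensions are artifacts.  Order-preserving, idempotent.
    """
    kept = []
    for c in contours:
        if len(c) < min_len_px:
            continue
        r0, c0, r1, c1 = c.bbox
        if (r1 - r0) < min_box_px and (c1 - c0) < min_box_px:
            continue
        kept.append(c)
    return kept


def segment_closed_vessels(
    image: np.ndarray, params: SegmentationParams | None = None
) -> tuple[np.ndarray, list[Contour]]:
    """Full colour branch: closed-vessel contours plus the refined membrane mask.

    Returns ``(membrane_mask, contours)``; the mask is reused by the radial
    branch, which probes for membrane around each candidate lumen.
    """
    params = params or SegmentationParams()
    hsv = rgb_to_hsv8(image)
    raw = brown_mask(hsv, params.T_H, params.T_S)
    membrane = morph_refine(raw)
    contours = filter_artifacts(trace_contours(membrane))
    return membrane, contours
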