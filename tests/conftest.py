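import numpy as np
import pytest

from angiopath.cli import process_image
from angiopath.core import Calibration, contour_interior
from angiopath.color_segmentation import trace_contours
from angiopath.synthetic_fixtures import preset_cores, render_core


@pytest.fixture(scope="session")
def calib():
    return Calibration()  # 0.23 um/px


@pytest.fixture(scope="session")
def unit_calib():
    return Calibration(1.0)


@pytest.fixture(scope="session")
def tiny_core():
    spec = preset_cores()["tiny"]
    return render_core(spec)


@pytest.fixture(scope="session")
def mixed_result():
    """Full pipeline run on the `mixed` preset (20 closed + 10 open vessels)."""
    spec = preset_cores()["mixed"]
    image, truths = render_core(spec)
    vessels, records, report = process_image(image)
    return image, truths, vessels, records, report


def make_annulus_case(r_lumen, arc_present, shape=(200, 200), gap=2, thick=6,
                      gap_angle_deg=90.0):
    """Crisp geometric fixture: a lumen contour plus an exact membrane arc mask.

    The membrane annulus starts ``gap`` px outside the lumen disk (the space
    the pipeline's final lumen erosion creates) and covers the stated
    fraction of the circle.
    """
    c = (shape[0] // 2, shape[1] // 2)
    rr, cc = np.mgrid[: shape[0], : shape[1]]
    dist = np.hypot(rr - c[0], cc - c[1])
    lumen = dist <= r_lumen
    ring = (dist >= r_lumen + gap) & (dist <= r_lumen + gap + thick)
    if arc_present < 1:
        ang = np.arctan2(rr - c[0], cc - c[1])
        diff = np.angle(np.exp(1j * (ang - np.deg2rad(gap_angle_deg))))
        ring &= np.abs(diff) > np.pi * (1 - arc_present)
    lumen_contour = trace_contours(lumen)[0]
    return lumen_contour, ring


def match_detections(vessels, truths, shape):
    """Match detections to ground-truth disks by >50% interior overlap.

    Returns (number of matched truths, number of unmatched detections).
    """
    idx_map = np.zeros(shape, dtype=np.int32)
    for i, v in enumerate(vessels, start=1):
        idx_map[contour_interior(v.contour, shape)] = i
    matched_ids = set()
    n_matched = 0
    for t in truths:
        (r0, c0), radius = t["spec"].center, t["spec"].outer_radius
        sl = np.s_[max(r0 - radius, 0): r0 + radius + 1,
                   max(c0 - radius, 0): c0 + radius + 1]
        rr, cc = np.mgrid[sl]
        disk = (rr - r0) ** 2 + (cc - c0) ** 2 <= radius**2
        ids = idx_map[sl][disk]
        counts = np.bincount(ids)
        if len(counts) > 1:
            best = counts[1:].argmax() + 1
            if counts[best] > 0.5 * disk.sum():
                n_matched += 1
                matched_ids.add(int(best))
    return n_matched, len(vessels) - len(matched_ids)
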