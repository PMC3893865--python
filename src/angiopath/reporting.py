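"""Per-core summaries and output files.

Vessels are grouped by height into five bins — [5, 15), [15, 20), [20, 50),
[50, 200) and >= 200 μm (heights under 5 μm fold into the first bin) — and
for each group the mean of every measurement, the group totals, the percent
of vessel area and the vessel count are reported, followed by an overall
average row, 24 summary quantities in all.  Outputs are an XLSX workbook
(per-vessel sheet + summary sheet), byte-stable CSV twins for diffing, and
a losslessly compressed labeled TIFF with each vessel's contour and index
drawn on the source image.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import Calibration, rasterize_contour
from .fusion import VesselSet
from .morphometry import VesselRecord, vascular_density

__all__ = [
    "HEIGHT_GROUP_BOUNDS",
    "HeightGroup",
    "CoreReport",
    "assign_height_group",
    "summarize",
    "write_measurements",
    "write_labeled_image",
]

#: Half-open height bins in μm; the last is unbounded above.
HEIGHT_GROUP_BOUNDS = [(5.0, 15.0), (15.0, 20.0), (20.0, 50.0), (50.0, 200.0), (200.0, math.inf)]

#: Per-vessel measurements that are averaged and totalled per group.
FEATURES = [
    "area",
    "width",
    "height",
    "perimeter",
    "angle",
    "aspect",
    "roundness",
    "perimeter_ratio",
    "deformity",
    "shape",
    "vertices",
]


@dataclass(frozen=True)
class HeightGroup:
    index: int  # 1-based
    low_um: float
    high_um: float

    @property
    def label(self) -> str:
        if math.isinf(self.high_um):
            return f">={self.low_um:g}"
        return f"[{self.low_um:g}-{self.high_um:g})"


def assign_height_group(height_um: float) -> HeightGroup:
    """Map a vessel height to its group; heights < 5 μm fold into group 1."""
    if height_um <= 0:
        raise ValueError(f"height must be positive, got {height_um}")
    for i, (lo, hi) in enumerate(HEIGHT_GROUP_BOUNDS, start=1):
        if height_um < hi:
            return HeightGroup(i, lo, hi)
    return HeightGroup(5, *HEIGHT_GROUP_BOUNDS[-1])  # pragma: no cover


@dataclass
class CoreReport:
    """Group summaries, the overall average row, and vascular density."""

    per_group: pd.DataFrame  # 5 rows: means, totals, percent area, count
    overall: pd.Series  # average row: means over all vessels + totals
    density: float
    n_vessels: int
    core_area_um2: float


def summarize(records: list[VesselRecord], core_area_um2: float) -> CoreReport:
    """Compute the per-group and overall summary of a vessel record list.

    Empty groups report zero counts and blank (NaN) means.  Percent areas
    sum to 100 whenever any vessel area is present; permutation-invariant.
    """
    if core_area_um2 <= 0:
        raise ValueError(f"core area must be positive, got {core_area_um2}")
    df = records_frame(records)
    group_idx = (
        df["height"].map(lambda h: assign_height_group(h).index)
        if len(df)
        else pd.Series(dtype=int)
    )
    total_area = df["area"].sum() if len(df) else 0.0

    rows = []
    for i, (lo, hi) in enumerate(HEIGHT_GROUP_BOUNDS, start=1):
        sub = df[group_idx == i] if len(df) else df
        row: dict[str, float] = {"group": HeightGroup(i, lo, hi).label}
        for f in FEATURES:
            row[f"mean_{f}"] = sub[f].mean() if len(sub) else np.nan
            row[f"total_{f}"] = sub[f].sum() if len(sub) else 0.0
        row["percent_area"] = (
            100.0 * sub["area"].sum() / total_area if total_area > 0 else 0.0
        )
        row["n_vessels"] = len(sub)
        rows.append(row)
    per_group = pd.DataFrame(rows).set_index("group")

    overall = {"group": "average"}
    for f in FEATURES:
        overall[f"mean_{f}"] = df[f].mean() if len(df) else np.nan
        overall[f"total_{f}"] = df[f].sum() if len(df) else 0.0
    overall["percent_area"] = 100.0 if total_area > 0 else 0.0
    overall["n_vessels"] = len(df)
    overall = pd.Series(overall).drop("group")
    overall.name = "average"

    return CoreReport(
        per_group=per_group,
        overall=overall,
        density=vascular_density(len(records), core_area_um2),
        n_vessels=len(records),
        core_area_um2=core_area_um2,
    )


def records_frame(records: list[VesselRecord]) -> pd.DataFrame:
    """Per-vessel records as a DataFrame with (x, y) centre columns."""
    rows = []
    for i, r in enumerate(records, start=1):
        row = {"vessel": i, "center_x": r.center[0], "center_y": r.center[1]}
        row.update({f: getattr(r, f) for f in FEATURES})
        rows.append(row)
    cols = ["vessel", "center_x", "center_y", *FEATURES]
    return pd.DataFrame(rows, columns=cols)


def write_measurements(
    report: CoreReport, records: list[VesselRecord], path: str | Path
) -> Path:
    """Write the measurement workbook plus CSV twins.

    ``path`` is the XLSX destination; ``<stem>.csv`` (per-vessel rows) and
    ``<stem>_summary.csv`` (5 group rows + 1 average row) are written next
    to it with fixed 6-significant-digit formatting so repeated runs are
    byte-identical.
    """
    path = Path(path)
    vessels = records_frame(records)
    summary = report.per_group.copy()
    summary.loc["average"] = report.overall
    summary.insert(0, "group", summary.index)

    with pd.ExcelWriter(path, engine="openpyxl") as xl:
        vessels.to_excel(xl, sheet_name="vessels", index=False)
        summary.to_excel(xl, sheet_name="summary", index=False)
    vessels.to_csv(path.with_suffix(".csv"), index=False, float_format="%.6g")
    summary.to_csv(
        path.with_name(path.stem + "_summary.csv"), index=False, float_format="%.6g"
    )
    return path


def write_labeled_image(
    image: np.ndarray, vessels: VesselSet, path: str | Path
) -> Path:
    """Write the source image with vessel contours and indices drawn on it.

    Contours are overdrawn in green and each vessel's 1-based index is
    rendered at its centre; the file is a deterministic, losslessly
    deflate-compressed TIFF.  With zero vessels the pixels are identical to
    the input.
    """
    import tifffile
    from PIL import Image, ImageDraw

    canvas = np.ascontiguousarray(image).copy()
    if len(vessels):
        outline = np.zeros(canvas.shape[:2], dtype=bool)
        for v in vessels:
            outline |= rasterize_contour(v.contour, canvas.shape[:2])
        canvas[outline] = (0, 200, 0)
        pil = Image.fromarray(canvas)
        draw = ImageDraw.Draw(pil)
        for i, v in enumerate(vessels, start=1):
            r, c = v.center
            draw.text((c, r), str(i), fill=(255, 0, 0), anchor="mm")
        canvas = np.asarray(pil)

    path = Path(path)
    tifffile.imwrite(path, canvas, photometric="rgb", compression="deflate")
    return path
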