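"""Synthetic TMA-core renderer with exact ground truth.

Real cores contain DAB-brown endothelial rings (sometimes incomplete) around
bright lumens, on a hematoxylin counterstained background.  This module
renders idealised versions of those structures — annular membranes with a
configurable erased arc, disk lumens whose green level clears the lumen
threshold, and a counterstain-like background with seeded noise — together
with the analytic truth (area, perimeter, width/height, aspect) of every
vessel, so each pipeline stage is testable without external data.

Membrane colours are chosen in HSV space (hue ≈ 20° at a preset-specific
saturation band) and converted to RGB, so predicate membership holds by
construction; it is re-verified against the actual brown predicate at render
time.  Noise is applied to background pixels only by default, keeping the
colour predicates exact on vessel pixels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from skimage.color import hsv2rgb

from .color_segmentation import brown_mask, rgb_to_hsv8
from .core import STAIN_PRESETS

__all__ = [
    "VesselSpec",
    "CoreSpec",
    "membrane_color_for",
    "render_core",
    "preset_cores",
    "write_fixture",
]

#: Near-white lumen colour; green channel comfortably above the 236 threshold.
LUMEN_COLOR = (250, 250, 250)
#: Pale counterstain-like background; blue hue, green level far below 236.
BACKGROUND_COLOR = (185, 180, 215)

# saturation (8-bit) per intended preset: inside (T_S, next stricter T_S]
_PRESET_SATURATION = {"WS": 16, "MS": 25, "SS": 180}


def membrane_color_for(stain_preset: str = "SS") -> tuple[int, int, int]:
    """An RGB membrane colour satisfying the brown predicate at the preset.

    WS colours are detectable only at the weak-stain threshold, MS at weak
    and medium, SS at every preset.
    """
    preset = stain_preset.upper()
    s8 = _PRESET_SATURATION[preset]
    hsv = np.array([[[14 / 255.0, s8 / 255.0, 150 / 255.0]]])
    rgb = tuple(int(v) for v in np.round(hsv2rgb(hsv)[0, 0] * 255))
    _verify_membrane_color(rgb, preset)
    return rgb


def _verify_membrane_color(rgb: tuple[int, int, int], preset: str) -> None:
    pixel = np.array([[rgb]], dtype=np.uint8)
    hsv8 = rgb_to_hsv8(pixel)
    t_s = STAIN_PRESETS[preset]
    if not brown_mask(hsv8, 20, t_s)[0, 0]:
        raise AssertionError(
            f"membrane colour {rgb} fails the brown predicate at preset {preset}"
        )
    for other, t in STAIN_PRESETS.items():
        if t > t_s and brown_mask(hsv8, 20, t)[0, 0]:
            raise AssertionError(
                f"membrane colour {rgb} for preset {preset} should fail at {other}"
            )


@dataclass
class VesselSpec:
    """One rendered vessel: an annular membrane around an optional lumen disk.

    ``open_arc_fraction`` is the fraction of the annulus angularly erased
    (0 = closed); open vessels always carry a lumen.
    """

    center: tuple[int, int]  # (row, col)
    inner_radius: int
    outer_radius: int
    open_arc_fraction: float = 0.0
    has_lumen: bool = True
    gap_angle_deg: float = 90.0
    membrane_color: tuple[int, int, int] | None = None
    lumen_color: tuple[int, int, int] = LUMEN_COLOR

    def __post_init__(self) -> None:
        if not 0 < self.inner_radius < self.outer_radius:
            raise ValueError("need 0 < inner_radius < outer_radius")
        if not 0 <= self.open_arc_fraction < 1:
            raise ValueError("open_arc_fraction must be in [0, 1)")
        if self.open_arc_fraction > 0:
            self.has_lumen = True  # open vessels always present a lumen


@dataclass
class CoreSpec:
    """A full synthetic core: image size, background, vessels, noise, seed."""

    shape: tuple[int, int] = (512, 512)
    vessels: list[VesselSpec] = field(default_factory=list)
    background: tuple[int, int, int] = BACKGROUND_COLOR
    stain_preset: str = "SS"
    noise: int = 6
    noise_everywhere: bool = False
    seed: int = 0


def render_core(spec: CoreSpec) -> tuple[np.ndarray, list[dict]]:
    """Render a core spec; returns the RGB image and per-vessel ground truth.

    Ground-truth entries carry the spec plus analytic values in pixel units:
    outer area π·r_out², outer perimeter 2π·r_out, width = height = 2·r_out,
    aspect 1.  Same spec and seed give byte-identical images.
    """
    _check_disjoint(spec.vessels)
    h, w = spec.shape
    img = np.empty((h, w, 3), dtype=np.uint8)
    img[:] = spec.background
    vessel_pixels = np.zeros((h, w), dtype=bool)
    default_membrane = membrane_color_for(spec.stain_preset)

    truths = []
    for v in spec.vessels:
        color = v.membrane_color or default_membrane
        _verify_membrane_color(color, spec.stain_preset)
        _draw_vessel(img, vessel_pixels, v, color)
        truths.append(
            {
                "spec": v,
                "is_open": v.open_arc_fraction > 0,
                "area_px": np.pi * v.outer_radius**2,
                "perimeter_px": 2 * np.pi * v.outer_radius,
                "width_px": 2 * v.outer_radius,
                "height_px": 2 * v.outer_radius,
                "aspect": 1.0,
            }
        )

    if spec.noise > 0:
        rng = np.random.default_rng(spec.seed)
        noise = rng.integers(-spec.noise, spec.noise + 1, size=(h, w, 3))
        target = np.ones((h, w), dtype=bool) if spec.noise_everywhere else ~vessel_pixels
        noisy = np.clip(img.astype(int) + noise, 0, 255).astype(np.uint8)
        img[target] = noisy[target]

    if not spec.noise_everywhere:
        _verify_background(img, vessel_pixels, spec)
    return img, truths


def _check_disjoint(vessels: list[VesselSpec]) -> None:
    for i, a in enumerate(vessels):
        for b in vessels[i + 1:]:
            d = np.hypot(a.center[0] - b.center[0], a.center[1] - b.center[1])
            if d <= a.outer_radius + b.outer_radius:
                raise ValueError(
                    f"vessels at {a.center} and {b.center} overlap (distance {d:.0f})"
                )


def _draw_vessel(
    img: np.ndarray, vessel_pixels: np.ndarray, v: VesselSpec, color: tuple
) -> None:
    h, w = img.shape[:2]
    r0 = max(v.center[0] - v.outer_radius - 1, 0)
    c0 = max(v.center[1] - v.outer_radius - 1, 0)
    r1 = min(v.center[0] + v.outer_radius + 2, h)
    c1 = min(v.center[1] + v.outer_radius + 2, w)
    rr, cc = np.mgrid[r0:r1, c0:c1]
    dr = rr - v.center[0]
    dc = cc - v.center[1]
    dist = np.hypot(dr, dc)

    patch = img[r0:r1, c0:c1]
    touched = vessel_pixels[r0:r1, c0:c1]
    if v.has_lumen:
        lumen = dist < v.inner_radius
        patch[lumen] = v.lumen_color
        touched |= lumen
    ring = (dist >= v.inner_radius) & (dist <= v.outer_radius)
    if v.open_arc_fraction > 0:
        ang = np.arctan2(dr, dc)  # radians, (-pi, pi]
        gap_center = np.deg2rad(v.gap_angle_deg)
        diff = np.angle(np.exp(1j * (ang - gap_center)))
        ring &= np.abs(diff) > np.pi * v.open_arc_fraction
    patch[ring] = color
    touched |= ring


def _verify_background(img: np.ndarray, vessel_pixels: np.ndarray, spec: CoreSpec) -> None:
    bg = ~vessel_pixels
    hsv = rgb_to_hsv8(img)
    t_s = STAIN_PRESETS["WS"]  # loosest preset: strongest claim
    if (brown_mask(hsv, 20, t_s) & bg).any():
        raise AssertionError("background noise leaked into the brown predicate")
    if ((img[..., 1] >= 236) & bg).any():
        raise AssertionError("background noise leaked into the lumen predicate")


# ---------------------------------------------------------------------------
# Preset cores
# ---------------------------------------------------------------------------

def _grid_centers(shape: tuple[int, int], rows: int, cols: int) -> list[tuple[int, int]]:
    h, w = shape
    return [
        (int((i + 0.5) * h / rows), int((j + 0.5) * w / cols))
        for i in range(rows)
        for j in range(cols)
    ]


def preset_cores() -> dict[str, CoreSpec]:
    """Named fixture cores mirroring the range of real TMA content.

    ``tiny``: 2 closed vessels, 512².  ``mixed``: 20 closed + 10 open large
    vessels, 2048².  ``weak_stain``/``strong_stain``: stain-preset bands.
    ``dense``: 200 vessels on 4096² (slow; not used by default tests).
    """
    presets: dict[str, CoreSpec] = {}

    presets["tiny"] = CoreSpec(
        shape=(512, 512),
        vessels=[
            VesselSpec((160, 160), 22, 32),
            VesselSpec((340, 340), 40, 52, has_lumen=False),
        ],
        seed=7,
    )

    mixed_centers = _grid_centers((2048, 2048), 5, 6)
    sizes = [(26, 36), (30, 42), (36, 48), (40, 52), (46, 60)]
    vessels = []
    for k, center in enumerate(mixed_centers):
        inner, outer = sizes[k % len(sizes)]
        if k < 20:  # closed; alternate lumen presence
            vessels.append(
                VesselSpec(center, inner, outer, has_lumen=(k % 2 == 0))
            )
        else:  # open, large lumens, 70% membrane arc present
            vessels.append(
                VesselSpec(
                    center,
                    inner,
                    outer,
                    open_arc_fraction=0.30,
                    gap_angle_deg=45.0 * (k - 20),
                )
            )
    presets["mixed"] = CoreSpec(shape=(2048, 2048), vessels=vessels, seed=11)

    for name, preset in (("weak_stain", "WS"), ("strong_stain", "SS")):
        presets[name] = CoreSpec(
            shape=(512, 512),
            vessels=[
                VesselSpec((170, 170), 24, 34),
                VesselSpec((350, 350), 30, 42),
            ],
            stain_preset=preset,
            seed=13,
        )

    dense_centers = _grid_centers((4096, 4096), 14, 15)[:200]
    presets["dense"] = CoreSpec(
        shape=(4096, 4096),
        vessels=[
            VesselSpec(c, 24 + (i % 5) * 4, 34 + (i % 5) * 5)
            for i, c in enumerate(dense_centers)
        ],
        seed=17,
    )
    return presets


def write_fixture(name: str, out_dir: str | Path) -> tuple[Path, Path]:
    """Render a preset core to ``<name>.png`` plus a ground-truth JSON sidecar."""
    import imageio.v3 as iio

    spec = preset_cores()[name]
    image, truths = render_core(spec)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    img_path = out_dir / f"{name}.png"
    iio.imwrite(img_path, image)
    payload = []
    for t in truths:
        v: VesselSpec = t["spec"]
        payload.append(
            {
                "center": list(v.center),
                "inner_radius": v.inner_radius,
                "outer_radius": v.outer_radius,
                "open_arc_fraction": v.open_arc_fraction,
                "is_open": t["is_open"],
                "area_px": t["area_px"],
                "perimeter_px": t["perimeter_px"],
                "width_px": t["width_px"],
                "height_px": t["height_px"],
                "aspect": t["aspect"],
            }
        )
    json_path = out_dir / f"{name}_truth.json"
    json_path.write_text(json.dumps(payload, indent=1))
    return img_path, json_path
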