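# Methods

`angiopath` quantifies blood and lymphatic microvessels in brightfield
images of immunohistochemically stained tissue-microarray (TMA) cores.
Endothelial markers (CD34 for blood vessels, D2-40 for lymphatics) are
rendered brown by the DAB chromogen; the counterstain is blue/pink.  Two
vessel populations exist in such material: *closed* vessels whose stained
membrane forms a complete ring, and *open* vessels whose staining is
interrupted but which always enclose a bright lumen.  The pipeline detects
both, fuses them into one vessel set, and reports per-vessel and per-core
morphometry.

## Pipeline

**Colour branch (closed vessels).**  The RGB image is converted to HSV with
all channels on an 8-bit scale (hue 360° → 255).  A pixel is called
membrane when `H <= T_H` and `S > T_S`; this is algebraically identical to
the four-step chain of a binary threshold on H, an inverted threshold on S,
a pixelwise OR and a NOT, and both formulations are implemented and tested
for pixelwise equality.  `T_H` defaults to 20 (hue below ≈28°, the DAB
band).  `T_S` encodes stain intensity: 10 for weak, 20 for medium, 30 for
strong stains; weaker stains are less saturated, so a looser threshold is
needed to see them.  The mask is refined by 2 erosions and 4 dilations with
a 3×3 square kernel — erosions remove sub-resolution specks, dilations
re-join fragmented membrane — then outer borders are extracted by
Moore-neighbour border following (ordered, 8-connected, one outer contour
per component; holes are not separate vessels).  Contours with fewer than 6
boundary points (1.38 μm at default calibration) or with bounding boxes
below 20 px (4.6 μm) in *both* dimensions are discarded as artifacts; thin
elongated fragments survive.

**Radial branch (open vessels).**  Candidate lumens are green-channel
pixels at gray level ≥ 236 (a value separating lumen glare from tissue in
these preparations).  The mask is refined by erosion ×3 and dilation ×2,
internal holes under 400 px² are filled, and one further erosion opens a
2 px gap between lumen and membrane.  Each lumen border point then probes
outward along its normal — perpendicular to the chord between its ±2
neighbours, oriented away from the contour centroid — for up to
`round(3 μm / um_per_px)` pixels (13 px at 0.23 μm/px), against the
membrane mask dilated ×2 (bridging the gap the final lumen erosion
created).  The fraction of border points that find membrane (*hit ratio*)
must reach 60% / 50% / 40% for small / medium / large lumens, where size is
the lumen contour length: small < 12.42 μm, medium 12.42–31.05 μm
(closed interval), large beyond.  Smaller vessels need the stricter ratio
because discrete dilation spreads membrane arc-ends azimuthally by an angle
inversely proportional to the radius, inflating hit ratios at small scales.
Accepted vessels are closed by connecting the membrane hit locations in
contour order; runs of misses are bridged by the straight segment between
the flanking hits (linear interpolation).  The closed polygons are filled,
re-traced and artifact-filtered like the colour branch.

**Fusion.**  Both branches' contours are rasterised onto one canvas, the
union re-traced, and artifacts filtered; outlines that touch or cross merge
naturally.  Remaining duplicates — e.g. the concentric outer ring and inner
closure of one vessel — are collapsed explicitly: vessels are kept in
decreasing area order, and a candidate sharing more than half its interior
with already-kept vessels is dropped.  Provenance is `closed_branch` when
the interior overlaps the colour-branch detections by more than half.
Manual mode removes vessels nearest to user-supplied centre points
(non-interactive: points come from a file, keeping the library headless).

**Morphometry.**  Twelve measurements per vessel: centre (exported as
(x, y) = (col, row)); area by the shoelace formula (μm²); width/height from
the axis-aligned bounding box (μm); perimeter as the sum of Euclidean
inter-point distances (μm); orientation angle of the best-fit-ellipse major
axis versus the horizontal, y-up, in (−π/2, π/2]; aspect = major/minor
axis from second-order central moments of the filled region; roundness
P²/(4πA); perimeter ratio = convex-hull perimeter / perimeter; deformity =
hull area − area; shape = max over the first two Hu invariants of
|mᵢᴬ − mᵢᴮ| / |mᵢᴬ| with mᵢ = sign(hᵢ)·log|hᵢ|, comparing the region (A)
with its filled convex hull (B); and the Douglas–Peucker vertex count.
Vascular density is vessels per μm² of core area.

**Reporting.**  Vessels are binned by height into [5, 15), [15, 20),
[20, 50), [50, 200) and ≥ 200 μm (heights under 5 μm fold into the first
bin — the artifact filter admits objects from 4.6 μm).  Per group: the mean
of each measurement, the totals, the percent of vessel area and the count;
plus an overall average row — 24 summary quantities.  Outputs are an XLSX
workbook, fixed-format CSV twins (byte-stable across runs, the diffable
testing surface), and a losslessly compressed labeled TIFF.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `um_per_px` | 0.23 | physical scale (Aperio ScanScope T2 at 40x); required everywhere physical units appear, overridable for other scanners |
| `T_H` | 20 | hue threshold of the brown predicate, 8-bit scale |
| `T_S` | 10/20/30 | saturation threshold per stain preset (WS/MS/SS) |
| `lumen_threshold` | 236 | green level at and above which a pixel is lumen |
| `probe_radius_um` | 3 | how far each lumen border point searches for membrane |
| `min/max_stained_fraction` | 0.1/0.9 | optional clamp on the per-size-class required hit ratio |
| `dp_epsilon_px` | 2 | Douglas–Peucker tolerance for the vertex count (the measurement needs *a* fixed tolerance; 2 px suppresses staircase steps without erasing real corners) |
| `hu_indices` | (1, 2) | Hu invariants entering the shape measure; widen to 1..7 to compare all seven |

## Numerical choices and conventions

- Coordinates are 0-based (row, col), origin top-left; bounding boxes are
  half-open.  Exported (x, y) is (col, row).
- The structuring element for every morphological step is the 3×3 square
  (8-connectivity).
- Border following uses Moore-neighbour tracing with Jacob's stopping
  criterion, started at the topmost-leftmost pixel of each component; the
  walk is a deterministic map on (pixel, backtrack) states and is cut at
  the first repeated state.
- Contour "length" in the artifact filter is the number of boundary points;
  perimeter elsewhere is Euclidean (diagonal steps count √2).
- The outward normal uses a ±2-point chord; for degenerate chords the
  radial direction from the centroid substitutes.  Orientation against the
  centroid assumes star-shaped lumens, which is what the method targets.
- Hu moments are computed on filled regions (not point sequences), and
  mᵢ uses log|hᵢ| since Hu invariants can be negative; vanishing invariants
  are skipped and logged.
- Deformity is reported in μm²: it is an area difference.
- The Douglas–Peucker ring is rotated to start at the point farthest from
  the centroid before simplification so the split chord never cuts a
  corner, making the vertex count independent of where the trace started.
- Degenerate inputs raise: collinear contours (zero area), ellipse fits on
  < 5 points, non-positive calibrations, thresholds outside [0, 255].

## Digitization properties worth knowing

- Perimeters of Moore-traced digital circles overestimate the true circle
  perimeter by a roughly constant ≈5% (staircase effect), so the roundness
  of an ideal circle plateaus near 1.10 at every radius rather than
  converging to 1.  Roundness is therefore comparable between vessels but
  carries this small positive bias in absolute terms.
- The straight interpolation chord that closes an open vessel can undercut
  the raw lumen disk by a few percent across the gap; the closed contour
  always encloses the refined (eroded) lumen the probe walks from.
- Morphological refinement grows closed-vessel contours by a net ≈2 px per
  side, inflating measured areas of small vessels by several percent.

## What the synthetic fixtures emulate — and what they do not

The fixture generator renders idealised cores: annular membranes (with a
configurable erased arc for open vessels) in colours constructed in HSV
space to satisfy the brown predicate at an intended stain preset and fail
at stricter ones (verified at render time), disk lumens above the lumen
threshold, and a counterstain-like background with seeded uniform noise
that is clipped away from both colour predicates.  Noise is restricted to
the background by default so predicate tests stay exact; a flag extends it
everywhere.  Preset cores span 2 vessels (`tiny`, 512²) through 20 closed +
10 open (`mixed`, 2048²) to 200 vessels (`dense`, 4096²); the default test
suite uses `tiny` and `mixed`, sizes chosen so the whole suite runs in well
under a minute of pipeline time per core.

Fixtures do **not** emulate: nuclei and tissue texture, stain gradients
along a membrane, touching/overlapping vessels, scanner compression
artifacts, or out-of-focus regions.  Passing fixture tests therefore
demonstrates the correctness of the algorithmic chain under its own
assumptions, not clinical-grade accuracy on real slides; colour thresholds
especially will need per-laboratory presets on real material.

## Known limitations

- Vessels whose closure polygon spans under 20 px in both dimensions are
  removed by the artifact filter, so open vessels of the smallest size
  class are effectively reportable only above ≈4.6 μm extents.
- Radial probing assumes star-shaped lumens; strongly folded lumens can
  mis-orient normals.
- No stain normalisation or colour deconvolution: strongly atypical
  staining requires custom `T_H`/`T_S`.
- Nested distinct vessels (one truly inside another) collapse to the outer
  vessel during fusion.
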