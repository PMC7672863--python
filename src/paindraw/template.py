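"""Body-outline drawing sheet: geometry, named anatomical regions, rendering.

The sheet mimics the paper form handed to patients: four body views
(anterior, posterior, two laterals), magnified panels for the hands, the
feet and the head, and four solid black calibration bars near the canvas
corners used downstream to undo scanner shift and rotation.

Coordinate convention (used package-wide): 0-based, row-major, origin at
the top-left corner, pixel centers at integer coordinates.  Polygons are
arrays of (row, col) vertices.  All geometry is defined in normalized
canvas fractions and scaled to pixels, so overriding the canvas size
rescales every feature proportionally.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml
from shapely.geometry import Polygon as _ShapelyPolygon
from shapely.geometry import box as _shapely_box
from skimage.draw import polygon as _draw_polygon
from skimage.morphology import disk, erosion

__all__ = [
    "REGION_NAMES",
    "TemplateSpec",
    "TemplateError",
    "build_default_template",
    "render_blank_sheet",
    "region_mask",
    "body_mask",
]


class TemplateError(ValueError):
    """Invalid template configuration (bad dimensions, overlapping bars...)."""


#: Controlled vocabulary of named anatomical regions (lowercase snake case).
REGION_NAMES: tuple[str, ...] = (
    "spine_with_neck",
    "tailbone",
    "knee_front",
    "knee_back",
    "shoulder",
    "elbow",
    "thumb_saddle_joint",
    "umbilical",
    "groin",
    "ankle",
    "hand_finger_joints",
    "metatarsophalangeal",
    "heel",
    "foot_dorsal",
    "foot_plantar",
    "fingertips_palmar",
    "palm_dorsal_left",
    "palm_dorsal_right",
    "lower_leg",
)

# ---------------------------------------------------------------------------
# Normalized geometry (fractions of canvas; x = col / width, y = row / height)
# ---------------------------------------------------------------------------

# Calibration bars: (x0, y0, x1, y1).  Placed far enough from the canvas
# edges that the supported shift/rotation budget cannot push a bar off the
# page, and far enough from printed content that a generous detection
# window around each bar sees nothing but the bar.
_BAR_FRACS = (
    (0.055, 0.038, 0.150, 0.054),
    (0.850, 0.038, 0.945, 0.054),
    (0.055, 0.946, 0.150, 0.962),
    (0.850, 0.946, 0.945, 0.962),
)

# Vertical band holding printed content (body views and panels).
_CONTENT_Y0, _CONTENT_Y1 = 0.105, 0.895

# Body-view boxes (x0, x1) within the upper content band.
_VIEW_Y0, _VIEW_Y1 = 0.105, 0.615
_VIEW_BOXES = {
    "anterior": (0.02, 0.24),
    "posterior": (0.26, 0.48),
    "lateral_left": (0.52, 0.70),
    "lateral_right": (0.74, 0.92),
}

# Frontal humanoid silhouette in view-box units (u across, v down); right
# half listed, mirrored for the left half.
_SILHOUETTE_RIGHT = [
    (0.500, 0.020), (0.580, 0.045), (0.615, 0.100), (0.585, 0.155),
    (0.560, 0.175), (0.620, 0.195), (0.760, 0.225), (0.815, 0.500),
    (0.790, 0.545), (0.720, 0.535), (0.660, 0.270), (0.655, 0.420),
    (0.650, 0.500), (0.675, 0.545), (0.660, 0.930), (0.705, 0.960),
    (0.700, 0.985), (0.550, 0.985), (0.545, 0.945), (0.512, 0.630),
    (0.500, 0.615),
]

# Side-profile slab used for the two lateral views (no named regions).
_SILHOUETTE_LATERAL = [
    (0.45, 0.020), (0.56, 0.030), (0.58, 0.100), (0.54, 0.170),
    (0.60, 0.220), (0.63, 0.500), (0.58, 0.620), (0.61, 0.930),
    (0.64, 0.985), (0.46, 0.985), (0.48, 0.600), (0.44, 0.400),
    (0.43, 0.200), (0.46, 0.120),
]

# Magnified panels in the lower content band: (x0, y0, x1, y1).
_PANEL_BOXES = {
    "hand_palmar_left": (0.020, 0.660, 0.110, 0.840),
    "hand_palmar_right": (0.120, 0.660, 0.210, 0.840),
    "hand_dorsal_left": (0.220, 0.660, 0.310, 0.840),
    "hand_dorsal_right": (0.320, 0.660, 0.410, 0.840),
    "foot_dorsal_panel": (0.460, 0.660, 0.570, 0.880),
    "foot_plantar_panel": (0.600, 0.660, 0.710, 0.880),
    "head_panel": (0.780, 0.660, 0.900, 0.820),
}

# Octagonal outline (corner-cut oblong) in unit-box coordinates for panels.
_OCTAGON = [
    (0.25, 0.00), (0.75, 0.00), (1.00, 0.12), (1.00, 0.88),
    (0.75, 1.00), (0.25, 1.00), (0.00, 0.88), (0.00, 0.12),
]

# Region shapes in the coordinate frame of their view or panel: either a
# rectangle (u0, v0, u1, v1) or an explicit list of (u, v) vertices (used
# where a slanted limb needs a slanted patch).  Frontal views use view-box
# units; panels use panel-box units.  All patches keep several pixels of
# clearance from the printed outlines at the default canvas so that
# template subtraction does not eat into marked areas.
_ELBOW_RIGHT = [(0.722, 0.360), (0.752, 0.360), (0.764, 0.420), (0.734, 0.420)]
_ELBOW_LEFT = [(1.0 - u, v) for u, v in _ELBOW_RIGHT]

_REGION_LAYOUT: dict[str, list[tuple[str, object]]] = {
    "spine_with_neck": [("posterior", (0.478, 0.055, 0.522, 0.545))],
    "tailbone": [("posterior", (0.46, 0.555, 0.54, 0.600))],
    "knee_front": [("anterior", (0.565, 0.760, 0.630, 0.815)),
                   ("anterior", (0.370, 0.760, 0.435, 0.815))],
    "knee_back": [("posterior", (0.565, 0.760, 0.630, 0.815)),
                  ("posterior", (0.370, 0.760, 0.435, 0.815))],
    "shoulder": [("anterior", (0.630, 0.235, 0.700, 0.263)),
                 ("anterior", (0.300, 0.235, 0.370, 0.263))],
    "elbow": [("anterior", _ELBOW_RIGHT), ("anterior", _ELBOW_LEFT)],
    "umbilical": [("anterior", (0.47, 0.430, 0.53, 0.480))],
    "groin": [("anterior", (0.44, 0.550, 0.56, 0.600))],
    "ankle": [("anterior", (0.582, 0.915, 0.624, 0.940)),
              ("anterior", (0.376, 0.915, 0.418, 0.940))],
    "lower_leg": [("posterior", (0.578, 0.835, 0.625, 0.900)),
                  ("posterior", (0.375, 0.835, 0.422, 0.900))],
    "fingertips_palmar": [("hand_palmar_left", (0.18, 0.10, 0.82, 0.22)),
                          ("hand_palmar_right", (0.18, 0.10, 0.82, 0.22))],
    "thumb_saddle_joint": [("hand_palmar_left", (0.12, 0.62, 0.38, 0.82)),
                           ("hand_palmar_right", (0.62, 0.62, 0.88, 0.82))],
    "hand_finger_joints": [("hand_dorsal_left", (0.15, 0.26, 0.85, 0.40)),
                           ("hand_dorsal_right", (0.15, 0.26, 0.85, 0.40))],
    "palm_dorsal_left": [("hand_dorsal_left", (0.15, 0.48, 0.85, 0.80))],
    "palm_dorsal_right": [("hand_dorsal_right", (0.15, 0.48, 0.85, 0.80))],
    "foot_dorsal": [("foot_dorsal_panel", (0.15, 0.15, 0.85, 0.85))],
    "metatarsophalangeal": [("foot_plantar_panel", (0.15, 0.14, 0.85, 0.28))],
    "foot_plantar": [("foot_plantar_panel", (0.15, 0.34, 0.85, 0.68))],
    "heel": [("foot_plantar_panel", (0.20, 0.74, 0.80, 0.86))],
}

DEFAULT_CANVAS_HEIGHT = 1200
DEFAULT_CANVAS_WIDTH = 900
DEFAULT_LINE_WIDTH = 2


@dataclass(frozen=True)
class TemplateSpec:
    """Complete geometry of the drawing sheet on a fixed pixel canvas.

    bar_boxes are axis-aligned (row0, col0, row1, col1) rectangles with
    exclusive upper bounds; polygons are (n, 2) arrays of (row, col)
    vertices; region_table maps region names to lists of polygons (one
    region may span several views).
    """

    canvas_height: int
    canvas_width: int
    bar_boxes: tuple[tuple[int, int, int, int], ...]
    body_polygons: tuple[np.ndarray, ...]
    region_table: dict[str, tuple[np.ndarray, ...]] = field(repr=False)
    line_width: int = DEFAULT_LINE_WIDTH

    @property
    def shape(self) -> tuple[int, int]:
        return (self.canvas_height, self.canvas_width)

    @property
    def bar_centers(self) -> np.ndarray:
        """(n_bars, 2) array of bar-center (row, col) coordinates.

        Pixel-center convention: the centroid of the pixel indices covered
        by the (exclusive-upper-bound) box, matching what a center-of-mass
        bar detector reports on an undistorted render.
        """
        return np.array(
            [((r0 + r1 - 1) / 2.0, (c0 + c1 - 1) / 2.0)
             for r0, c0, r1, c1 in self.bar_boxes]
        )

    def validate(self) -> None:
        """Check the structural invariants; raise TemplateError on violation."""
        if self.canvas_height <= 0 or self.canvas_width <= 0:
            raise TemplateError("canvas dimensions must be positive")
        if self.line_width <= 0:
            raise TemplateError("line_width must be positive")
        bars = [
            _shapely_box(c0, r0, c1, r1) for r0, c0, r1, c1 in self.bar_boxes
        ]
        for i in range(len(bars)):
            for j in range(i + 1, len(bars)):
                if bars[i].intersects(bars[j]):
                    raise TemplateError(f"calibration bars {i} and {j} overlap")
        bodies = [
            _ShapelyPolygon([(c, r) for r, c in poly]) for poly in self.body_polygons
        ]
        for i, bar in enumerate(bars):
            for body in bodies:
                if bar.intersects(body):
                    raise TemplateError(f"bar {i} intersects a body outline")
        for name, polys in self.region_table.items():
            if name not in REGION_NAMES:
                raise TemplateError(f"unknown region name: {name!r}")
            for poly in polys:
                region = _ShapelyPolygon([(c, r) for r, c in poly])
                if not any(body.contains(region) for body in bodies):
                    raise TemplateError(
                        f"region {name!r} polygon not inside any body outline"
                    )

    # -- serialization ------------------------------------------------------

    def to_yaml(self, path) -> None:
        doc = {
            "canvas_height": int(self.canvas_height),
            "canvas_width": int(self.canvas_width),
            "line_width": int(self.line_width),
            "bar_boxes": [list(map(int, b)) for b in self.bar_boxes],
            "body_polygons": [poly.tolist() for poly in self.body_polygons],
            "region_table": {
                name: [poly.tolist() for poly in polys]
                for name, polys in self.region_table.items()
            },
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "TemplateSpec":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        spec = cls(
            canvas_height=doc["canvas_height"],
            canvas_width=doc["canvas_width"],
            line_width=doc["line_width"],
            bar_boxes=tuple(tuple(b) for b in doc["bar_boxes"]),
            body_polygons=tuple(
                np.asarray(p, dtype=float) for p in doc["body_polygons"]
            ),
            region_table={
                name: tuple(np.asarray(p, dtype=float) for p in polys)
                for name, polys in doc["region_table"].items()
            },
        )
        spec.validate()
        return spec


# ---------------------------------------------------------------------------
# Construction
# ---------------------------------------------------------------------------

def _mirror(points):
    return [(1.0 - u, v) for u, v in points]


def _frontal_silhouette():
    right = list(_SILHOUETTE_RIGHT)
    left = _mirror(list(reversed(_SILHOUETTE_RIGHT)))
    # drop duplicated symmetric endpoints at u = 0.5
    return right + left[1:-1]


def _scale_view(points, box_x, height, width):
    """Map view-box (u, v) points to canvas (row, col) pixels."""
    x0, x1 = box_x
    rows = [(_VIEW_Y0 + v * (_VIEW_Y1 - _VIEW_Y0)) * height for _, v in points]
    cols = [(x0 + u * (x1 - x0)) * width for u, _ in points]
    return np.column_stack([rows, cols])


def _scale_panel(points, panel_box, height, width):
    x0, y0, x1, y1 = panel_box
    rows = [(y0 + v * (y1 - y0)) * height for _, v in points]
    cols = [(x0 + u * (x1 - x0)) * width for u, _ in points]
    return np.column_stack([rows, cols])


def _rect(u0, v0, u1, v1):
    return [(u0, v0), (u1, v0), (u1, v1), (u0, v1)]


def build_default_template(
    canvas_height: int = DEFAULT_CANVAS_HEIGHT,
    canvas_width: int = DEFAULT_CANVAS_WIDTH,
    line_width: int = DEFAULT_LINE_WIDTH,
) -> TemplateSpec:
    """Construct the default drawing sheet.

    Deterministic: two calls return identical specs.  Overriding the canvas
    size rescales all features proportionally (geometry is stored in canvas
    fractions), so invariants hold at any resolution where features remain
    at least a few pixels wide.
    """
    h, w = int(canvas_height), int(canvas_width)
    if h <= 0 or w <= 0:
        raise TemplateError("canvas dimensions must be positive")

    bar_boxes = tuple(
        (round(y0 * h), round(x0 * w), round(y1 * h), round(x1 * w))
        for x0, y0, x1, y1 in _BAR_FRACS
    )

    frontal = _frontal_silhouette()
    body_polygons = [
        _scale_view(frontal, _VIEW_BOXES["anterior"], h, w),
        _scale_view(frontal, _VIEW_BOXES["posterior"], h, w),
        _scale_view(_SILHOUETTE_LATERAL, _VIEW_BOXES["lateral_left"], h, w),
        _scale_view(_mirror(list(reversed(_SILHOUETTE_LATERAL))),
                    _VIEW_BOXES["lateral_right"], h, w),
    ]
    for panel_box in _PANEL_BOXES.values():
        body_polygons.append(_scale_panel(_OCTAGON, panel_box, h, w))

    region_table: dict[str, tuple[np.ndarray, ...]] = {}
    for name, placements in _REGION_LAYOUT.items():
        polys = []
        for frame, shape in placements:
            if isinstance(shape, tuple):
                corners = _rect(*shape)
            else:
                corners = list(shape)
            if frame in _VIEW_BOXES:
                polys.append(_scale_view(corners, _VIEW_BOXES[frame], h, w))
            else:
                polys.append(_scale_panel(corners, _PANEL_BOXES[frame], h, w))
        region_table[name] = tuple(polys)

    spec = TemplateSpec(
        canvas_height=h,
        canvas_width=w,
        bar_boxes=bar_boxes,
        body_polygons=tuple(body_polygons),
        region_table=region_table,
        line_width=int(line_width),
    )
    spec.validate()
    return spec


# ---------------------------------------------------------------------------
# Rasterization
# ---------------------------------------------------------------------------

def _fill_polygon(mask: np.ndarray, poly: np.ndarray) -> None:
    rr, cc = _draw_polygon(poly[:, 0], poly[:, 1], shape=mask.shape)
    mask[rr, cc] = True


def render_blank_sheet(spec: TemplateSpec) -> np.ndarray:
    """Render the unmarked sheet as a uint8 grayscale image (white 255).

    Body outlines are drawn as the inner boundary band of each silhouette,
    line_width pixels thick; calibration bars are solid black.
    """
    ink = np.zeros(spec.shape, dtype=bool)
    footprint = disk(spec.line_width)
    for poly in spec.body_polygons:
        filled = np.zeros(spec.shape, dtype=bool)
        _fill_polygon(filled, poly)
        ink |= filled & ~erosion(filled, footprint)
    for r0, c0, r1, c1 in spec.bar_boxes:
        ink[r0:r1, c0:c1] = True
    img = np.full(spec.shape, 255, dtype=np.uint8)
    img[ink] = 0
    return img


def region_mask(spec: TemplateSpec, region: str) -> np.ndarray:
    """Binary mask (canvas-sized, bool) of a named anatomical region."""
    if region not in spec.region_table:
        raise KeyError(f"unknown region: {region!r}")
    mask = np.zeros(spec.shape, dtype=bool)
    for poly in spec.region_table[region]:
        _fill_polygon(mask, poly)
    return mask


def body_mask(spec: TemplateSpec) -> np.ndarray:
    """Union of all filled body-outline polygons (bool)."""
    mask = np.zeros(spec.shape, dtype=bool)
    for poly in spec.body_polygons:
        _fill_polygon(mask, poly)
    return mask
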