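"""Color reference board: specification, rendering and digitization.

The board is a printed card carrying four corner fiducial markers, reference
color stripes along its sides, and a central sample region that hosts the
object being measured (a test strip, a colorimetric assay well, ...).  The
stripes regularly sample the HSV color model so that a color correction fitted
on them generalizes over the whole visible gamut:

* an H stripe varies hue over [0, 1] at S = V = 1,
* an S stripe varies saturation over [0, 1] at V = 1 and fixed hue,
* a V stripe varies value over [0, 1] at S = 1 and fixed hue.

Four stripe layouts are provided.  Pattern ``A`` (the default board) carries
all three families: hue stripes at top and bottom, a saturation stripe on the
left and a value stripe on the right.  Patterns ``B``–``D`` are reduced
variants used to study how much each HSV component contributes to correction
quality; ``D`` carries no hue-varying stripe at all.

World coordinates are millimetres with the origin at the bottom-left board
corner, x to the right, y up, z out of the board (right-hand rule).  Raster
coordinates are pixels, origin top-left, x right, y down; pixel ``(row, col)``
is centred on world point ``((col + 0.5)/ppm, H_mm - (row + 0.5)/ppm)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from skimage.color import hsv2rgb

from . import markers as _markers

PATTERNS = ("A", "B", "C", "D")

# stripe family per side for each pattern (None = no stripe on that side)
_PATTERN_SIDES: dict[str, dict[str, str | None]] = {
    "A": {"top": "H", "bottom": "H", "left": "S", "right": "V"},
    "B": {"top": "H", "bottom": "H", "left": "V", "right": "V"},
    "C": {"top": "H", "bottom": "H", "left": "S", "right": "S"},
    "D": {"top": "S", "bottom": "V", "left": "S", "right": "V"},
}

_FIXED_HUE = 0.0  # hue used by S- and V-varying stripes


@dataclass(frozen=True)
class StripeSpec:
    """One reference color stripe.

    ``rect_mm`` is ``(x0, y0, width, height)`` in world mm.  The varying HSV
    component is sampled regularly on [0, 1] over ``swatch_count`` swatches
    laid out along the stripe's long axis — left to right for horizontal
    stripes, bottom to top for vertical ones.
    """
    side: str                      # top | bottom | left | right
    varying_component: str         # H | S | V
    fixed_components: dict[str, float]
    swatch_count: int
    rect_mm: tuple[float, float, float, float]

    def __post_init__(self) -> None:
        if self.side not in ("top", "bottom", "left", "right"):
            raise ValueError(f"bad side {self.side!r}")
        if self.varying_component not in "HSV":
            raise ValueError(f"bad component {self.varying_component!r}")
        if set(self.fixed_components) != set("HSV") - {self.varying_component}:
            raise ValueError("fixed_components must name the other two of HSV")
        if not all(0.0 <= v <= 1.0 for v in self.fixed_components.values()):
            raise ValueError("fixed components must lie in [0, 1]")
        if self.swatch_count < 2:
            raise ValueError("need at least 2 swatches")

    @property
    def horizontal(self) -> bool:
        return self.side in ("top", "bottom")

    def swatch_hsv(self) -> np.ndarray:
        """(swatch_count, 3) HSV triples, varying component = k/(n-1)."""
        n = self.swatch_count
        vals = np.arange(n) / (n - 1)
        out = np.empty((n, 3))
        for j, comp in enumerate("HSV"):
            if comp == self.varying_component:
                out[:, j] = vals
            else:
                out[:, j] = self.fixed_components[comp]
        return out

    def swatch_rgb(self) -> np.ndarray:
        """(swatch_count, 3) uint8 swatch colors (hexcone HSV -> sRGB)."""
        rgb = hsv2rgb(self.swatch_hsv()[None])[0]
        return np.floor(rgb * 255.0 + 0.5).astype(np.uint8)  # round half up


@dataclass(frozen=True)
class MarkerPlacement:
    """A fiducial marker: id plus its 4 corner world points (mm, z = 0).

    Corner order matches the detector's canonical order: top-left, top-right,
    bottom-right, bottom-left of the upright marker as seen on the printed
    board (y up, so "top" is larger y).
    """
    marker_id: int
    corners_mm: np.ndarray  # (4, 2)


@dataclass
class BoardSpec:
    """Full geometric and colorimetric description of a reference board."""
    pattern: str
    board_width_mm: float = 100.0
    board_height_mm: float = 70.0
    px_per_mm: float = 5.0
    marker_size_mm: float = 10.0
    marker_margin_mm: float = 2.0
    stripe_thickness_mm: float = 6.0
    swatch_count: int = 24
    marker_dictionary: str = _markers.DICT_NAME
    markers: list[MarkerPlacement] = field(default_factory=list)
    stripes: list[StripeSpec] = field(default_factory=list)
    sample_region_mm: tuple[float, float, float, float] = (0, 0, 0, 0)

    # ------------------------------------------------------------------ geometry
    @property
    def raster_shape(self) -> tuple[int, int]:
        """(rows, cols) of the board raster."""
        return (int(round(self.board_height_mm * self.px_per_mm)),
                int(round(self.board_width_mm * self.px_per_mm)))

    def world_to_raster(self, pts_mm: np.ndarray) -> np.ndarray:
        """World (x, y) mm -> continuous raster (x, y) px."""
        pts = np.atleast_2d(np.asarray(pts_mm, dtype=float))
        out = np.empty_like(pts[:, :2])
        out[:, 0] = pts[:, 0] * self.px_per_mm - 0.5
        out[:, 1] = (self.board_height_mm - pts[:, 1]) * self.px_per_mm - 0.5
        return out

    def raster_to_world(self, pts_px: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts_px, dtype=float))
        out = np.empty_like(pts[:, :2])
        out[:, 0] = (pts[:, 0] + 0.5) / self.px_per_mm
        out[:, 1] = self.board_height_mm - (pts[:, 1] + 0.5) / self.px_per_mm
        return out

    def rect_to_slices(self, rect_mm) -> tuple[slice, slice]:
        """Pixel-index slices (rows, cols) covered by a world-mm rect."""
        x0, y0, w, h = rect_mm
        ppm = self.px_per_mm
        c0 = int(np.ceil(x0 * ppm - 0.5))
        c1 = int(np.ceil((x0 + w) * ppm - 0.5))
        r0 = int(np.ceil((self.board_height_mm - y0 - h) * ppm - 0.5))
        r1 = int(np.ceil((self.board_height_mm - y0) * ppm - 0.5))
        return slice(r0, r1), slice(c0, c1)

    def keypoint_world(self) -> dict[tuple[int, int], np.ndarray]:
        """(marker_id, corner_index) -> world (x, y) mm for all 16 corners."""
        return {(m.marker_id, k): m.corners_mm[k]
                for m in self.markers for k in range(4)}

    # ------------------------------------------------------------------ io
    def to_dict(self) -> dict:
        return {
            "pattern": self.pattern,
            "board_width_mm": self.board_width_mm,
            "board_height_mm": self.board_height_mm,
            "px_per_mm": self.px_per_mm,
            "marker_size_mm": self.marker_size_mm,
            "marker_margin_mm": self.marker_margin_mm,
            "stripe_thickness_mm": self.stripe_thickness_mm,
            "swatch_count": self.swatch_count,
            "marker_dictionary": self.marker_dictionary,
            "markers": [{"id": m.marker_id,
                         "corners_mm": np.asarray(m.corners_mm).tolist()}
                        for m in self.markers],
            "stripes": [{"side": s.side,
                         "varying_component": s.varying_component,
                         "fixed_components": s.fixed_components,
                         "swatch_count": s.swatch_count,
                         "rect_mm": list(s.rect_mm)} for s in self.stripes],
            "sample_region_mm": list(self.sample_region_mm),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BoardSpec":
        return cls(
            pattern=d["pattern"],
            board_width_mm=d["board_width_mm"],
            board_height_mm=d["board_height_mm"],
            px_per_mm=d["px_per_mm"],
            marker_size_mm=d["marker_size_mm"],
            marker_margin_mm=d["marker_margin_mm"],
            stripe_thickness_mm=d["stripe_thickness_mm"],
            swatch_count=d["swatch_count"],
            marker_dictionary=d["marker_dictionary"],
            markers=[MarkerPlacement(m["id"], np.asarray(m["corners_mm"]))
                     for m in d["markers"]],
            stripes=[StripeSpec(s["side"], s["varying_component"],
                                dict(s["fixed_components"]), s["swatch_count"],
                                tuple(s["rect_mm"])) for s in d["stripes"]],
            sample_region_mm=tuple(d["sample_region_mm"]),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def load(cls, path) -> "BoardSpec":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class ReferenceColorMap:
    """Reference RGB for every stripe pixel of the rectified board raster.

    ``image`` holds the reference colors on stripe pixels (zero elsewhere) and
    ``mask`` marks those pixels.  ``provenance`` records whether the colors
    are the theoretical render values or were digitized from a scan of the
    physically printed board — the printed colors routinely differ from the
    source file, and corrections must target what was actually printed.
    """
    image: np.ndarray      # (H, W, 3) uint8
    mask: np.ndarray       # (H, W) bool
    provenance: str        # "theoretical" | "digitized"

    def color_at(self, x: int, y: int) -> np.ndarray:
        if not self.mask[y, x]:
            raise KeyError(f"({x}, {y}) is not a stripe pixel")
        return self.image[y, x]

    def to_dict(self) -> dict:
        rows, cols = np.nonzero(self.mask)
        r0, r1 = int(rows.min()), int(rows.max()) + 1
        c0, c1 = int(cols.min()), int(cols.max()) + 1
        return {"provenance": self.provenance,
                "shape": list(self.mask.shape),
                "bbox": [r0, c0, r1, c1],
                "mask": self.mask[r0:r1, c0:c1].astype(int).tolist(),
                "pixels": self.image[r0:r1, c0:c1].tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "ReferenceColorMap":
        h, w = d["shape"]
        image = np.zeros((h, w, 3), dtype=np.uint8)
        mask = np.zeros((h, w), dtype=bool)
        r0, c0, r1, c1 = d["bbox"]
        sub_mask = np.asarray(d["mask"], dtype=bool)
        sub_img = np.asarray(d["pixels"], dtype=np.uint8)
        mask[r0:r1, c0:c1] = sub_mask
        image[r0:r1, c0:c1][sub_mask] = sub_img[sub_mask]
        return cls(image=image, mask=mask, provenance=d["provenance"])

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def load(cls, path) -> "ReferenceColorMap":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


# ---------------------------------------------------------------------- layout

def make_board_spec(pattern: str = "A", *,
                    board_width_mm: float = 100.0,
                    board_height_mm: float = 70.0,
                    px_per_mm: float = 5.0,
                    marker_size_mm: float = 10.0,
                    marker_margin_mm: float = 2.0,
                    stripe_thickness_mm: float = 6.0,
                    swatch_count: int = 24) -> BoardSpec:
    """Build the default board layout for a pattern.

    Markers sit in the four corners (ids clockwise from bottom-left: 0
    bottom-left, 1 top-left, 2 top-right, 3 bottom-right); stripes run along
    the four sides between them; the sample region fills the centre.
    """
    if pattern not in PATTERNS:
        raise ValueError(f"unknown pattern {pattern!r}; choose from {PATTERNS}")
    if board_width_mm <= 0 or board_height_mm <= 0 or px_per_mm <= 0:
        raise ValueError("board dimensions and resolution must be positive")
    W, H = board_width_mm, board_height_mm
    m, s = marker_margin_mm, marker_size_mm
    if 2 * (m + s) >= min(W, H):
        raise ValueError("markers do not fit on the board")

    def marker(mid: int, x0: float, y0: float) -> MarkerPlacement:
        x1, y1 = x0 + s, y0 + s
        return MarkerPlacement(mid, np.array(
            [[x0, y1], [x1, y1], [x1, y0], [x0, y0]], dtype=float))

    board_markers = [
        marker(0, m, m),                      # bottom-left
        marker(1, m, H - m - s),              # top-left
        marker(2, W - m - s, H - m - s),      # top-right
        marker(3, W - m - s, m),              # bottom-right
    ]

    t = stripe_thickness_mm
    gap = 1.0  # mm between stripe and marker / board edge
    x_in0, x_in1 = m + s + 2 * gap, W - m - s - 2 * gap   # horizontal span
    y_in0, y_in1 = m + s + 2 * gap, H - m - s - 2 * gap   # vertical span
    side_rects = {
        "top": (x_in0, H - m - gap - t, x_in1 - x_in0, t),
        "bottom": (x_in0, m + gap, x_in1 - x_in0, t),
        "left": (m + gap, y_in0, t, y_in1 - y_in0),
        "right": (W - m - gap - t, y_in0, t, y_in1 - y_in0),
    }
    stripes = []
    for side, family in _PATTERN_SIDES[pattern].items():
        if family is None:
            continue
        fixed = ({"S": 1.0, "V": 1.0} if family == "H" else
                 {"H": _FIXED_HUE, "V": 1.0} if family == "S" else
                 {"H": _FIXED_HUE, "S": 1.0})
        stripes.append(StripeSpec(side=side, varying_component=family,
                                  fixed_components=fixed,
                                  swatch_count=swatch_count,
                                  rect_mm=side_rects[side]))

    sx0 = x_in0
    sy0 = m + gap + t + 2 * gap
    sample = (sx0, sy0, x_in1 - sx0, H - m - gap - t - 2 * gap - sy0)
    return BoardSpec(pattern=pattern, board_width_mm=W, board_height_mm=H,
                     px_per_mm=px_per_mm, marker_size_mm=marker_size_mm,
                     marker_margin_mm=marker_margin_mm,
                     stripe_thickness_mm=stripe_thickness_mm,
                     swatch_count=swatch_count, markers=board_markers,
                     stripes=stripes, sample_region_mm=sample)


# ---------------------------------------------------------------------- render

def stripe_mask(spec: BoardSpec) -> np.ndarray:
    mask = np.zeros(spec.raster_shape, dtype=bool)
    for stripe in spec.stripes:
        rows, cols = spec.rect_to_slices(stripe.rect_mm)
        mask[rows, cols] = True
    return mask


def _paint_stripe(img: np.ndarray, spec: BoardSpec, stripe: StripeSpec) -> None:
    rows, cols = spec.rect_to_slices(stripe.rect_mm)
    colors = stripe.swatch_rgb()
    n = stripe.swatch_count
    length = (cols.stop - cols.start) if stripe.horizontal else (rows.stop - rows.start)
    idx = np.minimum((np.arange(length) * n) // length, n - 1)
    if stripe.horizontal:  # varying component increases with x
        img[rows, cols] = colors[idx][None, :, :]
    else:                  # increases with world y, i.e. upward = decreasing row
        img[rows, cols] = colors[idx[::-1]][:, None, :]


def render_board(spec: BoardSpec) -> np.ndarray:
    """Deterministically rasterize a board spec to an (H, W, 3) uint8 image."""
    img = np.full(spec.raster_shape + (3,), 255, dtype=np.uint8)
    for stripe in spec.stripes:
        _paint_stripe(img, spec, stripe)
    size_px = spec.marker_size_mm * spec.px_per_mm
    for mp in spec.markers:
        bitmap = _markers.render_marker(mp.marker_id, size_px)
        x0 = mp.corners_mm[:, 0].min()
        y0 = mp.corners_mm[:, 1].min()
        rows, cols = spec.rect_to_slices((x0, y0, spec.marker_size_mm,
                                          spec.marker_size_mm))
        img[rows, cols] = bitmap[:rows.stop - rows.start,
                                 :cols.stop - cols.start, None]
    return img


def theoretical_refmap(spec: BoardSpec,
                       rendered: np.ndarray | None = None) -> ReferenceColorMap:
    if rendered is None:
        rendered = render_board(spec)
    mask = stripe_mask(spec)
    image = np.zeros_like(rendered)
    image[mask] = rendered[mask]
    return ReferenceColorMap(image=image, mask=mask, provenance="theoretical")


def generate_board(pattern: str = "A", *,
                   board_width_mm: float = 100.0,
                   board_height_mm: float = 70.0,
                   px_per_mm: float = 5.0,
                   **kwargs) -> tuple[BoardSpec, np.ndarray, ReferenceColorMap]:
    """Generate a board: spec, rendered raster and theoretical reference map."""
    spec = make_board_spec(pattern, board_width_mm=board_width_mm,
                           board_height_mm=board_height_mm,
                           px_per_mm=px_per_mm, **kwargs)
    rendered = render_board(spec)
    return spec, rendered, theoretical_refmap(spec, rendered)


def digitize_board(scanned_image: np.ndarray, spec: BoardSpec, *,
                   median_patch: int = 0) -> ReferenceColorMap:
    """Turn a rectified scan of the printed board into a reference map.

    The printed colors — not the theoretical source-file colors — are what a
    photographed board can be corrected toward, so the scan's stripe pixels
    become the reference.  ``median_patch`` > 1 applies a k x k per-channel
    median filter first to suppress scanner noise (default: direct sampling).
    """
    scanned = np.asarray(scanned_image)
    if scanned.shape[:2] != spec.raster_shape or scanned.ndim != 3:
        raise ValueError(
            f"scan shape {scanned.shape} does not match board raster "
            f"{spec.raster_shape + (3,)}")
    if median_patch > 1:
        from scipy.ndimage import median_filter
        scanned = np.stack([median_filter(scanned[..., c], size=median_patch)
                            for c in range(3)], axis=-1)
    mask = stripe_mask(spec)
    image = np.zeros((*spec.raster_shape, 3), dtype=np.uint8)
    image[mask] = scanned[mask]
    return ReferenceColorMap(image=image, mask=mask, provenance="digitized")
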