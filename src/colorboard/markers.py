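"""Square binary fiducial markers: dictionary, rendering and detection.

The board carries four 4x4-bit square markers (one per corner), each a black
border enclosing a 4x4 grid of black/white cells.  A marker is identified by
its bit pattern, which is chosen so that every 90-degree rotation of every
marker is unique across the dictionary — a detector can therefore recover
both the marker id and its orientation from a single view.

The dictionary ``board4x4_50`` is generated deterministically at import time:
candidate 16-bit codes are visited in a seeded random permutation and accepted
greedily when all four of their rotations keep a minimum Hamming distance from
every rotation of every previously accepted code (and from each other, which
rules out rotationally symmetric patterns).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure
from skimage.transform import ProjectiveTransform

GRID = 4                 # payload cells per side
CELLS = GRID + 2         # payload + 1-cell black border
DICT_NAME = "board4x4_50"
DICT_SIZE = 50
_MIN_HAMMING = 4
_DICT_SEED = 73           # fixed: the dictionary is part of the board format


def _bits_to_int(bits: np.ndarray) -> int:
    return int(sum(int(b) << i for i, b in enumerate(bits.ravel())))


def _int_to_bits(code: int) -> np.ndarray:
    return np.array([(code >> i) & 1 for i in range(GRID * GRID)],
                    dtype=np.uint8).reshape(GRID, GRID)


def _rotations(bits: np.ndarray) -> list[int]:
    return [_bits_to_int(np.rot90(bits, -k)) for k in range(4)]


def _hamming(a: int, b: int) -> int:
    return bin(a ^ b).count("1")


def build_dictionary(size: int = DICT_SIZE,
                     min_distance: int = _MIN_HAMMING,
                     seed: int = _DICT_SEED) -> list[int]:
    """Deterministically generate ``size`` rotation-unique 16-bit codes."""
    rng = np.random.default_rng(seed)
    order = rng.permutation(1 << (GRID * GRID))
    accepted: list[int] = []
    taken_rots: list[int] = []
    for cand in order:
        bits = _int_to_bits(int(cand))
        rots = _rotations(bits)
        # rotationally symmetric codes are ambiguous
        if len({*rots}) < 4:
            continue
        if any(_hamming(r1, r2) < min_distance
               for i, r1 in enumerate(rots) for r2 in rots[i + 1:]):
            continue
        if any(_hamming(r, t) < min_distance for r in rots for t in taken_rots):
            continue
        accepted.append(rots[0])
        taken_rots.extend(rots)
        if len(accepted) == size:
            return accepted
    raise RuntimeError(f"could only build {len(accepted)} codes")


DICTIONARY: list[int] = build_dictionary()

# rotation-of-any-code -> (id, number of CW quarter turns applied)
_DECODE: dict[int, tuple[int, int]] = {}
for _id, _code in enumerate(DICTIONARY):
    for _k, _rot in enumerate(_rotations(_int_to_bits(_code))):
        _DECODE[_rot] = (_id, _k)


def marker_bits(marker_id: int) -> np.ndarray:
    """4x4 payload bit grid (1 = white cell) of a dictionary marker."""
    return _int_to_bits(DICTIONARY[marker_id])


def render_marker(marker_id: int, size_px: float) -> np.ndarray:
    """Render an upright marker as a square uint8 image (0/255).

    ``size_px`` may be non-integral; cell membership is decided per pixel
    center so markers can be drawn at any physical scale.
    """
    n = int(round(size_px))
    coords = (np.arange(n) + 0.5) / n * CELLS
    cell = np.clip(coords.astype(int), 0, CELLS - 1)
    full = np.zeros((CELLS, CELLS), dtype=np.uint8)
    full[1:-1, 1:-1] = marker_bits(marker_id)
    return (full[np.ix_(cell, cell)] * 255).astype(np.uint8)


@dataclass(frozen=True)
class MarkerDetection:
    """One detected marker: id plus its 4 corners in canonical order.

    Corners are (x, y) pixel coordinates ordered top-left, top-right,
    bottom-right, bottom-left *of the upright marker pattern* (i.e. after
    undoing the in-plane rotation read from the bit payload).
    """
    marker_id: int
    corners: np.ndarray  # (4, 2) float


def _to_gray(image: np.ndarray) -> np.ndarray:
    img = np.asarray(image)
    if img.ndim == 3:
        img = img[..., :3].astype(np.float64) @ [0.299, 0.587, 0.114]
    else:
        img = img.astype(np.float64)
    if img.max() > 1.5:
        img = img / 255.0
    return img


def _order_clockwise(pts: np.ndarray) -> np.ndarray:
    """Order quad corners clockwise in image coords, top-left-most first."""
    c = pts.mean(axis=0)
    ang = np.arctan2(pts[:, 1] - c[1], pts[:, 0] - c[0])
    pts = pts[np.argsort(ang)]  # CCW in math coords == CW on screen? no:
    # y grows downward, so increasing atan2 angle walks clockwise on screen.
    start = int(np.argmin(pts.sum(axis=1)))
    return np.roll(pts, -start, axis=0)


def _refine_quad(contour_xy: np.ndarray, quad: np.ndarray) -> np.ndarray:
    """Subpixel corners from total-least-squares lines fitted per quad edge."""
    refined = []
    lines = []
    for i in range(4):
        a, b = quad[i], quad[(i + 1) % 4]
        ab = b - a
        t = np.clip(((contour_xy - a) @ ab) / (ab @ ab), 0, 1)
        d = np.linalg.norm(contour_xy - (a + t[:, None] * ab), axis=1)
        pts = contour_xy[d < 2.0]
        # keep away from the corners where the contour turns
        tt = ((pts - a) @ ab) / (ab @ ab)
        pts = pts[(tt > 0.15) & (tt < 0.85)]
        if len(pts) < 4:
            return quad
        mu = pts.mean(axis=0)
        _, _, vt = np.linalg.svd(pts - mu)
        direction = vt[0]
        normal = np.array([-direction[1], direction[0]])
        lines.append((normal, normal @ mu))
    for i in range(4):
        (n1, c1), (n2, c2) = lines[i - 1], lines[i]
        A = np.array([n1, n2])
        if abs(np.linalg.det(A)) < 1e-9:
            return quad
        refined.append(np.linalg.solve(A, [c1, c2]))
    return np.asarray(refined)


def _sample_cells(gray: np.ndarray, corners: np.ndarray) -> np.ndarray:
    """Mean intensity of each of the CELLS x CELLS cells of a quad."""
    canon = np.array([[0, 0], [CELLS, 0], [CELLS, CELLS], [0, CELLS]],
                     dtype=float)
    tf = ProjectiveTransform.from_estimate(canon, corners)
    if not tf:
        raise ValueError("degenerate quad")
    off = np.linspace(0.3, 0.7, 3)
    oy, ox = np.meshgrid(off, off, indexing="ij")
    vals = np.empty((CELLS, CELLS))
    for i in range(CELLS):
        for j in range(CELLS):
            pts = tf(np.column_stack([(j + ox.ravel()), (i + oy.ravel())]))
            samp = ndimage.map_coordinates(gray, [pts[:, 1], pts[:, 0]],
                                           order=1, mode="nearest")
            vals[i, j] = samp.mean()
    return vals


def detect_markers(image: np.ndarray,
                   min_side_px: float = 10.0) -> list[MarkerDetection]:
    """Find all dictionary markers in an image.

    Thresholds the image, extracts dark connected components, keeps convex
    quadrilaterals, decodes the cell grid against the dictionary (under all
    four rotations) and returns subpixel-refined corners in canonical order.
    """
    gray = _to_gray(image)
    if gray.size == 0:
        return []
    lo, hi = gray.min(), gray.max()
    if hi - lo < 0.1:  # featureless image
        return []
    thresh = 0.5 * (lo + hi)
    dark = gray < thresh
    labels = measure.label(dark, connectivity=2)
    detections: list[MarkerDetection] = []
    seen: set[int] = set()
    for region in measure.regionprops(labels):
        if region.area < min_side_px ** 2 * 0.5:
            continue
        r0, c0, r1, c1 = region.bbox
        if min(r1 - r0, c1 - c0) < min_side_px:
            continue
        mask = np.pad(ndimage.binary_fill_holes(
            labels[r0:r1, c0:c1] == region.label), 2)
        # subpixel boundary: threshold-level contour of the gray values,
        # restricted to the component (white elsewhere so it cannot leak)
        pad = 2
        rr0, rr1 = max(r0 - pad, 0), min(r1 + pad, gray.shape[0])
        cc0, cc1 = max(c0 - pad, 0), min(c1 + pad, gray.shape[1])
        gcrop = np.ones((r1 - r0 + 2 * pad, c1 - c0 + 2 * pad))
        gcrop[rr0 - r0 + pad:rr1 - r0 + pad,
              cc0 - c0 + pad:cc1 - c0 + pad] = gray[rr0:rr1, cc0:cc1]
        gcrop = np.where(ndimage.binary_dilation(mask, iterations=2),
                         gcrop, 1.0)
        contours = measure.find_contours(gcrop, thresh)
        if not contours:
            continue
        contour = max(contours, key=len)
        # (row, col) -> (x, y) in the full image frame
        contour_xy = contour[:, ::-1] + [c0 - pad, r0 - pad]
        approx = measure.approximate_polygon(contour_xy, tolerance=3.0)
        if len(approx) >= 2 and np.allclose(approx[0], approx[-1]):
            approx = approx[:-1]
        if len(approx) != 4:
            continue
        quad = _order_clockwise(approx.astype(float))
        side = np.linalg.norm(np.diff(np.vstack([quad, quad[:1]]), axis=0),
                              axis=1)
        if side.min() < min_side_px * 0.7 or side.min() < 0.4 * side.max():
            continue
        quad = _refine_quad(contour_xy, quad)
        try:
            cells = _sample_cells(gray, quad)
        except ValueError:
            continue
        cut = 0.5 * (cells.min() + cells.max())
        bits = (cells > cut).astype(np.uint8)
        border = np.concatenate([bits[0], bits[-1], bits[1:-1, 0],
                                 bits[1:-1, -1]])
        if border.any():  # border must be fully black
            continue
        code = _bits_to_int(bits[1:-1, 1:-1])
        if code not in _DECODE:
            continue
        marker_id, k = _DECODE[code]
        if marker_id in seen:
            continue
        seen.add(marker_id)
        # sampled grid = upright grid rotated CW k times, so the canonical
        # top-left corner sits k positions further along the clockwise quad
        corners = np.roll(quad, -k, axis=0)
        detections.append(MarkerDetection(marker_id, corners))
    detections.sort(key=lambda d: d.marker_id)
    return detections
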