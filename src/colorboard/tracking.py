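"""Sparse pyramidal Lucas–Kanade tracking of the 16 marker corners.

Full marker detection on every video frame is wasteful: adjacent frames move
by a few pixels at most, so the corners found once can be followed with a
local optical-flow step and detection re-run only when tracking breaks.  To
bound drift, tracking is only attempted when a complete set of 16 corners is
available; anything less falls straight back to detection.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .geometry import KeyPointSet
from .markers import _to_gray


class TrackingError(RuntimeError):
    """Raised when any point cannot be followed; caller should re-detect."""


def _pyramid(gray: np.ndarray, levels: int) -> list[np.ndarray]:
    pyr = [gray]
    for _ in range(levels - 1):
        sm = ndimage.gaussian_filter(pyr[-1], 1.0, mode="nearest")
        pyr.append(sm[::2, ::2])
    return pyr


def _track_point(prev_pyr, next_pyr, grads, p0: np.ndarray,
                 win: int, iters: int, eps: float) -> np.ndarray:
    levels = len(prev_pyr)
    off = np.arange(-(win // 2), win // 2 + 1, dtype=float)
    oy, ox = np.meshgrid(off, off, indexing="ij")
    d = np.zeros(2)  # displacement at current level, (x, y)
    for lvl in range(levels - 1, -1, -1):
        prev_l, next_l = prev_pyr[lvl], next_pyr[lvl]
        gx, gy = grads[lvl]
        p = p0 / (2 ** lvl)
        h, w = prev_l.shape
        if not (0 <= p[0] < w and 0 <= p[1] < h):
            raise TrackingError("point outside pyramid level")
        coords = [p[1] + oy.ravel(), p[0] + ox.ravel()]  # (row, col)
        Iw = ndimage.map_coordinates(prev_l, coords, order=1, mode="nearest")
        Ix = ndimage.map_coordinates(gx, coords, order=1, mode="nearest")
        Iy = ndimage.map_coordinates(gy, coords, order=1, mode="nearest")
        G = np.array([[Ix @ Ix, Ix @ Iy], [Ix @ Iy, Iy @ Iy]])
        if np.linalg.det(G) < 1e-9:
            raise TrackingError("textureless window")
        Ginv = np.linalg.inv(G)
        for _ in range(iters):
            q = p + d
            if not (-win <= q[0] < w + win and -win <= q[1] < h + win):
                raise TrackingError("point drifted out of bounds")
            Jw = ndimage.map_coordinates(
                next_l, [q[1] + oy.ravel(), q[0] + ox.ravel()],
                order=1, mode="nearest")
            r = Jw - Iw
            step = -Ginv @ np.array([Ix @ r, Iy @ r])
            d += step
            if np.hypot(*step) < eps:
                break
        if lvl > 0:
            d *= 2.0
    return p0 + d


def track_keypoints(prev_frame: np.ndarray, next_frame: np.ndarray,
                    prev_points: KeyPointSet, *, window: int = 21,
                    levels: int = 3, iterations: int = 30,
                    epsilon: float = 0.01) -> KeyPointSet:
    """Follow all 16 corners from ``prev_frame`` into ``next_frame``.

    Raises :class:`TrackingError` if fewer than 16 points are supplied, if a
    point leaves the image, or if a flow window lacks texture — in every case
    the caller should fall back to full detection.
    """
    if len(prev_points) != 16:
        raise TrackingError(
            f"tracking requires a complete set of 16 points, got "
            f"{len(prev_points)}")
    prev_g = _to_gray(prev_frame)
    next_g = _to_gray(next_frame)
    if prev_g.shape != next_g.shape:
        raise TrackingError("frame size changed")
    prev_pyr = _pyramid(prev_g, levels)
    next_pyr = _pyramid(next_g, levels)
    grads = []
    for lvl in range(levels):
        gy, gx = np.gradient(prev_pyr[lvl])
        grads.append((gx, gy))
    h, w = next_g.shape
    new_pts = np.empty_like(prev_points.image_points)
    for i, p0 in enumerate(prev_points.image_points):
        p1 = _track_point(prev_pyr, next_pyr, grads, np.asarray(p0, float),
                          window, iterations, epsilon)
        if not (0 <= p1[0] < w and 0 <= p1[1] < h):
            raise TrackingError(f"point {i} left the frame")
        new_pts[i] = p1
    return KeyPointSet(prev_points.marker_ids.copy(),
                       prev_points.corner_indices.copy(),
                       new_pts, prev_points.world_points.copy(),
                       source="tracked")
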