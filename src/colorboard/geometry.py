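"""Camera geometry: keypoint detection, pose solving, capture guidance,
and rectification of the board to an orthogonal view.

The pinhole model used throughout is ``s * [p; 1] = K R (P_w - C)`` where
``P_w`` is a world point on the board plane (z = 0, mm), ``R`` the world-to-
camera rotation, ``C`` the camera centre in world coordinates and ``K`` the
intrinsic matrix.  Because all world points are coplanar, the board-to-image
map is a homography; pose is recovered by decomposing it and polishing with a
Levenberg–Marquardt reprojection fit over all available correspondences.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial.transform import Rotation
from skimage.transform import ProjectiveTransform, warp

from .board import BoardSpec
from .markers import detect_markers


class GeometryError(ValueError):
    pass


@dataclass
class KeyPointSet:
    """Detected or tracked marker corners with their world positions."""
    marker_ids: np.ndarray    # (n,) int
    corner_indices: np.ndarray  # (n,) int in 0..3
    image_points: np.ndarray  # (n, 2) float px, (x, y)
    world_points: np.ndarray  # (n, 3) float mm, z = 0
    source: str = "detected"  # "detected" | "tracked"

    def __post_init__(self) -> None:
        n = len(self.marker_ids)
        if not (len(self.corner_indices) == len(self.image_points)
                == len(self.world_points) == n):
            raise ValueError("inconsistent keypoint arrays")
        if n > 16:
            raise ValueError("at most 16 keypoints (4 corners x 4 markers)")
        keys = list(zip(self.marker_ids.tolist(),
                        self.corner_indices.tolist()))
        if len(set(keys)) != n:
            raise ValueError("duplicate (marker, corner) entries")
        if n and np.any(self.world_points[:, 2] != 0):
            raise ValueError("world points must lie on the board plane z=0")

    def __len__(self) -> int:
        return len(self.marker_ids)

    @classmethod
    def empty(cls) -> "KeyPointSet":
        return cls(np.empty(0, int), np.empty(0, int),
                   np.empty((0, 2)), np.empty((0, 3)))


@dataclass(frozen=True)
class CameraIntrinsics:
    fx: float
    fy: float
    cx: float
    cy: float

    def __post_init__(self) -> None:
        if self.fx <= 0 or self.fy <= 0:
            raise ValueError("focal lengths must be positive")

    @property
    def K(self) -> np.ndarray:
        return np.array([[self.fx, 0.0, self.cx],
                         [0.0, self.fy, self.cy],
                         [0.0, 0.0, 1.0]])

    @property
    def focal(self) -> float:
        """Scalar focal length in px (mean of fx, fy)."""
        return 0.5 * (self.fx + self.fy)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"fx": self.fx, "fy": self.fy,
                       "cx": self.cx, "cy": self.cy}, fh)

    @classmethod
    def from_json(cls, path) -> "CameraIntrinsics":
        with open(path) as fh:
            d = json.load(fh)
        return cls(d["fx"], d["fy"], d["cx"], d["cy"])


@dataclass
class Pose:
    """Camera pose: world-to-camera rotation R and camera centre C (mm)."""
    R: np.ndarray             # (3, 3)
    C: np.ndarray             # (3,)
    scales: np.ndarray = field(default_factory=lambda: np.empty(0))
    reprojection_rms: float = float("nan")

    def project(self, world_points: np.ndarray, K: np.ndarray) -> np.ndarray:
        """Project (n, 3) world mm points to (n, 2) image px."""
        cam = (self.R @ (np.atleast_2d(world_points) - self.C).T).T
        if np.any(cam[:, 2] <= 0):
            raise GeometryError("points behind the camera")
        uvw = (K @ cam.T).T
        return uvw[:, :2] / uvw[:, 2:3]


@dataclass(frozen=True)
class GuidanceResult:
    """Outcome of the capture-pose gate.

    ``arrow`` points from the projected board centre to the image centre (px):
    it is the correction the user should apply.  A pose is accepted when the
    arrow is within ``epsilon_px`` and the camera height is between 1.0 and
    1.5 times the optimal height.
    """
    arrow: tuple[float, float]
    height_ratio: float
    accepted: bool
    epsilon_px: float = 20.0
    height_range: tuple[float, float] = (1.0, 1.5)


# ------------------------------------------------------------------- detection

def detect_keypoints(image: np.ndarray, spec: BoardSpec) -> KeyPointSet:
    """Detect up to 16 marker-corner keypoints and attach world coordinates."""
    world = spec.keypoint_world()
    known = {m.marker_id for m in spec.markers}
    ids, corners, img_pts, wrd_pts = [], [], [], []
    for det in detect_markers(image):
        if det.marker_id not in known:
            continue
        for k in range(4):
            ids.append(det.marker_id)
            corners.append(k)
            img_pts.append(det.corners[k])
            w = world[(det.marker_id, k)]
            wrd_pts.append([w[0], w[1], 0.0])
    if not ids:
        return KeyPointSet.empty()
    return KeyPointSet(np.asarray(ids), np.asarray(corners),
                       np.asarray(img_pts, float), np.asarray(wrd_pts, float),
                       source="detected")


# ------------------------------------------------------------------- pose

def _pose_params(R: np.ndarray, C: np.ndarray) -> np.ndarray:
    return np.concatenate([Rotation.from_matrix(R).as_rotvec(), C])


def _params_pose(p: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    return Rotation.from_rotvec(p[:3]).as_matrix(), p[3:]


def _reproj_residuals(p, world, image, K):
    R, C = _params_pose(p)
    cam = (R @ (world - C).T).T
    z = np.where(np.abs(cam[:, 2]) < 1e-12, 1e-12, cam[:, 2])
    uvw = (K @ cam.T).T
    proj = uvw[:, :2] / z[:, None]
    res = (proj - image).ravel()
    # softly penalize points behind the camera so the optimizer leaves there
    res[np.repeat(cam[:, 2] <= 0, 2)] += 1e6
    return res


def _homography_init(world, image, K):
    """Initial (R, C) from the plane-to-image homography (world z = 0)."""
    tf = ProjectiveTransform.from_estimate(world[:, :2], image)
    if not tf:
        raise GeometryError("degenerate correspondences")
    H = tf.params
    B = np.linalg.solve(K, H)
    lam = 2.0 / (np.linalg.norm(B[:, 0]) + np.linalg.norm(B[:, 1]))
    # the board must be in front of the camera: t_z > 0 picks the sign
    if (lam * B[2, 2]) < 0:
        lam = -lam
    r1, r2, t = lam * B[:, 0], lam * B[:, 1], lam * B[:, 2]
    Q = np.column_stack([r1, r2, np.cross(r1, r2)])
    u, _, vt = np.linalg.svd(Q)
    R = u @ np.diag([1.0, 1.0, np.linalg.det(u @ vt)]) @ vt
    C = -R.T @ t
    return R, C


def solve_pose(points: KeyPointSet, intrinsics: CameraIntrinsics) -> Pose:
    """Recover camera pose from >= 3 keypoint correspondences.

    With >= 4 points the planar homography provides the initial pose, refined
    by Levenberg–Marquardt over all points.  With exactly 3 points (minimal
    case) the solution is ambiguous; a multi-start refinement is run and the
    candidate with the lowest reprojection error wins.
    """
    n = len(points)
    if n < 3:
        raise GeometryError(f"need at least 3 points, got {n}")
    K = intrinsics.K
    world = points.world_points.astype(float)
    image = points.image_points.astype(float)

    candidates: list[tuple[np.ndarray, np.ndarray]] = []
    if n >= 4:
        candidates.append(_homography_init(world, image, K))
    else:
        # structured starts above the board at several heights/offsets
        cx, cy = world[:, 0].mean(), world[:, 1].mean()
        span = max(np.ptp(world[:, 0]), np.ptp(world[:, 1]), 1.0)
        R0 = np.diag([1.0, -1.0, -1.0])  # looking straight down, y flipped
        for h in (0.5, 1.0, 2.0, 5.0, 10.0):
            for dx, dy in ((0, 0), (span, 0), (0, span), (-span, -span)):
                candidates.append((R0, np.array([cx + dx, cy + dy, h * span])))

    best = None
    for R0c, C0c in candidates:
        try:
            sol = least_squares(_reproj_residuals, _pose_params(R0c, C0c),
                                args=(world, image, K), method="lm",
                                xtol=1e-15, ftol=1e-15, gtol=1e-15,
                                max_nfev=500)
        except Exception:
            continue
        rms = float(np.sqrt(np.mean(sol.fun ** 2)))
        if best is None or rms < best[0]:
            best = (rms, sol.x)
    if best is None:
        raise GeometryError("pose estimation failed")
    R, C = _params_pose(best[1])
    cam = (R @ (world - C).T).T
    return Pose(R=R, C=C, scales=cam[:, 2].copy(),
                reprojection_rms=best[0])


# ------------------------------------------------------------------- guidance

def optimal_height(intrinsics: CameraIntrinsics,
                   image_dims_px: tuple[float, float],
                   spec: BoardSpec) -> float:
    """Optimal capture height (mm): focal / min(W_img/W_board, H_img/H_board).

    At this height the board exactly fills the tighter image dimension, the
    best trade-off between coverage and resolution for a top-down view.
    """
    w_img, h_img = image_dims_px
    if w_img <= 0 or h_img <= 0:
        raise GeometryError("image dimensions must be positive")
    if spec.board_width_mm <= 0 or spec.board_height_mm <= 0:
        raise GeometryError("board dimensions must be positive")
    ratio = min(w_img / spec.board_width_mm, h_img / spec.board_height_mm)
    return intrinsics.focal / ratio


def guidance(pose: Pose, intrinsics: CameraIntrinsics, spec: BoardSpec,
             image_dims_px: tuple[float, float], *,
             epsilon_px: float = 20.0,
             height_range: tuple[float, float] = (1.0, 1.5)) -> GuidanceResult:
    """Evaluate the capture-pose gate for a solved pose."""
    centre_world = np.array([[spec.board_width_mm / 2,
                              spec.board_height_mm / 2, 0.0]])
    proj = pose.project(centre_world, intrinsics.K)[0]  # raises if behind
    image_centre = np.array([image_dims_px[0] / 2, image_dims_px[1] / 2])
    arrow = image_centre - proj
    h_opt = optimal_height(intrinsics, image_dims_px, spec)
    ratio = float(pose.C[2]) / h_opt
    accepted = (float(np.hypot(*arrow)) <= epsilon_px
                and height_range[0] <= ratio <= height_range[1])
    return GuidanceResult(arrow=(float(arrow[0]), float(arrow[1])),
                          height_ratio=ratio, accepted=accepted,
                          epsilon_px=epsilon_px, height_range=height_range)


# ------------------------------------------------------------------- rectify

def rectify(image: np.ndarray, points: KeyPointSet,
            spec: BoardSpec) -> np.ndarray:
    """Warp the photographed board to its orthogonal raster view.

    Estimates the image-to-board homography from the keypoints and resamples
    (bicubic, clamped) onto the spec's raster grid.  Content outside the
    board is cropped by construction: the output contains exactly the board
    area.
    """
    if len(points) < 4:
        raise GeometryError("rectification needs at least 4 points")
    src = spec.world_to_raster(points.world_points[:, :2])
    # collinearity check: rank of centred points
    centred = src - src.mean(axis=0)
    if np.linalg.matrix_rank(centred, tol=1e-6) < 2:
        raise GeometryError("keypoints are collinear")
    tf = ProjectiveTransform.from_estimate(src, points.image_points)
    if not tf:
        raise GeometryError("homography estimation failed")
    img = np.asarray(image, dtype=float) / 255.0
    out = warp(img, tf, output_shape=spec.raster_shape, order=3,
               mode="constant", cval=0.0)
    return np.clip(np.round(out * 255.0), 0, 255).astype(np.uint8)
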