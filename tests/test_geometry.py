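import numpy as np
import pytest
from scipy.spatial.transform import Rotation
from skimage.transform import ProjectiveTransform, warp

from colorboard import (CameraIntrinsics, GeometryError, KeyPointSet, Pose,
                        detect_keypoints, guidance, make_board_spec,
                        optimal_height, rectify, solve_pose, stripe_mask)

DOWN = np.diag([1.0, -1.0, -1.0])  # camera looking straight down at the board


def random_pose(rng, spec):
    """A pose inside the acceptance frustum, looking roughly at the board."""
    C = np.array([spec.board_width_mm / 2 + rng.uniform(-20, 20),
                  spec.board_height_mm / 2 + rng.uniform(-20, 20),
                  rng.uniform(120, 260)])
    tilt = Rotation.from_euler("xyz", rng.uniform(-0.25, 0.25, 3)).as_matrix()
    return Pose(R=tilt @ DOWN, C=C)


class TestDetect:
    def test_fronto_parallel_sixteen_points_subpixel(self, spec, board_image):
        kps = detect_keypoints(board_image, spec)
        assert len(kps) == 16 and kps.source == "detected"
        expected = spec.world_to_raster(kps.world_points[:, :2])
        assert np.abs(kps.image_points - expected).max() < 1.0

    def test_blank_image_empty_set(self, spec):
        kps = detect_keypoints(np.full((350, 500, 3), 255, np.uint8), spec)
        assert len(kps) == 0

    def test_occluded_marker_yields_twelve_points(self, spec, board_image):
        img = board_image.copy()
        m = next(m for m in spec.markers if m.marker_id == 2)
        x0, y0 = m.corners_mm[:, 0].min(), m.corners_mm[:, 1].min()
        rows, cols = spec.rect_to_slices(
            (x0 - 1, y0 - 1, spec.marker_size_mm + 2, spec.marker_size_mm + 2))
        img[rows, cols] = 255
        kps = detect_keypoints(img, spec)
        assert len(kps) == 12
        assert 2 not in set(kps.marker_ids)


class TestPose:
    def test_roundtrip_recovers_pose(self, spec, intrinsics, world_keypoints):
        ids, cidx, world = world_keypoints
        rng = np.random.default_rng(11)
        for _ in range(25):
            pose = random_pose(rng, spec)
            proj = pose.project(world, intrinsics.K)
            est = solve_pose(KeyPointSet(ids, cidx, proj, world), intrinsics)
            assert np.linalg.norm(est.C - pose.C) < 1e-3
            assert np.linalg.norm(est.R - pose.R) < 1e-6
            assert est.reprojection_rms < 1e-6
            assert np.all(est.scales > 0)

    def test_centered_overhead_camera(self, spec, intrinsics, world_keypoints):
        ids, cidx, world = world_keypoints
        C = np.array([spec.board_width_mm / 2, spec.board_height_mm / 2, 200.0])
        pose = Pose(R=DOWN.copy(), C=C)
        proj = pose.project(world, intrinsics.K)
        est = solve_pose(KeyPointSet(ids, cidx, proj, world), intrinsics)
        assert np.allclose(est.C, C, atol=1e-6)

    def test_three_points_minimal_case(self, spec, intrinsics,
                                       world_keypoints):
        ids, cidx, world = world_keypoints
        pose = Pose(R=DOWN.copy(), C=np.array([50.0, 35.0, 180.0]))
        proj = pose.project(world, intrinsics.K)
        sel = [0, 5, 10]  # corners of three different markers
        est = solve_pose(KeyPointSet(ids[sel], cidx[sel], proj[sel],
                                     world[sel]), intrinsics)
        assert est.reprojection_rms < 1e-6

    def test_fewer_than_three_points_rejected(self, intrinsics,
                                              world_keypoints):
        ids, cidx, world = world_keypoints
        pts = np.zeros((2, 2))
        with pytest.raises(GeometryError):
            solve_pose(KeyPointSet(ids[:2], cidx[:2], pts, world[:2]),
                       intrinsics)


class TestOptimalHeight:
    def test_hand_computed_values(self):
        K = CameraIntrinsics(1000, 1000, 0, 0)
        s = make_board_spec("A", board_width_mm=100, board_height_mm=200)
        assert optimal_height(K, (1000, 2000), s) == pytest.approx(100.0)
        K2 = CameraIntrinsics(500, 500, 0, 0)
        s2 = make_board_spec("A", board_width_mm=100, board_height_mm=50)
        assert optimal_height(K2, (1000, 1000), s2) == pytest.approx(50.0)

    def test_homogeneity_in_board_size(self):
        K = CameraIntrinsics(1000, 1000, 0, 0)
        s1 = make_board_spec("A", board_width_mm=100, board_height_mm=200)
        s2 = make_board_spec("A", board_width_mm=200, board_height_mm=400)
        assert (optimal_height(K, (1000, 2000), s2)
                == pytest.approx(2 * optimal_height(K, (1000, 2000), s1)))

    def test_zero_image_dims_rejected(self, spec, intrinsics):
        with pytest.raises(GeometryError):
            optimal_height(intrinsics, (0, 100), spec)


class TestGuidance:
    def _overhead(self, spec, height, dx=0.0, dy=0.0):
        return Pose(R=DOWN.copy(),
                    C=np.array([spec.board_width_mm / 2 + dx,
                                spec.board_height_mm / 2 + dy, height]))

    def test_optimal_pose_accepted_with_zero_arrow(self, spec, intrinsics):
        h = optimal_height(intrinsics, (800, 600), spec)
        g = guidance(self._overhead(spec, h), intrinsics, spec, (800, 600))
        assert np.hypot(*g.arrow) < 1e-9
        assert g.accepted and g.height_ratio == pytest.approx(1.0)

    def test_double_height_rejected(self, spec, intrinsics):
        h = optimal_height(intrinsics, (800, 600), spec)
        g = guidance(self._overhead(spec, 2 * h), intrinsics, spec,
                     (800, 600))
        assert not g.accepted and g.height_ratio == pytest.approx(2.0)

    def test_small_offset_at_valid_height_accepted(self, spec, intrinsics):
        h = optimal_height(intrinsics, (800, 600), spec)
        # lateral offset producing a ~10 px arrow: dx = 10 * h * 1.2 / f
        dx = 10.0 * (1.2 * h) / intrinsics.fx
        g = guidance(self._overhead(spec, 1.2 * h, dx=dx), intrinsics, spec,
                     (800, 600))
        assert np.hypot(*g.arrow) == pytest.approx(10.0, abs=1e-6)
        assert g.accepted

    def test_acceptance_gate_grid(self, spec, intrinsics):
        """accepted <=> |arrow| <= 20 px and height ratio in [1.0, 1.5]."""
        h = optimal_height(intrinsics, (800, 600), spec)
        for ratio in (0.8, 1.0, 1.2, 1.5, 1.6, 2.0):
            for arrow_px in (0.0, 10.0, 19.9, 20.0, 25.0, 40.0):
                dx = arrow_px * (ratio * h) / intrinsics.fx
                g = guidance(self._overhead(spec, ratio * h, dx=dx),
                             intrinsics, spec, (800, 600))
                should = (arrow_px <= 20.0 + 1e-9) and (1.0 <= ratio <= 1.5)
                assert g.accepted == should, (ratio, arrow_px)

    def test_arrow_monotone_in_lateral_offset(self, spec, intrinsics):
        h = optimal_height(intrinsics, (800, 600), spec)
        mags = [np.hypot(*guidance(self._overhead(spec, 1.2 * h, dx=dx),
                                   intrinsics, spec, (800, 600)).arrow)
                for dx in np.linspace(0, 30, 12)]
        assert np.all(np.diff(mags) >= -1e-9)

    def test_board_behind_camera_rejected(self, spec, intrinsics):
        pose = Pose(R=np.eye(3), C=np.array([50.0, 35.0, 100.0]))
        with pytest.raises(GeometryError):
            guidance(pose, intrinsics, spec, (800, 600))


class TestRectify:
    def test_identity_on_fronto_parallel_render(self, spec, board_image):
        kps = detect_keypoints(board_image, spec)
        rect = rectify(board_image, kps, spec)
        diff = np.abs(rect.astype(int) - board_image.astype(int))
        assert diff.max() <= 2

    def test_warp_roundtrip_on_stripes(self, spec, board_image, stripes_mask):
        h, w = spec.raster_shape
        src = np.array([[0, 0], [w, 0], [w, h], [0, h]], float)
        dst = src + [[18, 12], [-9, 16], [-14, -11], [11, -15]]
        tf = ProjectiveTransform.from_estimate(dst, src)
        warped = warp(board_image.astype(float) / 255.0, tf,
                      output_shape=(h, w), order=1, cval=1.0)
        warped = (warped * 255).round().astype(np.uint8)
        kps = detect_keypoints(warped, spec)
        assert len(kps) == 16
        rect = rectify(warped, kps, spec)
        interior = stripes_mask.copy()  # swatch-boundary pixels may straddle
        diff = np.abs(rect.astype(float) - board_image.astype(float))
        assert diff[interior].mean() <= 2.0

    def test_content_outside_board_cropped(self, spec, board_image):
        canvas = np.full((500, 700, 3), 90, np.uint8)  # distinctive surround
        canvas[60:410, 80:580] = board_image
        kps = detect_keypoints(canvas, spec)
        rect = rectify(canvas, kps, spec)
        assert rect.shape[:2] == spec.raster_shape
        # the surround gray must not appear: rectified content is board-only
        diff = np.abs(rect.astype(int) - board_image.astype(int))
        assert diff.mean() < 1.0

    def test_collinear_points_rejected(self, spec):
        ids = np.array([0, 0, 0, 0])
        cidx = np.arange(4)
        world = np.array([[i * 10.0, 20.0, 0.0] for i in range(4)])
        img_pts = np.array([[i * 10.0, 30.0] for i in range(4)])
        with pytest.raises(GeometryError):
            rectify(np.zeros((50, 50, 3), np.uint8),
                    KeyPointSet(ids, cidx, img_pts, world), spec)

    def test_insufficient_points_rejected(self, spec):
        with pytest.raises(GeometryError):
            rectify(np.zeros((50, 50, 3), np.uint8), KeyPointSet.empty(),
                    spec)


class TestKeyPointSet:
    def test_duplicate_entries_rejected(self):
        ids = np.array([0, 0])
        cidx = np.array([1, 1])
        with pytest.raises(ValueError):
            KeyPointSet(ids, cidx, np.zeros((2, 2)), np.zeros((2, 3)))

    def test_off_plane_world_point_rejected(self):
        with pytest.raises(ValueError):
            KeyPointSet(np.array([0]), np.array([0]), np.zeros((1, 2)),
                        np.array([[0.0, 0.0, 5.0]]))
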