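import numpy as np
import pytest

from colorboard import (CameraIntrinsics, generate_board, generate_mosaic,
                        compose_scene, stripe_mask)


@pytest.fixture(scope="session")
def board_a():
    """Pattern-A board: (spec, rendered image, theoretical refmap)."""
    return generate_board("A")


@pytest.fixture(scope="session")
def spec(board_a):
    return board_a[0]


@pytest.fixture(scope="session")
def board_image(board_a):
    return board_a[1]


@pytest.fixture(scope="session")
def refmap(board_a):
    return board_a[2]


@pytest.fixture(scope="session")
def stripes_mask(spec):
    return stripe_mask(spec)


@pytest.fixture(scope="session")
def mosaic():
    return generate_mosaic(seed=42)


@pytest.fixture(scope="session")
def scene(spec, refmap, mosaic):
    """Ground-truth board with the seeded mosaic in the sample region."""
    return compose_scene(spec, refmap, mosaic)


@pytest.fixture(scope="session")
def intrinsics():
    return CameraIntrinsics(fx=800.0, fy=800.0, cx=400.0, cy=300.0)


@pytest.fixture(scope="session")
def world_keypoints(spec):
    """All 16 marker-corner (ids, corner_indices, world xyz) arrays."""
    items = sorted(spec.keypoint_world().items())
    ids = np.array([mid for (mid, _), _ in items])
    cidx = np.array([k for (_, k), _ in items])
    world = np.array([[w[0], w[1], 0.0] for _, w in items])
    return ids, cidx, world
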