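"""Solve the camera pose from marker corners and evaluate the capture gate.

A capture is accepted when the projected board centre lies within 20 px of
the image centre and the camera height is 1.0-1.5x the optimal height (the
height at which the board exactly fills the tighter image dimension).
"""

import numpy as np

from colorboard import (CameraIntrinsics, KeyPointSet, Pose, guidance,
                        make_board_spec, optimal_height, solve_pose)

spec = make_board_spec("A")
K = CameraIntrinsics(fx=800, fy=800, cx=400, cy=300)
h_opt = optimal_height(K, (800, 600), spec)
print(f"optimal capture height: {h_opt:.1f} mm")

items = sorted(spec.keypoint_world().items())
ids = np.array([m for (m, _), _ in items])
cidx = np.array([k for (_, k), _ in items])
world = np.array([[v[0], v[1], 0.0] for _, v in items])

for label, dx, ratio in [("centred at optimal height", 0.0, 1.0),
                         ("5 mm off-centre, 1.3x height", 5.0, 1.3),
                         ("centred but 2x too high", 0.0, 2.0)]:
    true = Pose(R=np.diag([1.0, -1.0, -1.0]),
                C=np.array([spec.board_width_mm / 2 + dx,
                            spec.board_height_mm / 2, ratio * h_opt]))
    est = solve_pose(KeyPointSet(ids, cidx, true.project(world, K.K), world),
                     K)
    g = guidance(est, K, spec, (800, 600))
    print(f"{label}: arrow {np.hypot(*g.arrow):6.1f} px, "
          f"height ratio {g.height_ratio:.2f} -> "
          f"{'ACCEPT' if g.accepted else 'move the camera'}")
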