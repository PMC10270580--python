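"""Generate a reference board and digitize a (simulated) scan of it.

The printed board never matches the source file exactly, so the reference
colors used for correction are taken from a scan of the actual print.  Here
the "print" shifts every red value up by 8 levels; the digitized map picks
that up while the theoretical map keeps the source colors.
"""

import numpy as np

from colorboard import digitize_board, generate_board

spec, image, theoretical = generate_board("A")
print(f"pattern A board: {spec.board_width_mm:g} x {spec.board_height_mm:g} mm "
      f"at {spec.px_per_mm:g} px/mm -> raster {image.shape[1]}x{image.shape[0]}")
print(f"stripes: {[(s.side, s.varying_component) for s in spec.stripes]}")
print(f"marker corner keypoints: {len(spec.keypoint_world())}")

# simulate a print/scan with a warm shift in the red channel
printed = image.astype(int)
printed[..., 0] = np.clip(printed[..., 0] + 8, 0, 255)
digitized = digitize_board(printed.astype(np.uint8), spec)

x, y = 465, 150  # a pixel on the right value stripe (mid-grey red level)
print(f"stripe pixel ({x},{y}): source file {theoretical.color_at(x, y)}, "
      f"scanned print {digitized.color_at(x, y)}")
print("corrections should target the printed colors, i.e. the digitized map.")
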