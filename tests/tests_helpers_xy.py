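"""Shared test helper: synthesize an sRGB color with a given chromaticity."""

import numpy as np

from colorboard.colorimetry import _RGB2XYZ


def xy_to_rgb(x, y, Y=0.4):
    X = x * Y / y
    Z = (1 - x - y) * Y / y
    lin = np.linalg.solve(_RGB2XYZ, np.array([X, Y, Z]))
    lin = np.clip(lin, 0, 1)
    srgb = np.where(lin <= 0.0031308, 12.92 * lin,
                    1.055 * lin ** (1 / 2.4) - 0.055)
    return np.round(srgb * 255)
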