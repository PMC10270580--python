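"""Evaluation metrics and chromaticity-based pH reading.

Correction quality is summarized by the mean RMSE over the RGB channels,

    mRMSE = (RMSE_R + RMSE_G + RMSE_B) / 3,
    RMSE_c = sqrt( mean over evaluated pixels of (I_ref_c - I_corr_c)^2 ),

in 8-bit intensity levels.  pH strips are read by locating the measured color
on a reference curve in CIE 1931 xy chromaticity space: each chart swatch
maps to an (x, y) point, the two reference points closest to the measured
chromaticity are found, and the pH is interpolated by inverse distance
weighting, pH = (pH1 * d2 + pH2 * d1) / (d1 + d2).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

D65_XY = (0.3127159, 0.3290015)

# linear sRGB -> CIE 1931 XYZ, D65 white, 2-degree observer
_RGB2XYZ = np.array([[0.4124564, 0.3575761, 0.1804375],
                     [0.2126729, 0.7151522, 0.0721750],
                     [0.0193339, 0.1191920, 0.9503041]])


class ColorimetryError(ValueError):
    pass


# --------------------------------------------------------------------- metrics

@dataclass(frozen=True)
class MetricReport:
    rmse: dict[str, float]      # per channel R/G/B
    mrmse: float
    shape: tuple[int, int]
    n_pixels: int               # pixels evaluated (mask size)

    def to_dict(self) -> dict:
        return {"rmse": self.rmse, "mrmse": self.mrmse,
                "shape": list(self.shape), "n_pixels": self.n_pixels}


def compute_mrmse(corrected: np.ndarray, reference: np.ndarray,
                  mask: np.ndarray | None = None) -> MetricReport:
    """Per-channel RMSE and their mean over an optional pixel mask."""
    corr = np.asarray(corrected, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if corr.shape != ref.shape:
        raise ColorimetryError("images must share dimensions")
    if mask is None:
        mask = np.ones(corr.shape[:2], dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != corr.shape[:2]:
        raise ColorimetryError("mask shape mismatch")
    if not mask.any():
        raise ColorimetryError("empty evaluation mask")
    diff = corr[mask] - ref[mask]
    rmse = {c: float(np.sqrt(np.mean(diff[:, i] ** 2)))
            for i, c in enumerate("RGB")}
    return MetricReport(rmse=rmse, mrmse=float(np.mean(list(rmse.values()))),
                        shape=tuple(corr.shape[:2]),
                        n_pixels=int(mask.sum()))


@dataclass(frozen=True)
class VarianceReport:
    """Across-image variance of the object's mean color, before vs after."""
    variance_before: dict[str, float]
    variance_after: dict[str, float]

    @property
    def reduction_ratio(self) -> dict[str, float]:
        return {c: (self.variance_before[c] / self.variance_after[c]
                    if self.variance_after[c] > 0 else float("inf"))
                for c in "RGB"}


def _mask_mean_variance(images, mask) -> dict[str, float]:
    means = np.array([np.asarray(im, float)[mask].mean(axis=0)
                      for im in images])
    var = means.var(axis=0)  # population variance (ddof=0)
    return {c: float(var[i]) for i, c in enumerate("RGB")}


def variance_report(images_before, images_after,
                    mask: np.ndarray) -> VarianceReport:
    """Color consistency of one object photographed under many conditions.

    For each image the mean RGB over ``mask`` is taken; the population
    variance of those means across images measures how much the apparent
    color drifts with illumination.  A good correction shrinks it.
    """
    if len(images_before) < 2 or len(images_after) < 2:
        raise ColorimetryError("need at least 2 images per condition set")
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ColorimetryError("empty object mask")
    return VarianceReport(_mask_mean_variance(images_before, mask),
                          _mask_mean_variance(images_after, mask))


# --------------------------------------------------------------- chromaticity

@dataclass(frozen=True)
class ChromaticityPoint:
    x: float
    y: float

    def __post_init__(self) -> None:
        if self.x < 0 or self.y < 0 or self.x + self.y > 1.0 + 1e-9:
            raise ColorimetryError("invalid chromaticity coordinates")

    def distance(self, other: "ChromaticityPoint") -> float:
        return float(np.hypot(self.x - other.x, self.y - other.y))


def srgb_to_linear(rgb: np.ndarray) -> np.ndarray:
    v = np.asarray(rgb, dtype=float) / 255.0
    return np.where(v <= 0.04045, v / 12.92, ((v + 0.055) / 1.055) ** 2.4)


def rgb_to_xyz(rgb) -> np.ndarray:
    return _RGB2XYZ @ srgb_to_linear(np.asarray(rgb, float))


def rgb_to_xy(rgb) -> ChromaticityPoint:
    """sRGB (8-bit, D65) -> CIE 1931 xy chromaticity.

    Black carries no chromaticity; by convention it maps to the D65 white
    point so that downstream distance computations remain defined.
    """
    xyz = rgb_to_xyz(rgb)
    total = xyz.sum()
    if total <= 0:
        return ChromaticityPoint(*D65_XY)
    return ChromaticityPoint(float(xyz[0] / total), float(xyz[1] / total))


# ----------------------------------------------------------------- pH reading

@dataclass(frozen=True)
class PHReferenceCurve:
    """Ordered (pH, chromaticity, source RGB) reference points."""
    ph_values: np.ndarray       # (n,) strictly increasing
    points: tuple[ChromaticityPoint, ...]
    rgb: np.ndarray             # (n, 3) uint8

    def __len__(self) -> int:
        return len(self.ph_values)


def build_ph_curve(chart: list[tuple[float, tuple[int, int, int]]]
                   ) -> PHReferenceCurve:
    """Build the reference curve from (pH, RGB) chart entries."""
    if len(chart) < 2:
        raise ColorimetryError("need at least 2 chart entries")
    phs = np.array([float(p) for p, _ in chart])
    if len(np.unique(phs)) != len(phs):
        raise ColorimetryError("duplicate pH values in chart")
    order = np.argsort(phs)
    rgbs = np.array([chart[i][1] for i in order], dtype=np.uint8)
    pts = tuple(rgb_to_xy(rgb) for rgb in rgbs)
    return PHReferenceCurve(ph_values=phs[order], points=pts, rgb=rgbs)


def load_chart(path) -> PHReferenceCurve:
    """Load a chart JSON: [{"ph": 6.8, "rgb": [r, g, b]}, ...]."""
    with open(path) as fh:
        entries = json.load(fh)
    return build_ph_curve([(e["ph"], tuple(e["rgb"])) for e in entries])


def read_ph(measured_rgb, curve: PHReferenceCurve) -> float:
    """Interpolate a pH value for a measured color by IDW on the curve.

    The two reference points nearest to the measured chromaticity are used;
    when the two smallest distances belong to non-adjacent chart entries the
    adjacent pair bracketing the single nearest point is used instead, so the
    reading always interpolates along the curve.  An exact color match
    returns that reference pH.
    """
    m = rgb_to_xy(measured_rgb)
    d = np.array([m.distance(p) for p in curve.points])
    i_near = int(np.argmin(d))
    if d[i_near] == 0.0:
        return float(curve.ph_values[i_near])
    order = np.argsort(d, kind="stable")
    i, j = int(order[0]), int(order[1])
    if abs(i - j) != 1:
        # fall back to the adjacent neighbour of the nearest point
        cands = [k for k in (i_near - 1, i_near + 1) if 0 <= k < len(curve)]
        j = min(cands, key=lambda k: d[k])
        i = i_near
    lo, hi = (i, j) if curve.ph_values[i] < curve.ph_values[j] else (j, i)
    d1, d2 = d[lo], d[hi]  # d1 to the lower-pH point
    ph1, ph2 = float(curve.ph_values[lo]), float(curve.ph_values[hi])
    return (ph1 * d2 + ph2 * d1) / (d1 + d2)
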