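"""Color correction models fitted on the board's reference stripes.

The captured, rectified board shows distorted stripe colors; their true
values are known from the reference map.  A per-channel linear map

    I_ref = alpha * I_img + beta

is fitted on (observed, reference) pairs sampled along the stripe
centerlines.  In the *simple linear model* (order 0) alpha and beta are
global scalars per channel.  In the *spatially varying coefficient model*
(SVCM) they are low-order polynomial surfaces of pixel position,

    order 1:  f(x, y) = a x + b y + c                      (3 parameters)
    order 2:  f(x, y) = a x^2 + b x y + c y^2 + l x + m y + n   (6 parameters)

which lets a single capture compensate illumination that varies smoothly
across the board.  Each channel is fitted independently by ordinary least
squares, jointly over the alpha and beta surfaces; pixel coordinates are
normalized to [0, 1]^2 first for conditioning.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from skimage.exposure import match_histograms

from .board import BoardSpec, ReferenceColorMap

_N_COEF = {0: 1, 1: 3, 2: 6}
# minimum sample-pair counts per order (total unknowns + 2)
MIN_PAIRS = {0: 2, 1: 8, 2: 14}


class CorrectionError(ValueError):
    pass


@dataclass
class SamplePairs:
    """Corresponding (observed, reference) stripe colors at sampled pixels."""
    positions: np.ndarray   # (n, 2) float, rectified (x, y) px
    observed: np.ndarray    # (n, 3) float, captured RGB
    reference: np.ndarray   # (n, 3) float, reference RGB
    raster_shape: tuple[int, int]  # (rows, cols) of the rectified raster

    def __len__(self) -> int:
        return len(self.positions)


@dataclass(frozen=True)
class CoefficientSurface:
    """A polynomial surface f(x, y) over normalized board coordinates."""
    order: int
    coefficients: np.ndarray  # order 0: (c,); 1: (a,b,c); 2: (a,b,c,l,m,n)

    def __post_init__(self) -> None:
        if self.order not in _N_COEF:
            raise CorrectionError(f"unsupported order {self.order}")
        if len(self.coefficients) != _N_COEF[self.order]:
            raise CorrectionError("coefficient count does not match order")

    def __call__(self, xn: np.ndarray, yn: np.ndarray) -> np.ndarray:
        c = self.coefficients
        if self.order == 0:
            return np.full_like(np.asarray(xn, float), c[0])
        if self.order == 1:
            return c[0] * xn + c[1] * yn + c[2]
        return (c[0] * xn ** 2 + c[1] * xn * yn + c[2] * yn ** 2
                + c[3] * xn + c[4] * yn + c[5])


@dataclass
class CorrectionModel:
    """Per-channel alpha/beta coefficient surfaces plus fit diagnostics."""
    order: int
    alpha: dict[str, CoefficientSurface]
    beta: dict[str, CoefficientSurface]
    raster_shape: tuple[int, int]
    residual_rms: dict[str, float] = field(default_factory=dict)
    fallback_channels: tuple[str, ...] = ()

    CHANNELS = ("R", "G", "B")

    def coefficient_maps(self, shape=None):
        """Dense (H, W) alpha and beta maps per channel."""
        h, w = shape or self.raster_shape
        xn, yn = _normalized_grid(h, w, self.raster_shape)
        a = np.stack([self.alpha[c](xn, yn) for c in self.CHANNELS], axis=-1)
        b = np.stack([self.beta[c](xn, yn) for c in self.CHANNELS], axis=-1)
        return a, b

    def to_dict(self) -> dict:
        return {"order": self.order,
                "raster_shape": list(self.raster_shape),
                "alpha": {c: self.alpha[c].coefficients.tolist()
                          for c in self.CHANNELS},
                "alpha_orders": {c: self.alpha[c].order
                                 for c in self.CHANNELS},
                "beta": {c: self.beta[c].coefficients.tolist()
                         for c in self.CHANNELS},
                "beta_orders": {c: self.beta[c].order for c in self.CHANNELS},
                "residual_rms": self.residual_rms,
                "fallback_channels": list(self.fallback_channels)}

    @classmethod
    def from_dict(cls, d: dict) -> "CorrectionModel":
        alpha = {c: CoefficientSurface(d["alpha_orders"][c],
                                       np.asarray(d["alpha"][c]))
                 for c in cls.CHANNELS}
        beta = {c: CoefficientSurface(d["beta_orders"][c],
                                      np.asarray(d["beta"][c]))
                for c in cls.CHANNELS}
        return cls(order=d["order"], alpha=alpha, beta=beta,
                   raster_shape=tuple(d["raster_shape"]),
                   residual_rms=dict(d.get("residual_rms", {})),
                   fallback_channels=tuple(d.get("fallback_channels", ())))

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def load(cls, path) -> "CorrectionModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _normalized_grid(h, w, raster_shape):
    rows, cols = raster_shape
    ys, xs = np.mgrid[0:h, 0:w]
    return xs / max(cols - 1, 1), ys / max(rows - 1, 1)


def _normalize_positions(pos, raster_shape):
    rows, cols = raster_shape
    return pos[:, 0] / max(cols - 1, 1), pos[:, 1] / max(rows - 1, 1)


# ----------------------------------------------------------------- sampling

def sample_pairs(rectified: np.ndarray, refmap: ReferenceColorMap,
                 spec: BoardSpec, interval_px: int = 10) -> SamplePairs:
    """Sample (observed, reference) pairs along each stripe centerline.

    Points are taken every ``interval_px`` pixels starting at the stripe's
    origin; a stripe of length L yields floor(L / interval) + 1 samples.
    """
    rectified = np.asarray(rectified)
    if rectified.shape[:2] != spec.raster_shape:
        raise CorrectionError("image is not in the board raster frame")
    if interval_px < 1:
        raise CorrectionError("interval must be >= 1 px")
    if not spec.stripes:
        raise CorrectionError("board spec has no stripes to sample")
    pos, obs, ref = [], [], []
    for stripe in spec.stripes:
        rows, cols = spec.rect_to_slices(stripe.rect_mm)
        if rows.stop <= rows.start or cols.stop <= cols.start:
            raise CorrectionError(f"stripe {stripe.side} rasterizes to empty")
        if stripe.horizontal:
            r = (rows.start + rows.stop - 1) // 2
            length = cols.stop - cols.start
            n = length // interval_px + 1
            cs = np.minimum(cols.start + np.arange(n) * interval_px,
                            cols.stop - 1)
            pts = [(c, r) for c in cs]
        else:
            c = (cols.start + cols.stop - 1) // 2
            length = rows.stop - rows.start
            n = length // interval_px + 1
            rs = np.minimum(rows.start + np.arange(n) * interval_px,
                            rows.stop - 1)
            pts = [(c, r) for r in rs]
        for x, y in pts:
            if not refmap.mask[y, x]:
                continue
            pos.append((x, y))
            obs.append(rectified[y, x, :3])
            ref.append(refmap.image[y, x])
    return SamplePairs(np.asarray(pos, float), np.asarray(obs, float),
                       np.asarray(ref, float), spec.raster_shape)


# ----------------------------------------------------------------- fitting

def _design(order: int, xn, yn, intensity):
    one = np.ones_like(xn)
    if order == 0:
        alpha_cols = [intensity]
        beta_cols = [one]
    elif order == 1:
        alpha_cols = [xn * intensity, yn * intensity, intensity]
        beta_cols = [xn, yn, one]
    else:
        alpha_cols = [xn ** 2 * intensity, xn * yn * intensity,
                      yn ** 2 * intensity, xn * intensity, yn * intensity,
                      intensity]
        beta_cols = [xn ** 2, xn * yn, yn ** 2, xn, yn, one]
    return np.column_stack(alpha_cols + beta_cols)


def fit_correction(pairs: SamplePairs, order: int = 1) -> CorrectionModel:
    """Fit the per-channel correction model of the given order by OLS.

    A channel whose design matrix is rank deficient (e.g. the observed
    channel is constant, so the spatial-gain columns are collinear) falls
    back to an order-0 fit and is flagged in ``fallback_channels``.
    """
    if order not in _N_COEF:
        raise CorrectionError(f"unsupported order {order}")
    if len(pairs) < MIN_PAIRS[order]:
        raise CorrectionError(
            f"order {order} needs >= {MIN_PAIRS[order]} pairs, "
            f"got {len(pairs)}")
    xn, yn = _normalize_positions(pairs.positions, pairs.raster_shape)
    alpha, beta, resid, fallbacks = {}, {}, {}, []
    k = _N_COEF[order]
    for ci, ch in enumerate(CorrectionModel.CHANNELS):
        intensity = pairs.observed[:, ci]
        target = pairs.reference[:, ci]
        A = _design(order, xn, yn, intensity)
        use_order = order
        if order > 0 and np.linalg.matrix_rank(A) < A.shape[1]:
            use_order = 0
            A = _design(0, xn, yn, intensity)
            fallbacks.append(ch)
        coef, _, rank, _ = np.linalg.lstsq(A, target, rcond=None)
        if use_order == 0 and rank < 2:
            # even the global fit is degenerate (constant observed == target?)
            coef = np.array([1.0, float(np.mean(target - intensity))])
        kk = _N_COEF[use_order]
        alpha[ch] = CoefficientSurface(use_order, coef[:kk])
        beta[ch] = CoefficientSurface(use_order, coef[kk:])
        resid[ch] = float(np.sqrt(np.mean((A @ coef - target) ** 2)))
    return CorrectionModel(order=order, alpha=alpha, beta=beta,
                           raster_shape=pairs.raster_shape,
                           residual_rms=resid,
                           fallback_channels=tuple(fallbacks))


def apply_correction(model: CorrectionModel, image: np.ndarray) -> np.ndarray:
    """Apply ``out = alpha(x, y) * in + beta(x, y)`` per channel, clamped."""
    img = np.asarray(image, dtype=float)
    if img.ndim != 3 or img.shape[-1] < 3:
        raise CorrectionError("expected an RGB image")
    a, b = model.coefficient_maps(img.shape[:2])
    out = a * img[..., :3] + b
    return np.clip(np.round(out), 0, 255).astype(np.uint8)


def fit_color_checker_baseline(pairs: SamplePairs) -> CorrectionModel:
    """Order-0 fit on exactly 24 pairs, emulating a 24-patch color checker.

    A color checker provides a couple dozen discrete patches and a single
    global linear map; subsampling the stripes to 24 points reproduces that
    baseline for comparison against the spatially varying models.
    """
    if len(pairs) != 24:
        raise CorrectionError(
            f"color-checker baseline requires exactly 24 pairs, "
            f"got {len(pairs)}")
    return fit_correction(pairs, order=0)


def subsample_pairs(pairs: SamplePairs, count: int = 24) -> SamplePairs:
    """Evenly subsample pairs (spread over all stripes) for the baseline."""
    if len(pairs) < count:
        raise CorrectionError(f"cannot subsample {count} from {len(pairs)}")
    idx = np.round(np.linspace(0, len(pairs) - 1, count)).astype(int)
    return SamplePairs(pairs.positions[idx], pairs.observed[idx],
                       pairs.reference[idx], pairs.raster_shape)


def histogram_match(image: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Non-parametric per-channel histogram matching baseline."""
    img = np.asarray(image)
    ref = np.asarray(reference)
    if img.shape != ref.shape:
        raise CorrectionError("image and reference must share dimensions")
    out = match_histograms(img.astype(float), ref.astype(float),
                           channel_axis=-1)
    return np.clip(np.round(out), 0, 255).astype(np.uint8)
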