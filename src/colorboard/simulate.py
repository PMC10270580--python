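"""Synthetic scenes: color mosaics, illumination distortion, oblique views.

No photographs are needed to exercise the pipeline.  A random color mosaic
stands in for the "object of interest" in the board's sample region; an
illumination model distorts the scene; a projective renderer produces oblique
views of the planar board.  The illumination model is

    out_c(p) = g_c(T) * (1 + m * (d . p_norm - 0.5)) * in_c(p) + eps

with per-channel gains ``g_c(T)`` derived from a blackbody illuminant at
color temperature ``T`` (normalized so ~6500 K is neutral), a linear gain
ramp of fractional span ``m`` along unit direction ``d`` over the normalized
pixel grid, and i.i.d. Gaussian sensor noise ``eps``.  This spans the study
conditions (color temperature x lighting direction x noise) while keeping an
exact ground truth; it deliberately contains the order-1 spatially varying
affine family that the correction model fits.

Blackbody gains go Planck spectrum -> CIE 1931 XYZ (2-degree observer via
the multi-lobe Gaussian analytic fit of the color-matching functions) ->
linear sRGB, ratioed against 6500 K and normalized to unit mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.transform import ProjectiveTransform, warp

from .board import BoardSpec, ReferenceColorMap, render_board
from .geometry import CameraIntrinsics, KeyPointSet, optimal_height


class SimulationError(ValueError):
    pass


# ----------------------------------------------------------------- blackbody

def _piecewise_gauss(lam, mu, s1, s2):
    s = np.where(lam < mu, s1, s2)
    return np.exp(-0.5 * ((lam - mu) / s) ** 2)


def cie_cmf(lam: np.ndarray) -> np.ndarray:
    """Analytic fit of the CIE 1931 2-degree color-matching functions.

    Multi-lobe Gaussian approximation (per-lobe piecewise sigmas); accurate
    to a few percent, ample for deriving relative channel gains.
    """
    x = (1.056 * _piecewise_gauss(lam, 599.8, 37.9, 31.0)
         + 0.362 * _piecewise_gauss(lam, 442.0, 16.0, 26.7)
         - 0.065 * _piecewise_gauss(lam, 501.1, 20.4, 26.2))
    y = (0.821 * _piecewise_gauss(lam, 568.8, 46.9, 40.5)
         + 0.286 * _piecewise_gauss(lam, 530.9, 16.3, 31.1))
    z = (1.217 * _piecewise_gauss(lam, 437.0, 11.8, 36.0)
         + 0.681 * _piecewise_gauss(lam, 459.0, 26.0, 13.8))
    return np.stack([x, y, z], axis=-1)


_XYZ2RGB = np.array([[3.2404542, -1.5371385, -0.4985314],
                     [-0.9692660, 1.8760108, 0.0415560],
                     [0.0556434, -0.2040259, 1.0572252]])


def _blackbody_linear_rgb(temperature_K: float) -> np.ndarray:
    lam = np.arange(380.0, 781.0, 1.0)          # nm
    lm = lam * 1e-9
    h, c, kb = 6.62607015e-34, 2.99792458e8, 1.380649e-23
    spectrum = 1.0 / (lm ** 5 * np.expm1(h * c / (lm * kb * temperature_K)))
    xyz = (cie_cmf(lam) * spectrum[:, None]).sum(axis=0)
    rgb = _XYZ2RGB @ (xyz / xyz[1])
    return np.clip(rgb, 1e-6, None)


def blackbody_gains(temperature_K: float) -> np.ndarray:
    """Per-channel RGB gains of a blackbody illuminant at T kelvin.

    Ratioed against the 6500 K response and normalized to unit mean, so 6500 K
    gives (1, 1, 1) and 2800 K boosts red over blue.
    """
    if not 1000.0 <= temperature_K <= 20000.0:
        raise SimulationError("color temperature outside [1000, 20000] K")
    g = _blackbody_linear_rgb(temperature_K) / _blackbody_linear_rgb(6500.0)
    return g / g.mean()


# ----------------------------------------------------------------- mosaics

@dataclass
class Mosaic:
    """A rows x cols grid of random reference colors."""
    rows: int
    cols: int
    cells: np.ndarray  # (rows, cols, 3) uint8
    seed: int | None = None


def generate_mosaic(rows: int = 44, cols: int = 24,
                    seed: int | None = None) -> Mosaic:
    """Uniform-random RGB mosaic, reproducible under ``seed``."""
    if rows < 1 or cols < 1:
        raise SimulationError("mosaic dimensions must be positive")
    rng = np.random.default_rng(seed)
    cells = rng.integers(0, 256, size=(rows, cols, 3), dtype=np.int64)
    return Mosaic(rows=rows, cols=cols, cells=cells.astype(np.uint8),
                  seed=seed)


def compose_scene(spec: BoardSpec, refmap: ReferenceColorMap,
                  mosaic: Mosaic) -> np.ndarray:
    """Ground-truth board image with the mosaic tiling the sample region.

    Stripe pixels take the reference-map colors; mosaic cells are laid out
    row-major from the top-left of the sample region with equal integer tile
    sizes (remainder pixels keep the board background).
    """
    img = render_board(spec)
    img[refmap.mask] = refmap.image[refmap.mask]
    rows, cols = spec.rect_to_slices(spec.sample_region_mm)
    rh, rw = rows.stop - rows.start, cols.stop - cols.start
    th, tw = rh // mosaic.rows, rw // mosaic.cols
    if th < 1 or tw < 1:
        raise SimulationError(
            f"{mosaic.rows}x{mosaic.cols} mosaic does not fit the "
            f"{rh}x{rw} px sample region")
    tiled = np.repeat(np.repeat(mosaic.cells, th, axis=0), tw, axis=1)
    img[rows.start:rows.start + th * mosaic.rows,
        cols.start:cols.start + tw * mosaic.cols] = tiled
    return img


def mosaic_center_mask(spec: BoardSpec, mosaic: Mosaic) -> np.ndarray:
    """One evaluation pixel per mosaic cell (the tile centre).

    Mirrors the evaluation protocol of sampling a single pixel per cell to
    cover the color space, and keeps tile-edge resampling artifacts out of
    the metric.
    """
    mask = np.zeros(spec.raster_shape, dtype=bool)
    rows, cols = spec.rect_to_slices(spec.sample_region_mm)
    th = (rows.stop - rows.start) // mosaic.rows
    tw = (cols.stop - cols.start) // mosaic.cols
    rr = rows.start + np.arange(mosaic.rows) * th + th // 2
    cc = cols.start + np.arange(mosaic.cols) * tw + tw // 2
    mask[np.ix_(rr, cc)] = True
    return mask


def mosaic_mask(spec: BoardSpec, mosaic: Mosaic) -> np.ndarray:
    """Pixels of the board raster covered by mosaic tiles."""
    mask = np.zeros(spec.raster_shape, dtype=bool)
    rows, cols = spec.rect_to_slices(spec.sample_region_mm)
    th = (rows.stop - rows.start) // mosaic.rows
    tw = (cols.stop - cols.start) // mosaic.cols
    mask[rows.start:rows.start + th * mosaic.rows,
         cols.start:cols.start + tw * mosaic.cols] = True
    return mask


# ------------------------------------------------------------- illumination

@dataclass(frozen=True)
class IlluminationCondition:
    """One simulated lighting condition."""
    color_temperature_K: float = 6500.0
    gradient_direction: tuple[float, float] = (1.0, 0.0)
    gradient_magnitude: float = 0.0   # fractional gain span across the board
    noise_sd: float = 0.0             # Gaussian sensor noise, intensity levels
    exposure: float = 1.0             # global gain (camera exposure), > 0

    def __post_init__(self) -> None:
        if not 1000.0 <= self.color_temperature_K <= 20000.0:
            raise SimulationError("temperature outside [1000, 20000] K")
        if not 0.0 <= self.gradient_magnitude < 1.0:
            raise SimulationError("gradient magnitude must lie in [0, 1)")
        n = np.hypot(*self.gradient_direction)
        if self.gradient_magnitude > 0 and n == 0:
            raise SimulationError("gradient direction must be a nonzero vector")
        if self.exposure <= 0:
            raise SimulationError("exposure must be positive")


def simulate_illumination(scene: np.ndarray,
                          condition: IlluminationCondition,
                          seed: int | None = None) -> np.ndarray:
    """Apply the blackbody-gain + linear-ramp + Gaussian-noise distortion."""
    img = np.asarray(scene, dtype=float)
    h, w = img.shape[:2]
    g = condition.exposure * blackbody_gains(condition.color_temperature_K)
    out = img[..., :3] * g[None, None, :]
    if condition.gradient_magnitude > 0:
        d = np.asarray(condition.gradient_direction, float)
        d = d / np.linalg.norm(d)
        xn, yn = np.meshgrid(np.linspace(0, 1, w), np.linspace(0, 1, h))
        proj = d[0] * xn + d[1] * yn
        span = proj.max() - proj.min()
        proj = (proj - proj.min()) / span if span > 0 else proj * 0 + 0.5
        ramp = 1.0 + condition.gradient_magnitude * (proj - 0.5)
        out = out * ramp[..., None]
    if condition.noise_sd > 0:
        rng = np.random.default_rng(seed)
        out = out + rng.normal(0.0, condition.noise_sd, size=out.shape)
    return np.clip(np.round(out), 0, 255).astype(np.uint8)


def study_conditions(temperatures=(2800.0, 4000.0, 6500.0),
                     directions=((1.0, 0.0), (0.0, 1.0), (1.0, 1.0)),
                     magnitude: float = 0.2,
                     noise_sd: float = 2.0) -> list[IlluminationCondition]:
    """The 3 x 3 temperature-by-direction grid of study conditions."""
    return [IlluminationCondition(color_temperature_K=t,
                                  gradient_direction=d,
                                  gradient_magnitude=magnitude,
                                  noise_sd=noise_sd)
            for t in temperatures for d in directions]


# ------------------------------------------------------------ oblique views

@dataclass
class RenderedScene:
    """An oblique camera view of the board plus its ground truth."""
    image: np.ndarray               # rendered (distorted) view, uint8
    truth: np.ndarray               # the fronto-parallel board image
    keypoints: KeyPointSet          # true projected marker corners
    viewing_angle_deg: float
    condition: IlluminationCondition | None = None
    homography: np.ndarray = field(default_factory=lambda: np.eye(3))


def _look_at_rotation(forward: np.ndarray) -> np.ndarray:
    f = forward / np.linalg.norm(forward)
    right = np.cross(f, np.array([0.0, 1.0, 0.0]))
    right /= np.linalg.norm(right)
    down = np.cross(f, right)
    return np.vstack([right, down, f])


def view_homography(spec: BoardSpec, angle_deg: float,
                    intrinsics: CameraIntrinsics,
                    image_shape: tuple[int, int],
                    distance_factor: float = 1.2) -> np.ndarray:
    """Homography from board raster (x, y) px to camera image (x, y) px.

    The camera sits at ``distance_factor`` times the optimal height from the
    board centre, at elevation ``angle_deg`` above the board plane (90 deg =
    straight overhead), approaching from the board's -y side.
    """
    theta = np.deg2rad(angle_deg)
    W, Hmm = spec.board_width_mm, spec.board_height_mm
    centre = np.array([W / 2, Hmm / 2, 0.0])
    h, w = image_shape
    dist = distance_factor * optimal_height(intrinsics, (w, h), spec)
    C = centre + dist * np.array([0.0, -np.cos(theta), np.sin(theta)])
    R = _look_at_rotation(centre - C)
    K = intrinsics.K
    H_world = K @ np.column_stack([R[:, 0], R[:, 1], -R @ C])
    ppm = spec.px_per_mm
    # raster (x, y) -> world (x, y) on the plane (pixel-centre convention)
    A = np.array([[1.0 / ppm, 0.0, 0.5 / ppm],
                  [0.0, -1.0 / ppm, Hmm - 0.5 / ppm],
                  [0.0, 0.0, 1.0]])
    H = H_world @ A
    return H / H[2, 2]


def render_view(board_image: np.ndarray, angle_deg: float,
                intrinsics: CameraIntrinsics, spec: BoardSpec, *,
                image_shape: tuple[int, int] = (600, 800),
                distance_factor: float = 1.2,
                background: float = 0.85,
                supersample: int = 3) -> RenderedScene:
    """Render the board as seen from an oblique elevation angle.

    The planar board is warped by the view homography and shaded by the
    Lambertian factor sin(angle) relative to the overhead view (a matte
    surface lit from above loses apparent irradiance with the cosine of the
    incidence angle; at 90 degrees the factor is 1).
    """
    if not 0.0 < angle_deg <= 90.0:
        raise SimulationError("viewing angle must lie in (0, 90] degrees")
    H = view_homography(spec, angle_deg, intrinsics, image_shape,
                        distance_factor)
    img = np.asarray(board_image, dtype=float) / 255.0
    # Sensor pixels integrate over their board-plane footprint: when the view
    # minifies the board, prefilter it accordingly (mipmap-style) so oblique
    # renders genuinely lose the detail a real camera would lose.
    rows, cols = spec.raster_shape
    centre = np.array([cols / 2.0, rows / 2.0, 1.0])
    u = H @ centre
    eps = 1.0
    jx = (H @ (centre + [eps, 0, 0]))
    jy = (H @ (centre + [0, eps, 0]))
    J = np.column_stack([jx[:2] / jx[2] - u[:2] / u[2],
                         jy[:2] / jy[2] - u[:2] / u[2]]) / eps
    sig = []
    for axis in (1, 0):  # board y (rows) then x (cols)
        s = np.linalg.norm(J[:, 1 - axis])
        sig.append(0.5 * np.sqrt(max(1.0 / s ** 2 - 1.0, 0.0)) if s < 1 else 0.0)
    if max(sig) > 0:
        from scipy.ndimage import gaussian_filter
        img = gaussian_filter(img, sigma=(sig[0], sig[1], 0.0),
                              mode="nearest")
    # Supersample the warp and box-average down: emulates the area
    # integration of a sensor pixel and suppresses resampling phase jitter.
    ss = int(supersample)
    Hs = np.diag([ss, ss, 1.0]) @ H
    tf = ProjectiveTransform(matrix=np.linalg.inv(Hs))
    big = warp(img, tf, output_shape=(image_shape[0] * ss,
                                      image_shape[1] * ss),
               order=1, mode="constant", cval=background)
    out = big.reshape(image_shape[0], ss, image_shape[1], ss,
                      -1).mean(axis=(1, 3))
    out = out * np.sin(np.deg2rad(angle_deg))
    view = np.clip(np.round(out * 255.0), 0, 255).astype(np.uint8)

    world = spec.keypoint_world()
    ids, cidx, img_pts, wrd_pts = [], [], [], []
    for (mid, k), wpt in sorted(world.items()):
        raster = spec.world_to_raster(wpt)[0]
        uvw = H @ np.array([raster[0], raster[1], 1.0])
        ids.append(mid)
        cidx.append(k)
        img_pts.append(uvw[:2] / uvw[2])
        wrd_pts.append([wpt[0], wpt[1], 0.0])
    kps = KeyPointSet(np.asarray(ids), np.asarray(cidx),
                      np.asarray(img_pts), np.asarray(wrd_pts))
    return RenderedScene(image=view, truth=np.asarray(board_image),
                         keypoints=kps, viewing_angle_deg=angle_deg,
                         homography=H)
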