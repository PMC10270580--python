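"""End-to-end pipelines: photo -> rectified -> corrected -> metrics / pH.

Each stage failure raises :class:`PipelineError` carrying the stage name so a
caller (or the CLI) can report exactly where a capture went wrong.  Given the
same inputs and seed the pipelines are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .board import BoardSpec, ReferenceColorMap, stripe_mask
from .colorimetry import MetricReport, PHReferenceCurve, compute_mrmse, read_ph
from .correction import (CorrectionModel, apply_correction, fit_correction,
                         sample_pairs)
from .geometry import (CameraIntrinsics, GeometryError, detect_keypoints,
                       guidance, rectify, solve_pose)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclass
class PipelineConfig:
    """Knobs for the capture-to-measurement pipelines."""
    order: int = 1
    interval_px: int = 10
    epsilon_px: float = 20.0
    height_range: tuple[float, float] = (1.0, 1.5)
    intrinsics: CameraIntrinsics | None = None


@dataclass
class PipelineResult:
    rectified: np.ndarray
    corrected: np.ndarray
    model: CorrectionModel
    report: MetricReport
    log: list[dict[str, Any]] = field(default_factory=list)


def run_correction_pipeline(image: np.ndarray, spec: BoardSpec,
                            refmap: ReferenceColorMap,
                            config: PipelineConfig | None = None
                            ) -> PipelineResult:
    """detect -> (pose/guidance) -> rectify -> sample -> fit -> apply -> score.

    Metrics are computed on the stripe pixels against the reference map; the
    returned log records each stage's key numbers.
    """
    cfg = config or PipelineConfig()
    log: list[dict[str, Any]] = []

    points = detect_keypoints(image, spec)
    if len(points) == 0:
        raise PipelineError("detect", "no markers found in image")
    log.append({"stage": "detect", "n_points": len(points)})

    if cfg.intrinsics is not None:
        try:
            pose = solve_pose(points, cfg.intrinsics)
            h, w = np.asarray(image).shape[:2]
            gate = guidance(pose, cfg.intrinsics, spec, (w, h),
                            epsilon_px=cfg.epsilon_px,
                            height_range=cfg.height_range)
            log.append({"stage": "pose",
                        "reprojection_rms": pose.reprojection_rms,
                        "height_ratio": gate.height_ratio,
                        "accepted": gate.accepted})
        except GeometryError as exc:
            raise PipelineError("pose", str(exc)) from exc

    try:
        rect = rectify(image, points, spec)
    except GeometryError as exc:
        raise PipelineError("rectify", str(exc)) from exc
    log.append({"stage": "rectify", "shape": rect.shape[:2]})

    try:
        pairs = sample_pairs(rect, refmap, spec, cfg.interval_px)
        model = fit_correction(pairs, order=cfg.order)
    except ValueError as exc:
        raise PipelineError("fit", str(exc)) from exc
    log.append({"stage": "fit", "n_pairs": len(pairs),
                "order": cfg.order,
                "residual_rms": model.residual_rms,
                "fallback_channels": list(model.fallback_channels)})

    corrected = apply_correction(model, rect)
    report = compute_mrmse(corrected, refmap.image, stripe_mask(spec))
    log.append({"stage": "evaluate", "mrmse": report.mrmse,
                "rmse": report.rmse})
    return PipelineResult(rectified=rect, corrected=corrected, model=model,
                          report=report, log=log)


def sample_region_mask(spec: BoardSpec, fraction: float = 0.5) -> np.ndarray:
    """Centered patch covering ``fraction`` of each sample-region dimension.

    Measuring the strip color away from the region's borders avoids board
    background and object edges.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must lie in (0, 1]")
    x0, y0, w, h = spec.sample_region_mm
    mx, my = w * (1 - fraction) / 2, h * (1 - fraction) / 2
    rows, cols = spec.rect_to_slices((x0 + mx, y0 + my,
                                      w - 2 * mx, h - 2 * my))
    mask = np.zeros(spec.raster_shape, dtype=bool)
    mask[rows, cols] = True
    return mask


def run_ph_pipeline(image: np.ndarray, spec: BoardSpec,
                    refmap: ReferenceColorMap, curve: PHReferenceCurve,
                    config: PipelineConfig | None = None,
                    mask: np.ndarray | None = None
                    ) -> tuple[float, PipelineResult]:
    """Correction pipeline, then pH from the sample-region mean color."""
    result = run_correction_pipeline(image, spec, refmap, config)
    if mask is None:
        mask = sample_region_mask(spec)
    if not mask.any():
        raise PipelineError("read-ph", "empty sample mask")
    mean_rgb = result.corrected[mask].mean(axis=0)
    ph = read_ph(mean_rgb, curve)
    result.log.append({"stage": "read-ph", "mean_rgb": mean_rgb.tolist(),
                       "ph": ph})
    return ph, result
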