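"""Validated run configuration and the end-to-end pipeline.

One call runs the full chain the reader implements in hardware:
acquisition (simulated or from file) -> morphological filtering ->
per-half entropy-Otsu segmentation -> line feature extraction -> T/C
result, optionally wrapped in the automatic exposure-adjustment loop.
The report contains every intermediate diagnostic and is byte-deterministic
for a fixed seed.
"""

from __future__ import annotations

import dataclasses
import json
import math
from typing import Literal

import numpy as np
from pydantic import BaseModel, ConfigDict

from . import virtual_assay as va
from .autoexposure import ExposureConfig, auto_adjust
from .errors import FicaError, StageError
from .quantify import QuantifyConfig, analyze_image
from .segmentation import SegmentationResult

__all__ = ["RunConfig", "run_pipeline", "report_to_json"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class CameraSettings(_Strict):
    dark_level: float = 3.480
    gain: float = 0.547
    t_linear_max: float = 400.0
    bit_depth: int = 8
    read_noise_sigma: float = 1.0
    impulse_noise_prob: float = 0.002


class AssaySettings(_Strict):
    concentration: float = 31.25   # ug/mL
    width: int = 200
    height: int = 80
    t_center: float = 50.0
    c_center: float = 150.0
    half_width: float = 18.0
    profile: Literal["rectangular", "gaussian"] = "rectangular"
    background_radiance: float = 0.02
    c_line_concentration: float = 0.8
    map_slope: float = 0.023
    map_intercept: float = 0.081


class ControllerSettings(_Strict):
    enabled: bool = True
    g_target: float = 230.0
    t_init: float = 100.0
    t_min: float = 1.0
    t_max: float = 400.0
    max_iterations: int = 8
    tolerance: float = 10.0
    saturation_fraction_limit: float = 0.05


class RunConfig(_Strict):
    """Full configuration of a simulated (or file-backed) pipeline run."""

    seed: int = 0
    layout: Literal["t-left", "t-right"] = "t-left"
    exposure_ms: float = 100.0      # fixed-protocol exposure when controller off
    saturation_fraction_limit: float = 0.05
    min_signal_gray: float = 5.0
    selem_size: int = 3
    camera: CameraSettings = CameraSettings()
    assay: AssaySettings = AssaySettings()
    controller: ControllerSettings = ControllerSettings()

    def camera_model(self) -> va.CameraModel:
        return va.CameraModel(**self.camera.model_dump(), rng_seed=self.seed)

    def assay_config(self) -> va.AssayConfig:
        params = self.assay.model_dump()
        params.pop("concentration")
        return va.AssayConfig(**params)

    def quantify_config(self) -> QuantifyConfig:
        return QuantifyConfig(
            saturation_fraction_limit=self.saturation_fraction_limit,
            min_signal_gray=self.min_signal_gray,
            layout=self.layout,
        )

    def exposure_config(self) -> ExposureConfig:
        c = self.controller.model_dump()
        c.pop("enabled")
        return ExposureConfig(**c)


def _seg_summary(seg: SegmentationResult | None) -> dict | None:
    if seg is None:
        return None
    return {
        "threshold": seg.threshold,
        "h_a": seg.h_a,
        "h_b": seg.h_b,
        "h_0": seg.h_0,
        "criterion_at_threshold": float(seg.criterion_curve[seg.threshold]),
        "foreground_pixels": int(seg.mask.sum()) if seg.mask is not None else None,
    }


def _nan_to_none(x: float) -> float | None:
    return None if x is None or (isinstance(x, float) and math.isnan(x)) else x


def run_pipeline(config: RunConfig, image: va.StripImage | None = None) -> dict:
    """Run the pipeline on a supplied image or a freshly simulated strip.

    Returns a JSON-serializable report with per-stage diagnostics.  Errors
    are re-raised as :class:`StageError` naming the failing stage.
    """
    report: dict = {"config": json.loads(config.model_dump_json())}
    camera = config.camera_model()
    try:
        quantify_cfg = config.quantify_config()
    except FicaError as exc:
        raise StageError("configure", exc) from exc

    trace = None
    if image is None:
        try:
            scene = va.build_scene(config.assay.concentration, config.assay_config())
        except FicaError as exc:
            raise StageError("simulate", exc) from exc
        if config.controller.enabled:
            try:
                image, tc, trace = auto_adjust(
                    scene, camera, config.exposure_config(), quantify_cfg
                )
            except FicaError as exc:
                raise StageError("autoexpose", exc) from exc
        else:
            try:
                image = va.capture(scene, camera, config.exposure_ms)
            except FicaError as exc:
                raise StageError("capture", exc) from exc

    try:
        tc, seg_left, seg_right = analyze_image(
            image, quantify_cfg, selem_size=config.selem_size
        )
    except FicaError as exc:
        raise StageError("analyze", exc) from exc

    report["image"] = {
        "exposure_ms": _nan_to_none(image.exposure_ms),
        "bit_depth": image.bit_depth,
        "shape": list(image.pixels.shape),
        "saturated_fraction": image.saturated_fraction,
        "beyond_linear_range": image.beyond_linear_range,
    }
    report["segmentation"] = {
        "left": _seg_summary(seg_left),
        "right": _seg_summary(seg_right),
    }
    report["features"] = {
        name: None if feat is None else dataclasses.asdict(feat)
        for name, feat in (("t_line", tc.t_feature), ("c_line", tc.c_feature))
    }
    report["result"] = {
        "ratio": _nan_to_none(tc.ratio),
        "valid": tc.valid,
        "invalid_reason": tc.invalid_reason,
    }
    if trace is not None:
        report["exposure_trace"] = {
            "steps": [
                {"t_ms": t, "g": _nan_to_none(g), "action": a}
                for t, g, a in trace.steps
            ],
            "final_t_ms": trace.final_t,
            "outcome": trace.outcome,
        }
    return report


def report_to_json(report: dict) -> str:
    """Canonical JSON rendering (sorted keys) so identical runs are
    byte-identical."""
    return json.dumps(report, sort_keys=True, indent=2, allow_nan=False)
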