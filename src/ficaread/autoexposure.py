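"""Closed-loop automatic exposure-range adjustment.

The controller drives the mean gray of the target region — the brighter of
the two segmented lines, so that neither line clips — to a target level G_M
near the top of the 8-bit range.  Because gray minus the dark offset is
proportional to exposure time within the sensor's linear range, one
proportional step

    t_next = clamp( (G_M - dark) / (G - dark) * t, t_min, t_max )

is exact for a noiseless unclipped scene; iteration only mops up
quantization and noise.  Saturated captures are handled by halving the
exposure before the proportional rule is trusted (a clipped mean
underestimates the true brightness, so the ratio step would overshoot).
The exposure never exceeds ``t_max``, the sensor's linear limit (400 ms for
the default camera): beyond it gray is no longer proportional to exposure
and the T/C cancellation would be distorted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import DomainError, NoSignalError
from .quantify import QuantifyConfig, TCResult, analyze_image
from .virtual_assay import CameraModel, FluorescenceModel, StripImage, StripScene, capture

__all__ = ["ExposureConfig", "ExposureTrace", "plan_exposure", "auto_adjust"]


@dataclass(frozen=True)
class ExposureConfig:
    g_target: float = 230.0       # G_M: target mean gray of the brighter line
    t_init: float = 100.0         # ms
    t_min: float = 1.0            # ms
    t_max: float = 400.0          # ms; the sensor's linear limit
    max_iterations: int = 8
    tolerance: float = 10.0       # gray units
    saturation_fraction_limit: float = 0.05

    def __post_init__(self):
        if not 0 < self.t_min <= self.t_init <= self.t_max:
            raise DomainError("need 0 < t_min <= t_init <= t_max")
        if self.g_target <= 0 or self.max_iterations < 1:
            raise DomainError("g_target and max_iterations must be positive")


@dataclass(frozen=True)
class ExposureTrace:
    """(exposure, measured G, action) per iteration plus the outcome."""

    steps: "list[tuple[float, float, str]]"
    final_t: float
    outcome: str   # converged | below_range | above_range | iteration_limit


def plan_exposure(
    t: float, g: float, config: ExposureConfig, dark_level: float = 0.0
) -> float:
    """One proportional exposure step, clamped to the allowed range.

    The dark offset is removed before forming the ratio: proportionality
    between gray and exposure holds only for the signal above dark.
    """
    if not config.t_min <= t <= config.t_max:
        raise DomainError(f"exposure {t} ms outside [{config.t_min}, {config.t_max}]")
    if g <= dark_level:
        raise NoSignalError(
            f"target gray {g} does not exceed the dark level {dark_level}"
        )
    k = (config.g_target - dark_level) / (g - dark_level)
    return float(min(max(k * t, config.t_min), config.t_max))


def _brighter_feature(tc: TCResult):
    feats = [f for f in (tc.t_feature, tc.c_feature) if f is not None]
    if not feats:
        return None
    return max(feats, key=lambda f: f.mean_gray_fg)


def auto_adjust(
    scene_or_capture_fn,
    camera: CameraModel,
    config: ExposureConfig = ExposureConfig(),
    quantify_config: QuantifyConfig = QuantifyConfig(),
    fmodel: FluorescenceModel = FluorescenceModel(),
) -> "tuple[StripImage, TCResult, ExposureTrace]":
    """Run the exposure-adjustment loop and analyze the final capture.

    ``scene_or_capture_fn`` is either a :class:`StripScene` (captured through
    the simulator with per-iteration RNG streams derived from the camera
    seed) or a callable ``f(exposure_ms) -> StripImage`` (e.g. a lookup into
    a pre-captured exposure stack).
    """
    if isinstance(scene_or_capture_fn, StripScene):
        scene = scene_or_capture_fn
        seeds = np.random.SeedSequence(camera.rng_seed).spawn(config.max_iterations)

        def capture_fn(t_ms: float, iteration: int = 0) -> StripImage:
            return capture(
                scene, camera, t_ms, fmodel, rng=np.random.default_rng(seeds[iteration])
            )

    else:
        raw_fn = scene_or_capture_fn

        def capture_fn(t_ms: float, iteration: int = 0) -> StripImage:
            return raw_fn(t_ms)

    steps: list[tuple[float, float, str]] = []
    t = float(config.t_init)
    image = None
    tc = None
    outcome = "iteration_limit"
    for it in range(config.max_iterations):
        image = capture_fn(t, it)
        tc, _, _ = analyze_image(image, quantify_config)
        feat = _brighter_feature(tc)

        if feat is None:  # degenerate segmentation: no line found at all
            steps.append((t, float("nan"), "no-signal"))
            if t < config.t_max:
                t = min(2 * t, config.t_max)   # seek signal at longer exposure
                continue
            outcome = "below_range"
            break

        g = feat.mean_gray_fg
        if feat.saturated_fraction_fg > config.saturation_fraction_limit:
            if t > config.t_min:
                steps.append((t, g, "halve"))
                t = max(t / 2.0, config.t_min)
                continue
            steps.append((t, g, "stop"))
            outcome = "above_range"
            break

        if abs(g - config.g_target) <= config.tolerance:
            steps.append((t, g, "converged"))
            outcome = "converged"
            break

        try:
            t_next = plan_exposure(t, g, config, dark_level=camera.dark_level)
        except NoSignalError:
            steps.append((t, g, "no-signal"))
            if t < config.t_max:
                t = min(2 * t, config.t_max)
                continue
            outcome = "below_range"
            break

        if math.isclose(t_next, t):   # clamped at a bound: target unreachable
            steps.append((t, g, "stop"))
            outcome = "below_range" if g < config.g_target else "above_range"
            break
        steps.append((t, g, "scale"))
        t = t_next

    final_t = image.exposure_ms if image is not None else t
    trace = ExposureTrace(steps=steps, final_t=final_t, outcome=outcome)
    return image, tc, trace
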