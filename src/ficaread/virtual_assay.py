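"""Synthetic fluorescence strip scenes and a simulated 8-bit camera.

The simulator is the package's synthetic-data generator.  A strip scene is a
ground-truth radiance field: a uniform membrane background plus two
fluorescent line bands — the test (T) line, whose fluorophore surface
concentration tracks the analyte, and the control (C) line, whose
concentration is fixed by the assay chemistry.  Band radiance follows the
standard fluorometric proportionality

    I_f = k_f * C * i_x

with ``k_f`` a lumped gain (quantum yield, absorptivity, path length and the
LED current-to-intensity coefficient are not separately identifiable from
image data), ``C`` the fluorophore concentration and ``i_x`` the excitation
current.  The camera integrates radiance over the exposure time t
(photometric exposure H = E * t) and quantizes:

    gray = clip(round(dark_level + gain * radiance * t + noise), 0, 2^bits - 1)

The gray-versus-exposure response is linear only up to ``t_linear_max``
(400 ms for the default sensor, whose reference response is
G = 0.547 t + 3.480); beyond it the simulator applies a smooth compressive
roll-off so that controller logic can be tested against violating the bound.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import DomainError

__all__ = [
    "FluorescenceModel",
    "LineBand",
    "StripScene",
    "CameraModel",
    "StripImage",
    "AssayConfig",
    "DEFAULT_ASSAY",
    "build_scene",
    "radiance_field",
    "capture",
    "calibration_series",
]


@dataclass(frozen=True)
class FluorescenceModel:
    """Lumped fluorescence response: band radiance = k_f * C * i_x."""

    k_f: float = 1.0   # radiance per (concentration x current)
    i_x: float = 1.0   # excitation current, normalized

    def __post_init__(self):
        if not self.k_f > 0:
            raise DomainError(f"k_f must be positive, got {self.k_f}")
        if not self.i_x > 0:
            raise DomainError(f"i_x must be positive, got {self.i_x}")


@dataclass(frozen=True)
class LineBand:
    """A vertical fluorescent line on the strip.

    ``profile`` is "rectangular" (flat plateau of half-width ``half_width``
    columns, the printed-line default) or "gaussian" (``half_width`` acts as
    the profile sigma).
    """

    center_x: float
    fluorophore_concentration: float
    half_width: float = 6.0
    profile: str = "rectangular"

    def __post_init__(self):
        if self.fluorophore_concentration < 0:
            raise DomainError("band concentration must be >= 0")
        if self.half_width <= 0:
            raise DomainError("band half_width must be positive")
        if self.profile not in ("rectangular", "gaussian"):
            raise DomainError(f"unknown profile {self.profile!r}")

    def column_profile(self, width: int) -> np.ndarray:
        """Unit-amplitude profile over image columns."""
        x = np.arange(width, dtype=float)
        if self.profile == "rectangular":
            return (np.abs(x - self.center_x) <= self.half_width).astype(float)
        return np.exp(-0.5 * ((x - self.center_x) / self.half_width) ** 2)


@dataclass(frozen=True)
class StripScene:
    """Ground-truth radiance description of one strip."""

    width: int
    height: int
    background_radiance: float
    t_line: LineBand
    c_line: LineBand
    analyte_concentration: float = float("nan")

    def __post_init__(self):
        if self.width < 2 or self.height < 1:
            raise DomainError("scene must be at least 2 px wide and 1 px tall")
        if self.background_radiance < 0:
            raise DomainError("background radiance must be >= 0")
        mid = self.width // 2
        halves = {self._half_of(self.t_line, mid), self._half_of(self.c_line, mid)}
        if halves != {"left", "right"}:
            raise DomainError(
                "T and C bands must lie fully in opposite halves of the strip"
            )

    def _half_of(self, band: LineBand, mid: int) -> str:
        # rectangular extent (or 3-sigma extent for gaussian bands) must not
        # cross the split
        reach = band.half_width * (1 if band.profile == "rectangular" else 3)
        lo = band.center_x - reach
        hi = band.center_x + reach
        if self.profile_extent_ok(lo, hi, 0, mid):
            return "left"
        if self.profile_extent_ok(lo, hi, mid, self.width):
            return "right"
        raise DomainError("band crosses the half-image split or the border")

    @staticmethod
    def profile_extent_ok(lo: float, hi: float, a: float, b: float) -> bool:
        return a <= lo and hi <= b


@dataclass(frozen=True)
class CameraModel:
    """Linear 8-bit sensor with dark offset and optional noise.

    ``gain`` is gray per (radiance x ms); the default sensor reproduces the
    reference response G = 0.547 t + 3.480 at unit radiance.  Gaussian read
    noise is added before quantization; impulse (salt-and-pepper) noise flips
    quantized pixels to 0 or full scale.
    """

    dark_level: float = 3.480
    gain: float = 0.547
    t_linear_max: float = 400.0
    bit_depth: int = 8
    read_noise_sigma: float = 0.0
    impulse_noise_prob: float = 0.0
    rng_seed: int = 0

    def __post_init__(self):
        if not 0 <= self.dark_level < 2 ** self.bit_depth:
            raise DomainError("dark_level must lie within the gray range")
        if self.gain <= 0 or self.t_linear_max <= 0:
            raise DomainError("gain and t_linear_max must be positive")
        if not 0 <= self.impulse_noise_prob < 1:
            raise DomainError("impulse_noise_prob must be in [0, 1)")
        if self.read_noise_sigma < 0:
            raise DomainError("read_noise_sigma must be >= 0")

    @property
    def max_gray(self) -> int:
        return 2 ** self.bit_depth - 1

    def effective_exposure(self, exposure_ms: float) -> float:
        """Linear up to t_linear_max, then a smooth logarithmic roll-off
        (continuous with continuous first derivative at the knee)."""
        t = float(exposure_ms)
        if t <= self.t_linear_max:
            return t
        return self.t_linear_max * (1.0 + np.log(t / self.t_linear_max))


@dataclass(frozen=True)
class StripImage:
    """Quantized gray image together with the exposure that produced it."""

    pixels: np.ndarray
    bit_depth: int
    exposure_ms: float
    saturated_fraction: float = field(default=None)  # type: ignore[assignment]
    beyond_linear_range: bool = False

    def __post_init__(self):
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise DomainError("pixels must be a 2-D array")
        maxg = 2 ** self.bit_depth - 1
        if px.min() < 0 or px.max() > maxg:
            raise DomainError("pixel values exceed the bit depth")
        if self.saturated_fraction is None:
            object.__setattr__(
                self, "saturated_fraction", float(np.mean(px == maxg))
            )

    @property
    def max_gray(self) -> int:
        return 2 ** self.bit_depth - 1

    def with_pixels(self, pixels: np.ndarray) -> "StripImage":
        """Same acquisition metadata, new pixel data (e.g. after filtering)."""
        return replace(self, pixels=pixels, saturated_fraction=None)


@dataclass(frozen=True)
class AssayConfig:
    """Default simulated assay: geometry, C-line load and the monotone
    analyte-concentration -> C_T map.

    The map is the calibration line of the reference assay
    (T/C = 0.023 x + 0.081, x in ug/mL, clamped at zero), so the simulator's
    ground-truth T/C ratio at analyte concentration x is exactly the value the
    calibrated reader should report.
    """

    width: int = 200
    height: int = 80
    t_center: float = 50.0
    c_center: float = 150.0
    half_width: float = 18.0
    profile: str = "rectangular"
    background_radiance: float = 0.02
    c_line_concentration: float = 0.8
    map_slope: float = 0.023     # (T/C) per (ug/mL)
    map_intercept: float = 0.081

    def concentration_to_ratio(self, analyte_concentration: float) -> float:
        """Ground-truth C_T/C_C for an analyte concentration in ug/mL."""
        return max(0.0, self.map_slope * analyte_concentration + self.map_intercept)


DEFAULT_ASSAY = AssayConfig()


def build_scene(
    analyte_concentration: float, assay: AssayConfig = DEFAULT_ASSAY
) -> StripScene:
    """Build the ground-truth scene for one strip at a given analyte level."""
    if analyte_concentration < 0:
        raise DomainError("analyte concentration must be >= 0")
    ratio = assay.concentration_to_ratio(analyte_concentration)
    c_conc = assay.c_line_concentration
    return StripScene(
        width=assay.width,
        height=assay.height,
        background_radiance=assay.background_radiance,
        t_line=LineBand(
            center_x=assay.t_center,
            fluorophore_concentration=ratio * c_conc,
            half_width=assay.half_width,
            profile=assay.profile,
        ),
        c_line=LineBand(
            center_x=assay.c_center,
            fluorophore_concentration=c_conc,
            half_width=assay.half_width,
            profile=assay.profile,
        ),
        analyte_concentration=analyte_concentration,
    )


def radiance_field(
    scene: StripScene, fmodel: FluorescenceModel = FluorescenceModel()
) -> np.ndarray:
    """Ground-truth radiance map: background plus both band profiles scaled
    by k_f * C * i_x.  Linear in each band's concentration and in i_x."""
    row = np.full(scene.width, scene.background_radiance, dtype=float)
    for band in (scene.t_line, scene.c_line):
        amplitude = fmodel.k_f * band.fluorophore_concentration * fmodel.i_x
        row = row + amplitude * band.column_profile(scene.width)
    return np.broadcast_to(row, (scene.height, scene.width)).copy()


def _round_half_away(x: np.ndarray) -> np.ndarray:
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def capture(
    scene: StripScene,
    camera: CameraModel,
    exposure_ms: float,
    fmodel: FluorescenceModel = FluorescenceModel(),
    rng: np.random.Generator | None = None,
) -> StripImage:
    """Simulate one exposure of the scene.

    Gaussian read noise is added to the pre-quantization gray; pixels are then
    rounded half-away-from-zero and clipped to the sensor range; impulse noise
    finally forces isolated pixels to 0 or full scale.  With ``rng`` omitted,
    the camera's own seed is used, so identical (scene, camera, exposure)
    yield bit-identical images.
    """
    if not exposure_ms > 0:
        raise DomainError("exposure must be positive")
    if rng is None:
        rng = np.random.default_rng(camera.rng_seed)
    t_eff = camera.effective_exposure(exposure_ms)
    gray = camera.dark_level + camera.gain * radiance_field(scene, fmodel) * t_eff
    if camera.read_noise_sigma > 0:
        gray = gray + rng.normal(0.0, camera.read_noise_sigma, size=gray.shape)
    px = np.clip(_round_half_away(gray), 0, camera.max_gray)
    if camera.impulse_noise_prob > 0:
        hit = rng.random(px.shape) < camera.impulse_noise_prob
        polarity = rng.random(px.shape) < 0.5
        px = np.where(hit, np.where(polarity, 0, camera.max_gray), px)
    dtype = np.uint8 if camera.bit_depth <= 8 else np.uint16
    return StripImage(
        pixels=px.astype(dtype),
        bit_depth=camera.bit_depth,
        exposure_ms=float(exposure_ms),
        beyond_linear_range=exposure_ms > camera.t_linear_max,
    )


def calibration_series(
    camera: CameraModel,
    exposures: "list[float]",
    reference_radiance: float = 1.0,
) -> "list[tuple[float, float]]":
    """Noiseless (exposure, mean pre-quantization gray) pairs at a uniform
    reference radiance — the gray-versus-exposure characterization used to
    fit the sensor line G = gain*radiance*t + dark_level."""
    if len(exposures) == 0:
        raise DomainError("need at least one exposure")
    if reference_radiance <= 0:
        raise DomainError("reference radiance must be positive")
    out = []
    for t in exposures:
        if not 0 < t <= camera.t_linear_max:
            raise DomainError(
                f"exposure {t} ms outside the linear range (0, {camera.t_linear_max}]"
            )
        out.append((float(t), camera.dark_level + camera.gain * reference_radiance * t))
    return out
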