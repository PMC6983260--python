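"""T/C quantification from segmented strip halves.

The characteristic value of a line is the mean gray of its segmented region
minus the mean gray of the rest of the half (floored at zero).  Subtracting
the local background removes the sensor dark offset and the membrane
contribution, which are additive and would otherwise break the cancellation
that makes the T/C ratio independent of exposure time and excitation
current:

    H_T / H_C = (k C_T i_x t) / (k C_C i_x t) = C_T / C_C .

A reading is flagged invalid rather than returned blindly when either line
region is saturated beyond a tolerated fraction (the sensor clipped, so the
mean underestimates the true brightness) or when either characteristic falls
below a minimum-signal floor (the fluorescent signal is lost in the
background).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateSegmentationError, DomainError
from .segmentation import SegmentationResult, morph_denoise, segment_halves, split_columns
from .virtual_assay import StripImage

__all__ = [
    "LineFeature",
    "TCResult",
    "QuantifyConfig",
    "extract_feature",
    "compute_tc",
    "analyze_image",
]

#: default validity thresholds (configurable via QuantifyConfig)
SATURATION_FRACTION_LIMIT = 0.05
MIN_SIGNAL_GRAY = 5.0


def extract_band_mask(mask: np.ndarray, min_column_fraction: float = 0.5) -> np.ndarray:
    """Reduce a threshold mask to the line-band region.

    A reagent line runs the full height of the imaged window, so the band is
    the contiguous run of columns that are majority-foreground; the region
    is taken full-height over that run.  This removes the two artifacts a
    histogram threshold leaves on a line image: stray foreground speckle
    (noise clusters, possibly touching the band) and missing band pixels
    where the threshold clipped the band's own noise tail.
    """
    mask = np.asarray(mask, dtype=bool)
    col_frac = mask.mean(axis=0)
    band_cols = col_frac >= min_column_fraction
    if not band_cols.any():
        raise DegenerateSegmentationError("no full column reaches the threshold")
    # largest contiguous run of band columns
    idx = np.flatnonzero(band_cols)
    breaks = np.flatnonzero(np.diff(idx) > 1)
    runs = np.split(idx, breaks + 1)
    best = max(runs, key=len)
    out = np.zeros_like(mask)
    out[:, best[0] : best[-1] + 1] = True
    return out


@dataclass(frozen=True)
class QuantifyConfig:
    """Validity thresholds for a T/C reading."""

    saturation_fraction_limit: float = SATURATION_FRACTION_LIMIT
    min_signal_gray: float = MIN_SIGNAL_GRAY
    layout: str = "t-left"   # which half holds the T line: "t-left" | "t-right"

    def __post_init__(self):
        if self.layout not in ("t-left", "t-right"):
            raise DomainError(f"unknown layout {self.layout!r}")


@dataclass(frozen=True)
class LineFeature:
    """Scalar summary of one segmented line region."""

    mean_gray_fg: float
    mean_gray_bg: float
    characteristic: float
    area: int
    saturated_fraction_fg: float


@dataclass(frozen=True)
class TCResult:
    t_feature: LineFeature | None
    c_feature: LineFeature | None
    ratio: float
    valid: bool
    invalid_reason: str   # none | underexposed | saturated | degenerate


def extract_feature(
    half: np.ndarray,
    mask: np.ndarray,
    bit_depth: int,
    bg_mask: np.ndarray | None = None,
) -> LineFeature:
    """Mean-gray feature of the masked line region within one image half.

    The background mean is taken over the complement of ``mask`` unless an
    explicit ``bg_mask`` is given (used by the pipeline to keep a guard zone
    around the band boundary out of both means).
    """
    half = np.asarray(half)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != half.shape:
        raise DomainError("mask shape must match the image half")
    n_fg = int(mask.sum())
    if n_fg == 0:
        raise DegenerateSegmentationError("empty foreground mask")
    max_gray = 2 ** bit_depth - 1
    fg = half[mask].astype(float)
    bg = half[~mask if bg_mask is None else np.asarray(bg_mask, dtype=bool)].astype(float)
    mean_fg = float(fg.mean())
    mean_bg = float(bg.mean()) if bg.size else 0.0
    return LineFeature(
        mean_gray_fg=mean_fg,
        mean_gray_bg=mean_bg,
        characteristic=max(0.0, mean_fg - mean_bg),
        area=n_fg,
        saturated_fraction_fg=float(np.mean(fg == max_gray)),
    )


def compute_tc(
    left: LineFeature,
    right: LineFeature,
    config: QuantifyConfig = QuantifyConfig(),
) -> TCResult:
    """Form the T/C result from the two per-half line features."""
    t_feat, c_feat = (left, right) if config.layout == "t-left" else (right, left)
    reason = "none"
    for feat in (t_feat, c_feat):
        if feat.saturated_fraction_fg > config.saturation_fraction_limit:
            reason = "saturated"
            break
    if reason == "none":
        if c_feat.characteristic == 0.0:
            reason = "degenerate"
        elif (
            t_feat.characteristic < config.min_signal_gray
            or c_feat.characteristic < config.min_signal_gray
        ):
            reason = "underexposed"
    ratio = (
        t_feat.characteristic / c_feat.characteristic
        if c_feat.characteristic > 0
        else float("nan")
    )
    return TCResult(
        t_feature=t_feat,
        c_feature=c_feat,
        ratio=ratio,
        valid=reason == "none",
        invalid_reason=reason,
    )


#: columns dropped on each side of the band boundary before taking means —
#: the morphological filter mixes background and plateau values there
BAND_GUARD_COLUMNS = 2

#: |raw - filtered| above this many gray levels marks a pixel as an impulse
#: outlier; read noise stays well below it, impulse flips far above
IMPULSE_RESIDUAL_GRAY = 10.0


def _guarded_feature(
    raw_half: np.ndarray,
    filtered_half: np.ndarray,
    mask: np.ndarray,
    bit_depth: int,
) -> LineFeature:
    """Band extraction with a boundary guard zone and impulse rejection.

    The filtered image drives segmentation but imprints a small value-
    dependent bias on noisy regions, so the means are taken from the raw
    pixels; the filter is used only to flag impulse outliers (pixels whose
    raw value departs far from the filtered one), which are excluded.
    """
    band = extract_band_mask(mask)
    cols = np.flatnonzero(band.any(axis=0))
    lo, hi = int(cols[0]), int(cols[-1])
    g = BAND_GUARD_COLUMNS
    fg = np.zeros_like(band)
    bg = np.ones_like(band)
    if hi - lo + 1 > 2 * g + 1:   # band wide enough to afford the guard
        fg[:, lo + g : hi + 1 - g] = True
    else:
        fg[:, lo : hi + 1] = True
    bg[:, max(0, lo - g) : hi + 1 + g] = False
    if not bg.any():
        bg = ~band
    clean = (
        np.abs(raw_half.astype(float) - filtered_half.astype(float))
        <= IMPULSE_RESIDUAL_GRAY
    )
    if (fg & clean).any():
        fg &= clean
    if (bg & clean).any():
        bg &= clean
    return extract_feature(raw_half, fg, bit_depth, bg_mask=bg)


def analyze_image(
    image: StripImage,
    config: QuantifyConfig = QuantifyConfig(),
    denoise: bool = True,
    selem_size: int = 3,
) -> "tuple[TCResult, SegmentationResult, SegmentationResult]":
    """Full read of one strip image: filter, segment halves, quantify.

    Degenerate segmentation (e.g. a blank half) yields an invalid TCResult
    with reason "degenerate" rather than an exception.
    """
    work = morph_denoise(image, selem_size=selem_size) if denoise else image
    raw = image.pixels
    mid = split_columns(work.pixels.shape[1])
    try:
        seg_left, seg_right = segment_halves(work)
        feat_left = _guarded_feature(
            raw[:, :mid], work.pixels[:, :mid], seg_left.mask, work.bit_depth
        )
        feat_right = _guarded_feature(
            raw[:, mid:], work.pixels[:, mid:], seg_right.mask, work.bit_depth
        )
    except DegenerateSegmentationError:
        return (
            TCResult(
                t_feature=None,
                c_feature=None,
                ratio=float("nan"),
                valid=False,
                invalid_reason="degenerate",
            ),
            None,
            None,
        )
    return compute_tc(feat_left, feat_right, config), seg_left, seg_right
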