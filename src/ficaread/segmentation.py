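"""Morphological denoising and entropy-modified Otsu thresholding.

The strip image is filtered with a grayscale opening (removes bright impulse
outliers and edge burrs) followed by a closing (fills dark pinholes and short
breaks) using the same structuring element.  Because the T and C lines sit on
opposite sides of the strip and may differ strongly in brightness, the image
is split into left and right halves and each half is thresholded
independently.

Threshold selection replaces the class gray means of the classical Otsu
criterion with partial Shannon entropies of the histogram.  With p_i the
probability of gray level i and

    H_A(t) = -sum_{i<=t} p_i log2 p_i        (candidate foreground range)
    H_B(t) = -sum_{i>t}  p_i log2 p_i        (complementary range)
    H_0    = H_A(t) + H_B(t)                 (whole-image entropy)

the selected threshold maximizes

    J(t) = (H_A-H_0)^2 (H_B-H_0)^2 / ((H_A-H_0)^2 + (H_B-H_0)^2)^2 ,

which is bounded by 1/4 and attains it when the two squared deviations are
equal.  The criterion depends only on the histogram, so it is exactly
invariant to gray shifts and (up to integer re-binning) to linear contrast
stretches.  H_A and H_B are the plain partial sums, not class-conditional
entropies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.morphology import closing, footprint_rectangle, opening

from .errors import DegenerateSegmentationError, DomainError
from .virtual_assay import StripImage

__all__ = [
    "GrayHistogram",
    "SegmentationResult",
    "morph_denoise",
    "histogram",
    "partial_entropy",
    "entropy_otsu_threshold",
    "segment_halves",
    "split_columns",
]


@dataclass(frozen=True)
class GrayHistogram:
    """Normalized gray-level histogram over L = 2^bit_depth levels."""

    probs: np.ndarray
    L: int

    def __post_init__(self):
        p = np.asarray(self.probs, dtype=float)
        if p.shape != (self.L,):
            raise DomainError(f"probs must have length L={self.L}")
        if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-12:
            raise DomainError("probs must be non-negative and sum to 1")
        object.__setattr__(self, "probs", p)


@dataclass(frozen=True)
class SegmentationResult:
    """Threshold, diagnostics and (when computed from an image) the mask.

    Foreground is defined as gray strictly above the threshold: fluorescent
    lines are bright on a dark membrane background.
    """

    threshold: int
    h_a: float
    h_b: float
    h_0: float
    criterion_curve: np.ndarray   # J(t) for t = 0..L-2, NaN where undefined
    mask: np.ndarray | None = None


def _selem(shape: str, size: int) -> np.ndarray:
    if size < 1:
        raise DomainError("structuring element size must be >= 1")
    if shape == "square":
        return footprint_rectangle((size, size))
    if shape == "cross":
        se = np.zeros((size, size), dtype=bool)
        se[size // 2, :] = True
        se[:, size // 2] = True
        return se
    raise DomainError(f"unknown structuring element shape {shape!r}")


def morph_denoise(
    image: StripImage, selem_shape: str = "square", selem_size: int = 3
) -> StripImage:
    """Grayscale open-then-close with one structuring element.

    Preserves acquisition metadata; the saturated fraction is recomputed on
    the filtered pixels.
    """
    se = _selem(selem_shape, selem_size)
    if se.shape[0] > image.pixels.shape[0] or se.shape[1] > image.pixels.shape[1]:
        raise DomainError("structuring element larger than the image")
    out = closing(opening(image.pixels, se), se)
    return image.with_pixels(out)


def histogram(region: np.ndarray, L: int) -> GrayHistogram:
    """Empirical gray-level probabilities of an image region."""
    vals = np.asarray(region).ravel()
    if vals.size == 0:
        raise DomainError("empty image region")
    counts = np.bincount(vals.astype(np.int64), minlength=L)
    if len(counts) > L:
        raise DomainError("gray values exceed the stated number of levels")
    return GrayHistogram(probs=counts / vals.size, L=L)


def _plogp(p: np.ndarray) -> np.ndarray:
    # convention: 0 * log2(0) = 0
    out = np.zeros_like(p)
    nz = p > 0
    out[nz] = -p[nz] * np.log2(p[nz])
    return out


def partial_entropy(hist: GrayHistogram, lo: int, hi: int) -> float:
    """-sum_{i=lo..hi} p_i log2 p_i, in bits (inclusive bounds)."""
    if not 0 <= lo <= hi <= hist.L - 1:
        raise DomainError(f"invalid range [{lo}, {hi}] for L={hist.L}")
    return float(_plogp(hist.probs[lo : hi + 1]).sum())


def entropy_otsu_threshold(hist: GrayHistogram) -> SegmentationResult:
    """Exhaustive argmax of the entropy-modified Otsu criterion.

    Candidate thresholds are those leaving both classes non-empty; ties are
    broken toward the lowest threshold; candidates with a zero denominator
    are skipped.
    """
    p = hist.probs
    if np.count_nonzero(p) < 2:
        raise DegenerateSegmentationError("histogram has fewer than 2 occupied bins")
    plogp = _plogp(p)
    h_a = np.cumsum(plogp)            # H_A(t) for t = 0..L-1
    h_0 = float(h_a[-1])
    h_a = h_a[:-1]                    # thresholds t = 0..L-2
    h_b = h_0 - h_a
    # a candidate threshold must leave both classes non-empty
    occupied = np.flatnonzero(p > 0)
    t_axis = np.arange(hist.L - 1)
    both_nonempty = (t_axis >= occupied[0]) & (t_axis < occupied[-1])
    a = (h_a - h_0) ** 2
    b = (h_b - h_0) ** 2
    denom = (a + b) ** 2
    valid = both_nonempty & (denom > 0)
    if not valid.any():
        raise DegenerateSegmentationError(
            "criterion undefined at every candidate threshold"
        )
    curve = np.full(hist.L - 1, np.nan)
    curve[valid] = a[valid] * b[valid] / denom[valid]
    t_star = int(np.nanargmax(curve))     # first occurrence on ties
    return SegmentationResult(
        threshold=t_star,
        h_a=float(h_a[t_star]),
        h_b=float(h_b[t_star]),
        h_0=h_0,
        criterion_curve=curve,
    )


def split_columns(width: int) -> int:
    """Column index separating the left and right halves."""
    if width < 2:
        raise DomainError("image must be at least 2 columns wide")
    return width // 2


def _segment_region(region: np.ndarray, L: int) -> SegmentationResult:
    res = entropy_otsu_threshold(histogram(region, L))
    mask = region > res.threshold
    return SegmentationResult(
        threshold=res.threshold,
        h_a=res.h_a,
        h_b=res.h_b,
        h_0=res.h_0,
        criterion_curve=res.criterion_curve,
        mask=mask,
    )


def segment_halves(
    image: StripImage,
) -> "tuple[SegmentationResult, SegmentationResult]":
    """Threshold the left and right image halves independently."""
    px = image.pixels
    mid = split_columns(px.shape[1])
    L = 2 ** image.bit_depth
    results = []
    for name, region in (("left", px[:, :mid]), ("right", px[:, mid:])):
        try:
            results.append(_segment_region(region, L))
        except DegenerateSegmentationError as exc:
            raise DegenerateSegmentationError(str(exc), half=name) from exc
    return results[0], results[1]
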