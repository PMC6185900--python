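"""Maximum-entropy binarisation of micro-CT slices and solid-fraction maps.

X-ray micro-CT of dried plant tissue images the solid matrix (cell walls)
as bright pixels — the solid reflects the beam — over a dark lumen/air
background.  Slices are binarised with the Kapur maximum-entropy threshold:
the grey-level histogram is split at the intensity T maximising the sum of
Shannon entropies of the two classes (below-T and at-or-above-T), and the
bright class is labelled solid.

Note on conventions: thresholding literature is split on whether "1" means
dark or bright.  Here the physics decides — solid matrix appears white, so
mask value 1 = intensity >= threshold = cell wall, and the wall (solid)
fraction is the mean of the mask.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import DegenerateHistogramError

__all__ = [
    "GrayImage",
    "SegmentationResult",
    "MaxEntropyThresholder",
    "entropy_threshold",
    "segment",
    "wall_fraction_profile",
]


@dataclass(frozen=True)
class GrayImage:
    """An 8-bit grayscale slice plus its physical pixel size (default 6 um,
    a typical desktop micro-CT resolution)."""

    pixels: np.ndarray
    resolution_um: float = 6.0

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.size == 0:
            raise ValueError("pixels must be a non-empty 2-D array")
        if px.dtype != np.uint8:
            if np.any((px < 0) | (px > 255)) or not np.allclose(px, np.round(px)):
                raise ValueError("intensities must be integers in [0, 255]")
            px = px.astype(np.uint8)
        if self.resolution_um <= 0:
            raise ValueError("resolution_um must be > 0")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class SegmentationResult:
    """Binary mask (1 = solid/cell wall), the threshold used, and the
    overall solid fraction."""

    mask: np.ndarray
    threshold: int
    wall_fraction: float

    def __post_init__(self) -> None:
        mask = np.asarray(self.mask, dtype=np.uint8)
        if mask.ndim != 2:
            raise ValueError("mask must be 2-D")
        if not 0 <= self.threshold <= 255:
            raise ValueError("threshold must lie in [0, 255]")
        if not 0.0 <= self.wall_fraction <= 1.0:
            raise ValueError("wall_fraction must lie in [0, 1]")
        object.__setattr__(self, "mask", mask)


def _kapur_threshold(pixels: np.ndarray) -> int:
    """Kapur maximum-entropy threshold on a 256-bin histogram.

    Candidate thresholds T in 1..255 split grey levels into [0, T) and
    [T, 255]; both classes must be occupied.  Empty bins contribute zero
    entropy (0*log 0 := 0).  Ties break to the lowest maximiser.
    """
    hist = np.bincount(pixels.ravel(), minlength=256).astype(float)
    if np.count_nonzero(hist) < 2:
        raise DegenerateHistogramError("image has fewer than 2 distinct intensities")
    p = hist / hist.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    P_low = np.cumsum(p)  # P_low[i] = P(level <= i)
    A_low = -np.cumsum(plogp)
    P_total, A_total = P_low[-1], A_low[-1]

    best_t, best_h = None, -np.inf
    for t in range(1, 256):
        pl = P_low[t - 1]
        ph = P_total - pl
        if pl <= 0 or ph <= 0:
            continue
        h_low = A_low[t - 1] / pl + np.log(pl)
        h_high = (A_total - A_low[t - 1]) / ph + np.log(ph)
        h = h_low + h_high
        if h > best_h + 1e-12:
            best_t, best_h = t, h
    return int(best_t)


class MaxEntropyThresholder(TransformerMixin, BaseEstimator):
    """Kapur maximum-entropy auto-threshold as a transformer.

    ``fit`` learns the threshold from an image's histogram; ``transform``
    binarises (1 = intensity >= threshold = solid).  Stateless across
    images when used per-slice, which is how stacks are handled.

    Attributes
    ----------
    threshold_ : int
        The entropy-maximising grey-level cut, in [1, 255].
    """

    def fit(self, X, y=None):
        img = X.pixels if isinstance(X, GrayImage) else GrayImage(np.asarray(X)).pixels
        self.threshold_ = _kapur_threshold(img)
        return self

    def transform(self, X) -> np.ndarray:
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "threshold_")
        img = X.pixels if isinstance(X, GrayImage) else GrayImage(np.asarray(X)).pixels
        return (img >= self.threshold_).astype(np.uint8)


def entropy_threshold(image: GrayImage) -> int:
    """Maximum-entropy (Kapur) threshold of an image's grey-level histogram.

    Deterministic; ties break to the lowest maximising threshold.  Raises
    :class:`DegenerateHistogramError` on single-intensity images.
    """
    if not isinstance(image, GrayImage):
        image = GrayImage(np.asarray(image))
    return _kapur_threshold(image.pixels)


def segment(image: GrayImage, threshold: int) -> SegmentationResult:
    """Binarise at a given threshold: pixels >= threshold are solid (1).

    Idempotent on binary masks: re-segmenting ``255 * mask`` at the same
    threshold (for any threshold in [1, 255]) reproduces the mask.
    """
    if not isinstance(image, GrayImage):
        image = GrayImage(np.asarray(image))
    if not 0 <= threshold <= 255:
        raise ValueError("threshold must lie in [0, 255]")
    mask = (image.pixels >= threshold).astype(np.uint8)
    return SegmentationResult(
        mask=mask, threshold=int(threshold), wall_fraction=float(mask.mean())
    )


def wall_fraction_profile(result: SegmentationResult, axis: int = 0) -> np.ndarray:
    """Solid fraction resolved along one axis of the mask.

    ``axis=0`` gives one value per row (averaging over columns), i.e. a
    depth profile when the sample surface is at row 0 and the centre at the
    last row; ``axis=1`` the transpose reading.  A rupture front advancing
    from the surface shows up as a rising trend away from row 0.
    """
    if axis not in (0, 1):
        raise ValueError("axis must be 0 or 1")
    return result.mask.mean(axis=1 - axis)
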