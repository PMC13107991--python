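"""Background correction, normalization, and thresholding primitives.

The TUNEL channel (and the nuclear channel) are corrected for uneven
illumination with rolling-ball background subtraction, rescaled by robust
percentile normalization, and binarized with Otsu's method. These three
primitives are the calibrated front end consumed by segmentation and by the
overlap-fraction classifier.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.restoration import rolling_ball

from .imaging import CalibratedImage

__all__ = [
    "BinaryMask",
    "rolling_ball_subtract",
    "percentile_normalize",
    "otsu_threshold",
]


@dataclass(frozen=True)
class BinaryMask:
    """A boolean image sharing the calibration of its source."""

    pixels: np.ndarray
    pixels_per_um: float

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=bool)
        if px.ndim != 2 or px.size == 0:
            raise ValueError("mask must be a non-empty 2-D array")
        if not self.pixels_per_um > 0:
            raise ValueError("pixels_per_um must be > 0")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    @property
    def foreground_fraction(self) -> float:
        return float(self.pixels.mean())

    def area_um2(self) -> float:
        return float(self.pixels.sum()) / self.pixels_per_um**2


def rolling_ball_subtract(img: CalibratedImage, radius_um: float = 6.5) -> CalibratedImage:
    """Subtract a rolling-ball background estimate.

    The ball radius is given in micrometers and scaled to pixels by the
    image's calibration (nearest integer, floor 1 px). The background is a
    grayscale morphological estimate that never exceeds the image, so the
    result is non-negative everywhere; a constant image maps to zero.

    Parameters
    ----------
    img
        Calibrated single-channel image.
    radius_um
        Ball radius in µm; default 6.5, of the order of one photoreceptor
        soma so that structures at cell scale survive subtraction.
    """
    if not radius_um > 0:
        raise ValueError("radius_um must be > 0")
    radius_px = max(1, round(radius_um * img.pixels_per_um))
    data = img.pixels.astype(float, copy=False)
    background = rolling_ball(data, radius=radius_px)
    out = np.clip(data - background, 0.0, None)
    return img.with_pixels(out)


def percentile_normalize(
    img: CalibratedImage, p_low: float = 1.0, p_high: float = 99.8
) -> CalibratedImage:
    """Rescale intensities so the p_low/p_high percentiles map to 0 and 1.

    No clipping is applied: values outside the percentile window fall
    outside [0, 1], which downstream Otsu tolerates because it bins over the
    observed range. A constant-range image maps to all zeros.
    """
    if not (0.0 <= p_low < p_high <= 100.0):
        raise ValueError("require 0 <= p_low < p_high <= 100")
    data = img.pixels.astype(float, copy=False)
    q_low, q_high = np.percentile(data, [p_low, p_high])
    if q_high == q_low:
        return img.with_pixels(np.zeros_like(data))
    return img.with_pixels((data - q_low) / (q_high - q_low))


def otsu_threshold(img: CalibratedImage, n_bins: int = 256) -> tuple[float, BinaryMask]:
    """Otsu's between-class-variance threshold over an n_bins histogram.

    The histogram spans [min, max] of the image (classic 8-bit behavior on
    integer input, and well defined for floats). Variance ties are broken
    toward the lowest bin. The returned threshold is the midpoint between
    the darkest foreground and brightest background pixel of the optimal
    split, so it lies strictly between the two classes; the mask uses the
    strict comparison ``pixels > threshold``.

    Raises
    ------
    ValueError
        If the image is constant (cannot be thresholded).
    """
    data = img.pixels.astype(float, copy=False)
    lo, hi = float(data.min()), float(data.max())
    if lo == hi:
        raise ValueError("cannot threshold constant image")
    # bin index per pixel (right-inclusive last bin, as np.histogram does);
    # per-bin intensity sums make the class means exact pixel means, not
    # bin-center approximations
    idx = np.minimum(
        ((data - lo) * (n_bins / (hi - lo))).astype(np.int64), n_bins - 1
    )
    counts = np.bincount(idx.ravel(), minlength=n_bins).astype(float)
    sums = np.bincount(idx.ravel(), weights=data.ravel(), minlength=n_bins)

    w0 = np.cumsum(counts)[:-1]               # pixels in bins 0..k
    w1 = counts.sum() - w0
    cum_sum = np.cumsum(sums)[:-1]
    total = float(sums.sum())
    valid = (w0 > 0) & (w1 > 0)
    mu0 = np.where(valid, cum_sum / np.where(w0 > 0, w0, 1), 0.0)
    mu1 = np.where(valid, (total - cum_sum) / np.where(w1 > 0, w1, 1), 0.0)
    between = np.where(valid, w0 * w1 * (mu0 - mu1) ** 2, -np.inf)
    k = int(np.argmax(between))
    fg = idx > k
    threshold = float((data[~fg].max() + data[fg].min()) / 2.0)
    mask = BinaryMask(data > threshold, img.pixels_per_um)
    return threshold, mask
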