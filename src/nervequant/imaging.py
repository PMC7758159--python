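"""Intermodes histogram thresholding and stained-area fraction.

The intermodes threshold is the classic iterate-and-smooth construction: the
256-bin histogram is repeatedly smoothed with a 3-bin running mean until
exactly two local maxima survive, and the threshold is the floor of the
midpoint of the two surviving mode positions.  The area fraction is simply
the proportion of pixels strictly above the threshold.
"""

from __future__ import annotations

import warnings

import numpy as np

from .errors import DataError, DegenerateDataWarning, NotBimodalError, ParameterError

__all__ = [
    "quantize_to_uint8",
    "intensity_histogram",
    "intermodes_threshold",
    "area_fraction",
    "per_animal_average",
    "quantify_image",
    "MAX_SMOOTH_ITERATIONS",
]

MAX_SMOOTH_ITERATIONS = 10_000


def quantize_to_uint8(image: np.ndarray) -> np.ndarray:
    """Map an image to uint8 by linear min-max scaling (uint8 passes through)."""
    img = np.asarray(image)
    if img.size == 0:
        raise DataError("empty image")
    if img.dtype == np.uint8:
        return img
    lo, hi = float(img.min()), float(img.max())
    if hi == lo:
        warnings.warn("constant image: quantized to all zeros", DegenerateDataWarning,
                      stacklevel=2)
        return np.zeros(img.shape, dtype=np.uint8)
    return np.round((img.astype(float) - lo) / (hi - lo) * 255.0).astype(np.uint8)


def intensity_histogram(image: np.ndarray) -> np.ndarray:
    """256-bin intensity histogram of a uint8 (or quantisable) image."""
    img = quantize_to_uint8(image)
    return np.bincount(img.ravel(), minlength=256)


def _mode_positions(h: np.ndarray) -> np.ndarray:
    """Interior strict local maxima of the (smoothed) histogram."""
    inner = (h[1:-1] > h[:-2]) & (h[1:-1] > h[2:])
    return np.nonzero(inner)[0] + 1


def _smooth3(h: np.ndarray) -> np.ndarray:
    """3-bin running mean with edge replication."""
    padded = np.concatenate([h[:1], h, h[-1:]])
    return (padded[:-2] + padded[1:-1] + padded[2:]) / 3.0


def intermodes_threshold(
    hist: np.ndarray, max_iterations: int = MAX_SMOOTH_ITERATIONS
) -> int:
    """Smooth until exactly two modes remain; threshold = floor of their midpoint.

    Raises :class:`NotBimodalError` if the histogram becomes unimodal (it can
    never be made bimodal by smoothing) or if two modes do not emerge within
    the iteration cap.
    """
    h = np.asarray(hist, dtype=float)
    if h.ndim != 1 or h.size < 3:
        raise ParameterError("histogram must be 1-D with at least 3 bins")
    if np.any(h < 0) or h.sum() <= 0:
        raise ParameterError("histogram counts must be nonnegative with positive total")
    for _ in range(max_iterations + 1):
        modes = _mode_positions(h)
        if modes.size == 2:
            return int((modes[0] + modes[1]) // 2)
        if modes.size < 2:
            raise NotBimodalError(
                "histogram is unimodal; intermodes threshold undefined"
            )
        h = _smooth3(h)
    raise NotBimodalError(
        f"histogram not bimodal after {max_iterations} smoothing iterations"
    )


def area_fraction(image: np.ndarray, thr: int) -> float:
    """Fraction of pixels strictly above ``thr``, in [0, 1]."""
    img = np.asarray(image)
    if img.size == 0:
        raise DataError("empty image")
    return float(np.count_nonzero(img > thr)) / img.size


def per_animal_average(fractions: list[float]) -> float:
    """Arithmetic mean of field-of-view area fractions for one animal."""
    if not fractions:
        raise DataError("need at least one field-of-view fraction")
    return float(np.mean(fractions))


def quantify_image(image: np.ndarray) -> tuple[int, float]:
    """Quantize, threshold by intermodes, and return ``(threshold, fraction)``.

    The fraction is measured on the quantised image so it matches the
    histogram the threshold came from.
    """
    img8 = quantize_to_uint8(image)
    thr = intermodes_threshold(intensity_histogram(img8))
    return thr, area_fraction(img8, thr)
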