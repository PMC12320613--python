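"""Local mean suppression filter (LMSF) kernels in one and two dimensions.

The filter is a pixel-wise (sample-wise) rule: compare a value with the mean
of its local neighborhood and replace it with zero when the ratio falls below
a threshold ``theta``; otherwise keep the original value.  Background pixels
of a fluorescence image are exactly the zeroed pixels.

Local means use *adaptive* windows: near the borders only the samples that
actually exist are averaged — there is no padding of any kind, so a constant
input has a constant local mean all the way into the corners.  The means are
computed with summed-area tables (integral images) together with a matching
table of window counts, which reproduces ``sum of available values / count of
available values`` exactly in O(K*M) time independent of the window size.

The suppression comparison is evaluated multiplicatively, ``x < theta * mean``
rather than ``x / mean < theta``, which is algebraically identical for a
positive mean and well defined when a window is entirely zero.
"""

from __future__ import annotations

import logging

import numpy as np
import numpy.typing as npt

__all__ = [
    "n_max",
    "local_mean_1d",
    "lmsf_1d",
    "local_mean_2d",
    "lmsf_2d",
    "oracle_local_mean_2d",
    "oracle_lmsf_2d",
    "sine_squared_local_mean",
]

logger = logging.getLogger(__name__)

#: Recommended operating range for the threshold parameter theta.
THETA_RECOMMENDED_RANGE = (0.5, 1.0)


def n_max(rows: int, cols: int) -> int:
    """Largest admissible half-window ``n`` for a ``rows x cols`` image.

    ``n_max = floor(min(rows, cols) / 2) - 1``.  Images smaller than 4 pixels
    on a side admit no valid window (the bound would drop below 1) and are
    rejected.
    """
    rows, cols = int(rows), int(cols)
    if rows < 4 or cols < 4:
        raise ValueError(
            f"image too small for LMSF: need at least 4x4 pixels, got {rows}x{cols}"
        )
    return min(rows, cols) // 2 - 1


def _check_theta(theta: float) -> float:
    theta = float(theta)
    if not np.isfinite(theta) or theta <= 0:
        raise ValueError(f"theta must be a positive finite number, got {theta}")
    lo, hi = THETA_RECOMMENDED_RANGE
    if not lo <= theta <= hi:
        logger.warning(
            "theta=%g is outside the recommended operating range [%g, %g]",
            theta, lo, hi,
        )
    return theta


def _check_signal(signal: npt.ArrayLike) -> np.ndarray:
    s = np.asarray(signal, dtype=np.float64)
    if s.ndim != 1 or s.size < 1:
        raise ValueError("signal must be a non-empty 1-D sequence")
    if not np.all(np.isfinite(s)):
        raise ValueError("signal contains non-finite values")
    return s


def _check_image(image: npt.ArrayLike) -> np.ndarray:
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 2 or img.shape[0] < 1 or img.shape[1] < 1:
        raise ValueError("image must be a non-empty 2-D array")
    if not np.all(np.isfinite(img)):
        raise ValueError("image contains non-finite values")
    if img.min() < 0:
        raise ValueError("negative intensities are not valid fluorescence values")
    return img


def local_mean_1d(signal: npt.ArrayLike, n: int) -> np.ndarray:
    """Adaptive local mean of a 1-D signal over windows ``[k-n, k+n]``.

    Interior samples average exactly ``2n + 1`` values; at the sequence ends
    only the available samples are averaged (``n + 1`` at the end points,
    ``n + 2`` one sample in, and so on).
    """
    s = _check_signal(signal)
    K = s.size
    n = int(n)
    if not 1 <= n < K:
        raise ValueError(f"window half-width n={n} outside valid range [1, {K - 1}]")
    csum = np.concatenate(([0.0], np.cumsum(s, dtype=np.float64)))
    idx = np.arange(K)
    lo = np.clip(idx - n, 0, None)
    hi = np.minimum(idx + n + 1, K)
    return (csum[hi] - csum[lo]) / (hi - lo)


def lmsf_1d(signal: npt.ArrayLike, n: int, theta: float) -> np.ndarray:
    """1-D LMSF response: zero sample ``k`` where ``s_k < theta * local mean``.

    Samples exactly at the threshold are kept.  The output has the input's
    length and dtype; every sample is either 0 or the original value.
    """
    theta = _check_theta(theta)
    mean = local_mean_1d(signal, n)
    s = np.asarray(signal)
    out = s.copy()
    out[np.asarray(s, dtype=np.float64) < theta * mean] = 0
    return out


def local_mean_2d(image: npt.ArrayLike, n: int) -> np.ndarray:
    """Adaptive local mean over square windows ``[k-n, k+n] x [m-n, m+n]``.

    The window is intersected with the image; the mean divides the window sum
    by the number of pixels actually inside.  Computed with a summed-area
    table, O(K*M) regardless of ``n``.

    Any ``1 <= n < min(K, M)`` is accepted here; the stricter image-size
    bound :func:`n_max` applies at the public multi-scale entry points.
    """
    img = _check_image(image)
    K, M = img.shape
    n = int(n)
    if not 1 <= n < min(K, M):
        raise ValueError(
            f"window half-width n={n} outside valid range [1, {min(K, M) - 1}] "
            f"for a {K}x{M} image"
        )
    sat = np.zeros((K + 1, M + 1), dtype=np.float64)
    np.cumsum(np.cumsum(img, axis=0), axis=1, out=sat[1:, 1:])
    r = np.arange(K)
    c = np.arange(M)
    r0 = np.clip(r - n, 0, None)
    r1 = np.minimum(r + n + 1, K)
    c0 = np.clip(c - n, 0, None)
    c1 = np.minimum(c + n + 1, M)
    sums = (
        sat[np.ix_(r1, c1)]
        - sat[np.ix_(r0, c1)]
        - sat[np.ix_(r1, c0)]
        + sat[np.ix_(r0, c0)]
    )
    counts = np.outer(r1 - r0, c1 - c0)
    return sums / counts


def lmsf_2d(image: npt.ArrayLike, n: int, theta: float) -> np.ndarray:
    """2-D LMSF response: zero pixel ``(k, m)`` where ``I < theta * local mean``.

    Pixels exactly at the threshold are kept.  The output has the input's
    shape and dtype; every pixel is either 0 or the original intensity.  A
    pixel with zero intensity always ends up zero (background).
    """
    theta = _check_theta(theta)
    mean = local_mean_2d(image, n)
    img = np.asarray(image)
    out = img.copy()
    out[np.asarray(img, dtype=np.float64) < theta * mean] = 0
    return out


def oracle_local_mean_2d(image: npt.ArrayLike, n: int) -> np.ndarray:
    """Adaptive local mean by explicit per-pixel window enumeration.

    Direct O(K^2 * M^2) reference used to validate :func:`local_mean_2d`;
    intended for small images only.
    """
    img = _check_image(image)
    K, M = img.shape
    n = int(n)
    if not 1 <= n < min(K, M):
        raise ValueError(
            f"window half-width n={n} outside valid range [1, {min(K, M) - 1}] "
            f"for a {K}x{M} image"
        )
    out = np.empty_like(img)
    for k in range(K):
        for m in range(M):
            window = img[max(k - n, 0):k + n + 1, max(m - n, 0):m + n + 1]
            out[k, m] = window.mean()
    return out


def oracle_lmsf_2d(image: npt.ArrayLike, n: int, theta: float) -> np.ndarray:
    """2-D LMSF computed with the brute-force window oracle."""
    theta = _check_theta(theta)
    mean = oracle_local_mean_2d(image, n)
    img = np.asarray(image)
    out = img.copy()
    out[np.asarray(img, dtype=np.float64) < theta * mean] = 0
    return out


def sine_squared_local_mean(t: npt.ArrayLike, T: float) -> np.ndarray | float:
    """Closed-form local mean of ``sin^2(t)`` over the window ``[t-T, t+T]``.

    ``(1 / 2T) * integral_{-T}^{T} sin^2(t + tau) d tau
    = 1/2 - (cos(2t) / 2) * sin(2T) / (2T)``.

    The mean oscillates around 1/2 and is exactly 1/2 for every ``t`` when
    the window spans an integer number of signal periods (``T = k * pi / 2``).
    Analytic reference used in tests of the discrete filter.
    """
    T = float(T)
    if T <= 0:
        raise ValueError("window half-length T must be positive")
    return 0.5 - 0.5 * np.cos(2.0 * np.asarray(t, dtype=np.float64)) * (
        np.sin(2.0 * T) / (2.0 * T)
    )
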