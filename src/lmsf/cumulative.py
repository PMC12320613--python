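"""Multi-scale cumulative background identification.

A single LMSF pass at half-window ``n`` finds background at one spatial
scale: small windows mark narrow gaps between bright objects, large windows
mark wide, gradually varying empty regions.  The cumulative method runs the
filter over an increasing scale set ``N = {n_1 < n_2 < ... < n_L}`` and
combines the per-scale backgrounds with a Boolean union: a pixel is
background if any scale calls it background, equivalently the foreground
indicator is the logical AND (product) of the per-scale foreground
indicators.

Two combination modes are offered.  In ``independent`` mode (default) every
scale filters the *original* image and the backgrounds are unioned.  In
``sequential`` mode the output of each scale is fed to the next, in
increasing order of ``n``; because a filter output is everywhere 0 or the
original intensity, surviving pixels still carry their original values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import numpy.typing as npt

from .core import _check_image, _check_theta, lmsf_2d, n_max

__all__ = [
    "CumulativeResult",
    "background_mask",
    "validate_scales",
    "cumulative_lmsf",
    "scales_from_background_width",
    "scales_for_large_background",
    "theta_sweep",
]

#: Smallest half-window used in every worked scale recipe.
DEFAULT_MIN_SCALE = 5


@dataclass
class CumulativeResult:
    """Outcome of a cumulative multi-scale LMSF run.

    Attributes
    ----------
    filtered
        Image with background pixels zeroed; foreground pixels keep their
        original intensities and the input dtype.
    background
        Boolean mask, ``True`` exactly where ``filtered`` is zero.
    scales, theta, mode
        Parameters of the run, kept for provenance.
    per_scale_backgrounds
        One background mask per scale, retained only when requested
        (diagnostics; costs ``L`` masks of the image size).
    """

    filtered: np.ndarray
    background: np.ndarray
    scales: tuple[int, ...]
    theta: float
    mode: str
    per_scale_backgrounds: list[np.ndarray] | None = field(default=None, repr=False)

    @property
    def foreground(self) -> np.ndarray:
        return ~self.background


def background_mask(filtered: npt.ArrayLike) -> np.ndarray:
    """Boolean background indicator of a filter response: True where zero."""
    return np.asarray(filtered) == 0


def validate_scales(scales: Iterable[int], shape: tuple[int, int]) -> tuple[int, ...]:
    """Check a scale set: non-empty, strictly increasing, within [1, n_max]."""
    ns = tuple(int(n) for n in scales)
    if not ns:
        raise ValueError("scale set must be non-empty")
    if any(b <= a for a, b in zip(ns, ns[1:])):
        raise ValueError(f"scale set must be strictly increasing, got {ns}")
    bound = n_max(*shape)
    for n in ns:
        if not 1 <= n <= bound:
            raise ValueError(
                f"scale n={n} outside valid range [1, {bound}] for a "
                f"{shape[0]}x{shape[1]} image"
            )
    return ns


def cumulative_lmsf(
    image: npt.ArrayLike,
    scales: Iterable[int],
    theta: float = 0.5,
    mode: str = "independent",
    keep_per_scale: bool = False,
) -> CumulativeResult:
    """Cumulative LMSF over a scale set.

    Parameters
    ----------
    image
        2-D non-negative intensity image.
    scales
        Strictly increasing half-windows, each within ``[1, n_max]``.
    theta
        Suppression threshold; 0.5 is the recommended default.
    mode
        ``"independent"`` — each scale filters the original image, the
        background is the union of per-scale backgrounds.  ``"sequential"``
        — each scale filters the previous scale's output.
    keep_per_scale
        Retain the individual per-scale background masks for diagnostics.
    """
    img = np.asarray(image)
    _check_image(img)
    theta = _check_theta(theta)
    ns = validate_scales(scales, img.shape)
    if mode not in ("independent", "sequential"):
        raise ValueError(f"mode must be 'independent' or 'sequential', got {mode!r}")

    per_scale: list[np.ndarray] | None = [] if keep_per_scale else None
    if mode == "independent":
        bg = np.zeros(img.shape, dtype=bool)
        for n in ns:
            scale_bg = background_mask(lmsf_2d(img, n, theta))
            bg |= scale_bg
            if per_scale is not None:
                per_scale.append(scale_bg)
        filtered = img.copy()
        filtered[bg] = 0
    else:
        current = img
        for n in ns:
            current = lmsf_2d(current, n, theta)
            if per_scale is not None:
                per_scale.append(background_mask(current))
        filtered = current
        bg = background_mask(filtered)
    return CumulativeResult(
        filtered=filtered,
        background=bg,
        scales=ns,
        theta=theta,
        mode=mode,
        per_scale_backgrounds=per_scale,
    )


def scales_from_background_width(
    max_gap_width_px: int, min_scale: int = DEFAULT_MIN_SCALE
) -> tuple[int, ...]:
    """Scale recipe for images whose background forms narrow gaps.

    The largest scale is half the maximal background gap width; further
    scales are obtained by repeated halving (integer floor) until the next
    value would fall below ``min_scale``.  Returned in increasing order.

    >>> scales_from_background_width(80, 5)
    (5, 10, 20, 40)
    """
    width = int(max_gap_width_px)
    min_scale = int(min_scale)
    if min_scale < 1:
        raise ValueError("min_scale must be >= 1")
    if width < 2 * min_scale:
        raise ValueError(
            f"gap too narrow for requested minimum scale: width {width} < "
            f"2 * {min_scale}"
        )
    out = []
    n = width // 2
    while n >= min_scale:
        out.append(n)
        n //= 2
    return tuple(sorted(out))


def scales_for_large_background(
    rows: int, cols: int, small_scales: Iterable[int]
) -> tuple[int, ...]:
    """Scale recipe for images with an extensive background.

    Appends the image-size bound ``n_max`` to the given small scales so the
    largest window also captures wide, gradually varying empty regions.
    Deduplicated and increasing.
    """
    bound = n_max(rows, cols)
    return tuple(sorted(set(int(n) for n in small_scales) | {bound}))


def theta_sweep(
    image: npt.ArrayLike,
    scales: Iterable[int],
    thetas: Sequence[float],
    mode: str = "independent",
) -> list[CumulativeResult]:
    """Cumulative LMSF at a fixed scale set across an increasing theta list.

    Used for images with fuzzy foreground/background boundaries, where the
    right threshold is found by inspection of the sweep.  In independent
    mode the background grows monotonically with theta.
    """
    ths = [float(t) for t in thetas]
    if not ths:
        raise ValueError("theta list must be non-empty")
    if any(b <= a for a, b in zip(ths, ths[1:])):
        raise ValueError(f"theta list must be strictly increasing, got {ths}")
    return [cumulative_lmsf(image, scales, t, mode=mode) for t in ths]
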