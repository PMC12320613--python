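"""Downstream uses of the cumulative filter.

Two applications are covered: co-localization labeling of multiplexed
fluorescence channels, and background removal as a denoising pre-processing
step before instance segmentation.

For co-localization, each of C co-registered channels is filtered
independently to a binary foreground mask, and the C masks are combined
per pixel into a single integer label ``sum_c bit_c * 2**c`` (first-listed
channel = least significant bit).  The 2**C possible labels enumerate every
on/off combination of markers; label 0 means background in every channel.
Registration across channels is assumed to have been done upstream.

For pre-processing, the identified background is simply zeroed in the
original image; the downstream segmenter itself is outside this package.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import numpy.typing as npt

from .cumulative import cumulative_lmsf

__all__ = [
    "ChannelMaskStack",
    "ColocalizationLabelImage",
    "colocalization_labels",
    "decode_labels",
    "multiplex_cumulative",
    "apply_background_mask",
]


@dataclass
class ChannelMaskStack:
    """Ordered collection of same-shape boolean foreground masks."""

    masks: list[np.ndarray]
    names: list[str] | None = None

    def __post_init__(self) -> None:
        if not self.masks:
            raise ValueError("at least one channel mask is required")
        if self.names is None:
            self.names = [f"channel{i}" for i in range(len(self.masks))]
        if len(self.names) != len(self.masks):
            raise ValueError("one name per channel mask is required")
        self.masks = [np.asarray(m, dtype=bool) for m in self.masks]
        shape = self.masks[0].shape
        for name, m in zip(self.names, self.masks):
            if m.ndim != 2:
                raise ValueError(f"channel {name!r}: mask must be 2-D")
            if m.shape != shape:
                raise ValueError(
                    f"channel {name!r}: mask shape {m.shape} differs from "
                    f"first channel shape {shape}"
                )

    def __len__(self) -> int:
        return len(self.masks)


@dataclass
class ColocalizationLabelImage:
    """Per-pixel binary encoding of channel membership.

    ``labels[k, m] = sum_c mask_c[k, m] * 2**c`` with channel 0 the least
    significant bit; values lie in ``[0, 2**C - 1]``.
    """

    labels: np.ndarray
    names: list[str]

    @property
    def num_channels(self) -> int:
        return len(self.names)

    @property
    def classes_present(self) -> np.ndarray:
        return np.unique(self.labels)

    def class_counts(self) -> dict[int, int]:
        """Pixel count per label present in the image."""
        values, counts = np.unique(self.labels, return_counts=True)
        return {int(v): int(c) for v, c in zip(values, counts)}

    def class_table(self) -> list[dict]:
        """One row per present class: label, channel combination, count."""
        rows = []
        for label, count in self.class_counts().items():
            combo = "+".join(
                name for c, name in enumerate(self.names) if label >> c & 1
            )
            rows.append(
                {"label": label, "channels": combo or "none", "pixels": count}
            )
        return rows

    def decode(self) -> ChannelMaskStack:
        """Recover the original channel masks by bit extraction."""
        masks = [
            (self.labels >> c & 1).astype(bool) for c in range(self.num_channels)
        ]
        return ChannelMaskStack(masks=masks, names=list(self.names))


def colocalization_labels(stack: ChannelMaskStack) -> ColocalizationLabelImage:
    """Combine C binary channel masks into a single 2**C-class label image."""
    labels = np.zeros(stack.masks[0].shape, dtype=np.int32)
    for c, mask in enumerate(stack.masks):
        labels |= mask.astype(np.int32) << c
    return ColocalizationLabelImage(labels=labels, names=list(stack.names))


def decode_labels(labels: npt.ArrayLike, num_channels: int) -> list[np.ndarray]:
    """Bit-extract the per-channel foreground masks from a label image."""
    arr = np.asarray(labels)
    return [(arr >> c & 1).astype(bool) for c in range(int(num_channels))]


def multiplex_cumulative(
    channels: Sequence[npt.ArrayLike],
    per_channel_theta: Sequence[float],
    scales: Iterable[int],
    mode: str = "independent",
    names: Sequence[str] | None = None,
) -> ChannelMaskStack:
    """Filter each channel independently; return per-channel foreground masks.

    All channels share the scale set; the threshold may differ per channel
    (markers differ in contrast — e.g. a dim membrane marker needs a higher
    theta than a bright nuclear stain).
    """
    channels = list(channels)
    thetas = [float(t) for t in per_channel_theta]
    if len(thetas) != len(channels):
        raise ValueError(
            f"got {len(channels)} channels but {len(thetas)} theta values"
        )
    scales = tuple(scales)
    masks = [
        cumulative_lmsf(ch, scales, th, mode=mode).foreground
        for ch, th in zip(channels, thetas)
    ]
    if names is None:
        names = [f"channel{i}" for i in range(len(channels))]
    return ChannelMaskStack(masks=masks, names=list(names))


def apply_background_mask(
    image: npt.ArrayLike, background: npt.ArrayLike
) -> np.ndarray:
    """Zero the background pixels of an image; foreground is untouched.

    This is the denoising step handed to a downstream segmenter.  Idempotent
    for a fixed mask.
    """
    img = np.asarray(image)
    bg = np.asarray(background, dtype=bool)
    if bg.shape != img.shape:
        raise ValueError(
            f"mask shape {bg.shape} does not match image shape {img.shape}"
        )
    out = img.copy()
    out[bg] = 0
    return out
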