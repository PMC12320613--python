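"""Image and table I/O plus overlay rendering.

Supported pixel formats: grayscale TIFF (8/16-bit, single- or multi-page —
multi-page is the multiplexed-channel interchange format, channel order =
page order) and 8-bit grayscale PNG.  1-D signals travel as CSV columns.
Binary masks are written as 8-bit images, foreground white (255) by default;
overlays draw the foreground boundary in green over the (optionally
gamma-corrected, display only) input.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import numpy.typing as npt
import tifffile
from skimage.segmentation import find_boundaries

from .applications import ColocalizationLabelImage
from .cumulative import CumulativeResult

__all__ = [
    "read_image",
    "write_image",
    "write_mask",
    "make_overlay",
    "write_outputs",
    "read_signal_csv",
    "write_signal_csv",
    "write_class_table",
    "write_scene",
]

_TIFF_SUFFIXES = {".tif", ".tiff"}


def _check_loaded(arr: np.ndarray, path: Path) -> np.ndarray:
    if arr.ndim != 2:
        raise ValueError(f"{path}: expected a 2-D grayscale image, got shape {arr.shape}")
    if np.issubdtype(arr.dtype, np.signedinteger) and arr.min() < 0:
        raise ValueError(f"{path}: negative intensities are not supported")
    return arr


def read_image(
    path: str | Path, channel: int | None = None
) -> np.ndarray | list[np.ndarray]:
    """Read a grayscale TIFF or PNG.

    Multi-page TIFFs return a list of same-shape channel images in page
    order.  RGB(A) PNGs are rejected unless ``channel`` selects one color
    plane.  Pixel values are returned losslessly in the stored dtype.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in _TIFF_SUFFIXES:
        arr = tifffile.imread(path)
        if arr.ndim == 3:
            pages = [_check_loaded(p, path) for p in arr]
            if len({p.shape for p in pages}) > 1:
                raise ValueError(f"{path}: TIFF pages have differing shapes")
            if channel is not None:
                return pages[channel]
            return pages
        return _check_loaded(arr, path)
    if suffix == ".png":
        arr = iio.imread(path)
        if arr.ndim == 3:
            if channel is None:
                raise ValueError(
                    f"{path}: RGB PNG requires a channel selector (--channel)"
                )
            arr = arr[..., channel]
        return _check_loaded(arr, path)
    raise ValueError(f"{path}: unsupported image format {suffix!r} (use TIFF or PNG)")


def write_image(path: str | Path, image: npt.ArrayLike | Sequence[npt.ArrayLike]) -> None:
    """Write a grayscale image (TIFF/PNG) or a list of channels (multi-page TIFF)."""
    path = Path(path)
    suffix = path.suffix.lower()
    if isinstance(image, (list, tuple)):
        if suffix not in _TIFF_SUFFIXES:
            raise ValueError(f"{path}: multi-channel output requires TIFF")
        tifffile.imwrite(path, np.stack([np.asarray(c) for c in image]),
                         photometric="minisblack")
        return
    arr = np.asarray(image)
    if suffix in _TIFF_SUFFIXES:
        tifffile.imwrite(path, arr)
    elif suffix == ".png":
        iio.imwrite(path, arr)
    else:
        raise ValueError(f"{path}: unsupported image format {suffix!r}")


def write_mask(
    path: str | Path, background: npt.ArrayLike, polarity: str = "white-foreground"
) -> None:
    """Write a background mask as an 8-bit binary image.

    ``white-foreground`` (default): foreground 255, background 0, matching
    the usual binary-segmentation rendering; ``black-foreground`` flips it.
    """
    bg = np.asarray(background, dtype=bool)
    if polarity == "white-foreground":
        out = np.where(bg, 0, 255).astype(np.uint8)
    elif polarity == "black-foreground":
        out = np.where(bg, 255, 0).astype(np.uint8)
    else:
        raise ValueError(f"unknown polarity {polarity!r}")
    write_image(path, out)


def make_overlay(
    image: npt.ArrayLike, foreground: npt.ArrayLike, gamma: float | None = None
) -> np.ndarray:
    """RGB rendering of the image with green contours around the foreground.

    Contours are the inner 4-connected boundary of the foreground components.
    ``gamma`` applies a display-only power-law stretch (gamma < 1 reveals dim
    structure); it never feeds back into filtering.
    """
    img = np.asarray(image, dtype=np.float64)
    fg = np.asarray(foreground, dtype=bool)
    if fg.shape != img.shape:
        raise ValueError("foreground mask shape does not match image shape")
    top = img.max()
    norm = img / top if top > 0 else img
    if gamma is not None:
        if gamma <= 0:
            raise ValueError("gamma must be positive")
        norm = norm ** gamma
    gray = (norm * 255).round().astype(np.uint8)
    rgb = np.stack([gray, gray, gray], axis=-1)
    contour = find_boundaries(fg, connectivity=1, mode="inner")
    rgb[contour] = (0, 255, 0)
    return rgb


def write_outputs(
    result: CumulativeResult,
    image: npt.ArrayLike,
    out_filtered: str | Path | None = None,
    out_mask: str | Path | None = None,
    out_overlay: str | Path | None = None,
    polarity: str = "white-foreground",
    gamma: float | None = None,
) -> None:
    """Write any of the requested products of a cumulative filter run."""
    if out_filtered is not None:
        write_image(out_filtered, result.filtered)
    if out_mask is not None:
        write_mask(out_mask, result.background, polarity=polarity)
    if out_overlay is not None:
        iio.imwrite(Path(out_overlay), make_overlay(image, result.foreground, gamma))


def read_signal_csv(path: str | Path, column: str | int = 0) -> np.ndarray:
    """Read one numeric column from a CSV file (by header name or index)."""
    import pandas as pd

    frame = pd.read_csv(path)
    series = frame.iloc[:, column] if isinstance(column, int) else frame[column]
    return series.to_numpy(dtype=np.float64)


def write_signal_csv(
    path: str | Path, signal: npt.ArrayLike, filtered: npt.ArrayLike
) -> None:
    """Write original and filtered signal samples side by side."""
    import pandas as pd

    pd.DataFrame(
        {"signal": np.asarray(signal), "filtered": np.asarray(filtered)}
    ).to_csv(path, index=False)


def write_class_table(path: str | Path, coloc: ColocalizationLabelImage) -> None:
    """CSV sidecar mapping label -> channel combination -> pixel count."""
    rows = coloc.class_table()
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=["label", "channels", "pixels"])
        writer.writeheader()
        writer.writerows(rows)


def write_scene(
    path: str | Path, image: npt.ArrayLike, background: npt.ArrayLike
) -> None:
    """Save a synthetic scene as a 2-page 16-bit TIFF: image, then mask.

    The ground-truth background page stores 65535 for background, 0 for
    foreground.  Intensities are rounded to the nearest integer and clipped
    to the 16-bit range.
    """
    img = np.asarray(image, dtype=np.float64)
    pixels = np.clip(np.round(img), 0, 65535).astype(np.uint16)
    mask = np.where(np.asarray(background, dtype=bool), 65535, 0).astype(np.uint16)
    tifffile.imwrite(Path(path), np.stack([pixels, mask]), photometric="minisblack")
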