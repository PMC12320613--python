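"""Deterministic generators for fluorescence-like test inputs.

Everything the test suite and the worked examples consume is generated here:
1-D reference signals (sine-squared, plateau/gap steps) and 2-D scenes of
blob-shaped objects on a noisy background with an exactly known ground-truth
background mask.  A scene is a pure function of its :class:`SceneSpec`
(including the seed), so identical specs give bit-identical images.

Blobs emulate nuclei: ``flat`` disks (uniform stain), ``gaussian`` profiles
(intensity falling off from the center, truncated at the support radius so
the ground truth stays crisp), and ``rim`` profiles (bright edge, dim
interior — the nucleus-membrane geometry that defeats purely local
binarizers).  The scene background is a constant level, optionally with a
linear gradient, plus Gaussian and/or Poisson noise, clipped at zero.

These scenes stand in for real tissue images.  They share the features the
filter keys on — intensity ratios, gap geometry, noise — but not the full
texture of tissue (no point-spread blur, no autofluorescence structure), so
passing tests demonstrate the mechanics of the method, not clinical-grade
performance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .cumulative import scales_from_background_width

__all__ = [
    "BlobSpec",
    "SceneSpec",
    "make_sine_squared_signal",
    "make_step_gap_signal",
    "make_scene",
    "dense_blob_spec",
    "dense_scene_scales",
    "sparse_blob_spec",
    "two_plateau_gap_image",
]

PROFILES = ("flat", "gaussian", "rim")

#: Fraction of the support radius occupied by the bright band of a rim blob.
RIM_BAND_FRACTION = 0.3
#: Interior intensity of a rim blob relative to its rim peak.
RIM_CORE_LEVEL = 0.25


@dataclass(frozen=True)
class BlobSpec:
    """One blob: center (row, col), support radius, peak intensity, profile."""

    center: tuple[float, float]
    radius: float
    peak: float
    profile: str = "flat"

    def __post_init__(self) -> None:
        if self.radius < 1:
            raise ValueError("blob radius must be >= 1 pixel")
        if self.peak <= 0:
            raise ValueError("blob peak intensity must be positive")
        if self.profile not in PROFILES:
            raise ValueError(f"profile must be one of {PROFILES}, got {self.profile!r}")


@dataclass
class SceneSpec:
    """Full description of a synthetic scene; with the seed it determines
    the image and its ground-truth background mask exactly."""

    shape: tuple[int, int]
    blobs: list[BlobSpec] = field(default_factory=list)
    background_level: float = 0.0
    gradient: tuple[float, float] | None = None  # intensity per pixel (row, col)
    noise_sigma: float = 0.0
    poisson: bool = False
    seed: int = 0

    def to_dict(self) -> dict:
        """Plain-Python representation (YAML/JSON serializable)."""

        def plain(obj):
            if isinstance(obj, dict):
                return {k: plain(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [plain(v) for v in obj]
            if isinstance(obj, np.integer):
                return int(obj)
            if isinstance(obj, np.floating):
                return float(obj)
            return obj

        return plain(asdict(self))


def make_sine_squared_signal(
    num_periods: int, samples_per_period: int
) -> np.ndarray:
    """Samples of ``sin^2(t)`` on a uniform grid covering whole periods.

    The period of ``sin^2`` is pi, so sample ``j`` sits at
    ``t_j = j * pi / samples_per_period`` for
    ``j = 0 .. num_periods * samples_per_period - 1``.
    """
    num_periods = int(num_periods)
    samples_per_period = int(samples_per_period)
    if num_periods < 1 or samples_per_period < 1:
        raise ValueError("num_periods and samples_per_period must be >= 1")
    j = np.arange(num_periods * samples_per_period)
    t = j * (np.pi / samples_per_period)
    return np.sin(t) ** 2


def make_step_gap_signal(
    high: float,
    gap_widths: list[int],
    plateau_width: int = 10,
    low: float = 0.0,
) -> np.ndarray:
    """Piecewise-constant signal: plateaus at ``high`` separated by gaps.

    ``len(gap_widths) + 1`` plateaus of ``plateau_width`` samples alternate
    with gaps of the requested widths at level ``low`` (default 0).  Emulates
    high-level signal regions separated by narrow and wide background gaps;
    a nonzero ``low`` reproduces the regime where a very large window no
    longer identifies narrow gaps (the gap level stays above the threshold
    times the near-global mean).
    """
    high = float(high)
    low = float(low)
    if high <= low:
        raise ValueError("plateau level must exceed the gap level")
    plateau = np.full(int(plateau_width), high)
    parts = [plateau]
    for w in gap_widths:
        parts.append(np.full(int(w), low))
        parts.append(plateau)
    return np.concatenate(parts)


def _render_blob(image: np.ndarray, support: np.ndarray, blob: BlobSpec) -> None:
    K, M = image.shape
    r0, c0 = blob.center
    rad = blob.radius
    if not (rad <= r0 <= K - 1 - rad and rad <= c0 <= M - 1 - rad):
        raise ValueError(
            f"blob at {blob.center} with radius {rad} does not fit inside "
            f"a {K}x{M} image"
        )
    lo_r, hi_r = int(np.floor(r0 - rad)), int(np.ceil(r0 + rad)) + 1
    lo_c, hi_c = int(np.floor(c0 - rad)), int(np.ceil(c0 + rad)) + 1
    rr, cc = np.meshgrid(
        np.arange(lo_r, hi_r), np.arange(lo_c, hi_c), indexing="ij"
    )
    dist = np.hypot(rr - r0, cc - c0)
    inside = dist <= rad
    patch = np.zeros(dist.shape)
    if blob.profile == "flat":
        patch[inside] = blob.peak
    elif blob.profile == "gaussian":
        sigma = rad / 3.0  # support truncates the profile at 3 sigma
        patch[inside] = blob.peak * np.exp(-0.5 * (dist[inside] / sigma) ** 2)
    else:  # rim
        band = dist >= rad * (1.0 - RIM_BAND_FRACTION)
        patch[inside & band] = blob.peak
        patch[inside & ~band] = blob.peak * RIM_CORE_LEVEL
    image[lo_r:hi_r, lo_c:hi_c] += patch
    support[lo_r:hi_r, lo_c:hi_c] |= inside


def make_scene(spec: SceneSpec) -> tuple[np.ndarray, np.ndarray]:
    """Render a scene: returns ``(image, background_mask)``.

    The ground-truth background is everything outside the union of blob
    supports, fixed before noise is applied.  Intensities are clipped at 0.
    """
    K, M = (int(s) for s in spec.shape)
    if K < 1 or M < 1:
        raise ValueError("scene shape must be at least 1x1")
    image = np.full((K, M), float(spec.background_level))
    if image.min() < 0:
        raise ValueError("background level must be non-negative")
    if spec.gradient is not None:
        gr, gc = spec.gradient
        image += gr * np.arange(K)[:, None] + gc * np.arange(M)[None, :]
    support = np.zeros((K, M), dtype=bool)
    for blob in spec.blobs:
        _render_blob(image, support, blob)
    rng = np.random.default_rng(spec.seed)
    if spec.poisson:
        image = rng.poisson(np.clip(image, 0, None)).astype(np.float64)
    if spec.noise_sigma > 0:
        image = image + rng.normal(0.0, spec.noise_sigma, size=image.shape)
    image = np.clip(image, 0.0, None)
    return image, ~support


def dense_blob_spec(shape: tuple[int, int] = (512, 512), seed: int = 0) -> SceneSpec:
    """Dense-foreground scene: a jittered grid of bright flat nuclei.

    At the default 512x512 shape: a 7x7 grid of radius-24 disks at peak 300
    on a level-20 background with Gaussian noise sigma 15 (5% of peak).
    Inter-blob gaps are 18-30 px and the widest background run (diagonal
    between four blobs) is ~60 px, so the half-width recipe with the default
    minimum scale gives N = {8,16,32}.  Smaller shapes get proportionally
    fewer blobs at the same ~72 px grid pitch (minimum shape 128x128).
    """
    K, M = shape
    if min(K, M) < 128:
        raise ValueError("dense_blob_spec needs a shape of at least 128x128")
    rng = np.random.default_rng(seed)
    radius, peak = 24.0, 300.0
    centers_r = np.linspace(40, K - 40, max(1, (K - 80) // 72 + 1))
    centers_c = np.linspace(40, M - 40, max(1, (M - 80) // 72 + 1))
    blobs = []
    for r in centers_r:
        for c in centers_c:
            jr, jc = rng.integers(-3, 4, size=2)
            blobs.append(BlobSpec(center=(r + jr, c + jc), radius=radius, peak=peak))
    return SceneSpec(
        shape=shape,
        blobs=blobs,
        background_level=20.0,
        noise_sigma=15.0,
        seed=seed + 1,
    )


def dense_scene_scales(spec: SceneSpec) -> tuple[int, ...]:
    """Recipe scales for :func:`dense_blob_spec` (max gap width ~64 px)."""
    return scales_from_background_width(64)


def sparse_blob_spec(shape: tuple[int, int] = (200, 200), seed: int = 0) -> SceneSpec:
    """Sparse-foreground scene: small bright blobs in a large empty field.

    5x5 grid of radius-4 disks at peak 500 over a dim background (level 2,
    sigma 0.5), the geometry under which the background identified by large
    windows saturates: once the window comfortably exceeds the blob size,
    growing it further barely changes the mask.
    """
    K, M = shape
    centers_r = np.linspace(20, K - 20, 5)
    centers_c = np.linspace(20, M - 20, 5)
    blobs = [
        BlobSpec(center=(r, c), radius=4.0, peak=500.0)
        for r in centers_r
        for c in centers_c
    ]
    return SceneSpec(
        shape=shape,
        blobs=blobs,
        background_level=2.0,
        noise_sigma=0.5,
        seed=seed + 1,
    )


def two_plateau_gap_image(
    gap: int = 6,
    margin: int = 40,
    plateau: int = 40,
    high: float = 300.0,
    low: float = 10.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Two bright rectangular objects separated by a narrow gap, surrounded
    by a wide low-level margin; returns ``(image, background_mask)``.

    A fixture for the two spatial scales of the cumulative method: a small
    window marks the narrow gap but not the wide margin; only a large window
    marks the margin.
    """
    rows = margin + plateau + margin
    half = (plateau - gap) // 2
    cols = margin + half + gap + (plateau - gap - half) + margin
    image = np.full((rows, cols), float(low))
    fg = np.zeros((rows, cols), dtype=bool)
    r0, r1 = margin, margin + plateau
    c_left = (margin, margin + half)
    c_right = (margin + half + gap, margin + plateau)
    for c0, c1 in (c_left, c_right):
        image[r0:r1, c0:c1] = high
        fg[r0:r1, c0:c1] = True
    return image, ~fg
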