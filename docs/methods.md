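# Methods

## The filter

The local mean suppression filter compares each sample with the mean of its
local neighborhood. For a 1-D signal *s_k* (k = 0…K−1) with half-window *n*:

    ŝ_k = 0    if s_k < θ · s̄_k
    ŝ_k = s_k  otherwise,       s̄_k = mean of s over [k−n, k+n] ∩ [0, K−1]

and analogously in 2-D with square windows [k−n, k+n] × [m−n, m+n]. The
output always has the input's shape and dtype, and every output value is
either 0 or the original value — the filter labels, it never re-scales.
Because the rule depends only on the intensity *ratio*, the background mask
is invariant under global intensity scaling (gain, exposure).

Motivation for the default θ: for the analog test signal sin²(t), the local
mean over a window of half-length T is

    s̄(t) = 1/2 − (cos 2t / 2) · (sin 2T / 2T),

which is exactly 1/2 whenever the window spans an integer number of periods
(T = kπ/2). At θ = 0.5 the filter then suppresses precisely the values below
0.25; at θ = 1, below 0.5. These two numbers are what
`scripts/acceptance.py` recomputes.

### Numerical choices

- **Adaptive edges, no padding.** Border means average only the pixels that
  exist: the end point of a signal averages n+1 samples, the next n+2, etc.;
  in 2-D the divisor is the area of window ∩ image, which is separable in
  rows × columns. A constant image therefore has a constant local mean all
  the way into the corners — the test suite asserts this, since any padding
  scheme fails it. The 2-D edge rule is the natural extension of the 1-D
  definition; it is a design choice of this package.
- **Summed-area tables.** Window sums come from an integral image and the
  divisor from the clipped index arithmetic, giving O(KM) per scale
  independent of *n*, accumulated in double precision. A brute-force
  per-pixel window oracle (`oracle_lmsf_2d`) validates the fast path to
  1e−9 relative on random images; the suite runs >200 such comparisons.
- **Multiplicative comparison.** The rule is evaluated as `I < θ·Ī`, not
  `I/Ī < θ`, avoiding 0/0 for all-zero windows; for Ī > 0 the two are
  identical. A pixel with intensity exactly 0 always ends as background
  (either 0 < θ·Ī, or it is already zero when Ī = 0).
- **Ties.** `I = θ·Ī` keeps the pixel (the strict `<` of the rule); the
  constant image at θ = 1 is therefore all foreground, and at any θ > 1 all
  background.
- **Bounds.** The public multi-scale entry points enforce 1 ≤ n ≤
  n_max = ⌊min(K,M)/2⌋ − 1 (images smaller than 4×4 are rejected). The 2-D
  kernels themselves accept any 1 ≤ n < min(K,M), mirroring the 1-D kernel
  whose only requirement is n < K; this keeps small worked examples (e.g. a
  3×3 spike) expressible while the method-level API stays within the bound.
- **Dtypes.** Integer images are averaged in double precision; preserved
  foreground values are returned in the input dtype. Negative intensities
  are rejected for images (fluorescence is non-negative) but allowed for
  generic 1-D signals.
- **θ range.** Any θ > 0 is accepted; values outside the recommended
  operating range 0.5 ≤ θ ≤ 1 log a warning rather than fail, since
  sweeping θ past 1 is a legitimate exploration tool.

## The cumulative method

`cumulative_lmsf(image, N, θ, mode)` combines single-scale responses.

- **independent** (default): every scale filters the original image; the
  cumulative background is the union of per-scale backgrounds. This gives
  the two monotonicity guarantees the tests assert: appending a scale never
  shrinks the background, and raising θ never shrinks it.
- **sequential**: scales run in increasing order, each on the previous
  output. Zeros are never resurrected (per-stage backgrounds are nested),
  and surviving pixels keep their original intensities, since every stage
  outputs only 0-or-original values. Sequential mode is *not* guaranteed to
  contain the independent background: zeroing pixels lowers later local
  means, which lowers the threshold θ·Ī and can rescue pixels independent
  mode would remove. Random-image counterexamples are easy to find, so this
  containment is documented as an observation that fails in general, not an
  invariant.

A single-element N reproduces the single-scale filter exactly in both modes.

**Choosing N.** For images whose background forms narrow gaps between
objects: estimate the widest background run *w* (a rough visual estimate
suffices), set max(N) = w/2 and halve downward to a minimum scale (default
5): `scales_from_background_width(80) == (5, 10, 20, 40)`. Halving uses
integer floor; the classic worked setting is a power of two so the rounding
rule only matters for odd widths. For images with a large empty background,
append n_max (`scales_for_large_background`), which exploits the
*saturation effect*: over wide low-level regions the identified background
stabilizes once the window comfortably exceeds the foreground objects, so
very large windows capture extended background without eroding small
objects. `theta_sweep` runs a fixed N over an increasing θ list for fuzzy
images where the right threshold is picked by inspection.

## Applications

- **Co-localization.** Each of C co-registered channels is filtered to a
  foreground mask (channel-specific θ, shared N); per pixel the masks are
  packed into a label `Σ_c bit_c·2^c`, first-listed channel = least
  significant bit (the encoding is this package's convention; outputs carry
  the channel names so it is self-describing). Labels decode back to the
  exact masks by bit extraction; class tables report pixel counts per
  combination. Registration is assumed done upstream.
- **Segmentation pre-processing.** `apply_background_mask` zeroes the
  identified background and returns the cleaned image for a downstream
  instance segmenter; the segmenter itself is out of scope here.

## Synthetic scenes

All tests run on generated data with exact ground truth; no microscopy data
ships with the package. A scene is blobs on a constant (optionally
linearly graded) background with Gaussian and/or Poisson noise, rendered
deterministically from a `SceneSpec` + seed. Blob profiles: `flat` disks;
`gaussian` (σ = radius/3, truncated at the support radius so ground truth
stays crisp); `rim` (bright band on the outer 30% of the radius, interior at
25% of the rim — the bright-edge/dim-core geometry that defeats purely local
binarizers). Ground-truth background = complement of the union of blob
supports, fixed before noise.

Two presets define the standing test conditions:

- **dense** (512×512): 7×7 grid of flat r=24 blobs at peak 300, centers
  jittered ±3 px, background 20, Gaussian σ=15 (5% of peak). Peak is 15×
  background, gaps run 18–30 px with ~60 px diagonal runs, so the recipe
  scales are {8, 16, 32} and every gap exceeds twice the smallest scale. On
  these scenes the cumulative filter at θ=0.5 recovers the foreground with
  pixel precision and recall ≥ 0.9 (the suite checks three seeds).
- **sparse** (200×200): 5×5 grid of r=4 blobs at peak 500 on a dim floor
  (level 2, σ=0.5), the geometry for the saturation checks: foreground masks
  at n = 36…90 and at n_max = 99 differ on well under 1% of foreground
  pixels.

These scenes share with real tissue the features the filter actually uses —
intensity ratios, gap geometry, noise — but not point-spread blur,
autofluorescence texture, or out-of-focus light. Passing tests demonstrate
the mechanics and the published parameter recipes, not clinical performance
on tissue.

The problem sizes used throughout (512×512 recovery scenes, ≤40×40 oracle
comparisons, 200×200 saturation scenes) were chosen as the smallest sizes at
which the respective geometric regimes — multi-scale gaps, window clipping,
saturation — are unambiguously present.

## Known limitations

- 2-D only; volumetric (3-D) filtering is not implemented.
- The maximal background gap width is supplied by the user, not estimated
  from the image.
- One θ per channel across all scales; no per-scale θ schedules.
- Isolated bright noise far from any foreground can survive all scales in
  very heterogeneous backgrounds (small false-positive foreground specks);
  standard post-processing (blur + global threshold) removes them if needed.
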