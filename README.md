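# lmsf — local mean suppression filtering for fluorescence images

Fluorescence microscopy images of tissue sections mix bright, densely packed
objects (nuclei, membranes) with dim foreground and a noisy, spatially varying
background. Before any quantitative analysis — co-localization, instance
segmentation, spatial statistics — the background has to be identified and
removed, and global thresholds fail exactly where tissue is interesting: at
low-contrast objects and fuzzy transitions.

`lmsf` implements the **local mean suppression filter**: for a pixel with
intensity *I(k,m)* and local mean *Ī(k,m)* over a *(2n+1)×(2n+1)* window,

```
Î(k,m) = 0       if I(k,m) / Ī(k,m) < θ
Î(k,m) = I(k,m)  otherwise
```

so a pixel is background when it falls below a fraction θ of its
neighborhood mean. Local means use *adaptive* windows — near the image border
only the pixels that exist are averaged, never padded values — and are
computed with summed-area tables in O(KM) regardless of *n*. The half-window
is bounded by *n*<sub>max</sub> = ⌊min(K,M)/2⌋ − 1.

One window size sees one spatial scale. The **cumulative method** runs the
filter over an increasing scale set *N* = {n₁ < … < n_L} and takes the union
of the per-scale backgrounds (Boolean AND of foregrounds): small windows find
the narrow gaps between touching objects, large windows find wide empty
regions. θ = 0.5 is a good default, with 0.5 ≤ θ ≤ 1 the useful range for
fuzzy images. For narrow-gap images, set max(*N*) to half the widest
background gap and halve downward (`scales_from_background_width`); for large
empty backgrounds, append *n*<sub>max</sub> (`scales_for_large_background`).

Also included: per-channel filtering of multiplexed images with 2^C-class
co-localization labeling, background removal as a segmentation pre-processing
step, and deterministic synthetic scene generators with exact ground truth.

## Worked example

Generate a 512×512 synthetic nuclei scene and identify its background:

```sh
$ lmsf synth --preset dense --seed 0 --out scene.tif
wrote scene.tif: shape (512, 512), foreground fraction 0.335

$ lmsf filter scene.tif --channel 0 --theta 0.5 --auto-gap-width 64 \
      --out-mask mask.png --out-overlay overlay.png --gamma 0.5
INFO lmsf: filter: theta=0.5 N=[8, 16, 32] mode=independent n_max=255
background: 172781 of 262144 pixels (65.9%)
```

`--auto-gap-width 64` applies the halving recipe (widest background run
≈ 64 px → scales 8, 16, 32). The filter marks 65.9% of pixels as background,
matching the scene's 33.5% generated foreground; against the ground-truth
page of `scene.tif` this mask scores pixel precision 0.983 and recall 1.000.
`mask.png` is the binary segmentation (foreground white), `overlay.png`
draws green foreground contours over the γ-corrected input.

The same from Python:

```python
import lmsf

image, true_bg = lmsf.make_scene(lmsf.synthetic.dense_blob_spec(seed=0))
result = lmsf.cumulative_lmsf(image, scales=(8, 16, 32), theta=0.5)
result.background      # boolean mask, True = background
result.filtered        # original intensities, background zeroed
```

Multiplexed co-localization (one θ per channel, shared scales):

```python
stack = lmsf.multiplex_cumulative(channels, [0.5, 0.95, 0.6],
                                  scales=(5, 10, 20, 40, 80, 160, 499))
labels = lmsf.colocalization_labels(stack)   # 2^3 = 8 classes
labels.class_table()
```

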