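# flocia

**Flower color image analysis** for ray-floret phenotyping of composite
flowers (Asteraceae, e.g. ornamental sunflower).

Breeders score ray-floret ("petal") color against the seven categories of
the UPOV sunflower descriptor — *yellowish white, light yellow, medium
yellow, orange yellow, orange, purple, reddish brown* — by eye, which is
subjective and poorly repeatable.  `flocia` replaces the eyeball with a
digital pipeline: it segments a single flower head photographed on a
near-white background, removes the textured central disk, and classifies
every remaining ray-floret pixel into a UPOV category, reporting the
percentage of pixels per category so a human can make the final call
(including whether the flower is *multicolored*).

## Method

1. **Background removal** — the near-white backdrop is identified in HSV
   (value ≥ 0.85, saturation ≤ 0.15); the complement, reduced to its
   largest connected component and hole-filled, is the flower.
2. **Disk removal** — disk florets share hues with the petals but are far
   more textured.  A local standard-deviation filter (5×5) on the
   intensity image yields a texture-energy map; thresholding it inside
   the flower (Otsu), followed by morphological closing/opening, isolates
   the disk.  `ray = flower ∧ ¬disk`.
3. **Color representation** — pixels are converted to CIE L\*a\*b\*
   (sRGB primaries, D65 white point) and stored in an 8-bit offset
   encoding: `L8 = L*·255/100`, `a8 = a* + 128`, `b8 = b* + 128`.
4. **Dominant clusters** — k-means (k ≤ 3, seeded) on the chroma plane
   (a8, b8); lightness is ignored so uneven illumination does not split
   a color.  The two largest clusters are the flower's dominant colors.
5. **Classification** — each ray pixel is assigned to the category *c*
   minimizing the Euclidean distance ‖(a8, b8) − μ_c‖ to the reference
   palette mean vectors μ_c; the report gives
   `pct_c = 100 · n_c / n_ray` and the overall mean Lab8 vector.
6. **Evaluation** — matching/confusion matrices, accuracy
   (trace / total), per-category precision (diagonal / column sum), and
   Fleiss' κ with the conventional strength-of-agreement bands
   (κ ∈ [0.4, 0.6) → "moderate", etc.).

An optional hue gamut filter (keep 17.99° ≤ H ≤ 66.95°, S ≥ 12.5 % of the
maximum observed saturation) restricts analysis to the yellow–red region;
it is off by default because purple and reddish-brown petals are valid
categories.

Because official UPOV exemplar scans are not redistributable, the package
ships a default palette built from synthetic flat-color swatches; rebuild
from real exemplar images with `flocia palette build`.

## Worked example

Render a synthetic three-color flower (60 % medium yellow, 30 % orange,
10 % reddish brown) and classify it:

```sh
echo '{"composition": {"medium yellow": 0.6, "orange": 0.3, "reddish brown": 0.1}}' > spec.json
flocia simulate --out sim --n 1 --seed 7 --spec spec.json
flocia classify sim/flower_000.png --seed 7 --report report.json
```

`report.json` then contains (abridged):

```json
{
  "dominant_category": "medium yellow",
  "multicolored": true,
  "n_pixels": 25797,
  "percentages": {"medium yellow": 59.76, "orange": 30.15, "reddish brown": 9.93},
  "mean_vector": [179.21, 143.27, 195.40]
}
```

The 25 797 segmented ray pixels split 59.76/30.15/9.93 % across the three
painted categories — within a few tenths of a point of the rendered
ground truth — and the flower is flagged multicolored because two
categories exceed the 20 % threshold.  The mean vector is the flower's
average Lab8 color (the "dominant color dot" in `flocia plot` scatter
plots).  All randomness (k-means initialization, rendering noise) is
controlled by `--seed`, so reruns are byte-identical.

The same library surface is importable from Python
(`from flocia import classify_image, default_palette, ...`); see
`docs/methods.md` for the model details and parameter defaults.

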