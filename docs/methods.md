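# Methods

## Scope and model

`flocia` quantifies the ray-floret color of a single composite flower
head from one RGB photograph taken on a near-white background.  The
underlying model is deliberately simple: flower color is summarized by
the empirical distribution of ray-floret pixels in the chroma plane of
CIE L\*a\*b\*, and categorical scoring is nearest-centroid assignment to
seven fixed UPOV reference vectors.  No learning is involved; every step
is a deterministic image operation plus one seeded k-means.

### Lab8 encoding

All color distances use an 8-bit offset encoding of CIE L\*a\*b\*
(`L8 = L*·255/100`, `a8 = a* + 128`, `b8 = b* + 128`, clipped to
[0, 255]).  This is the common convention for storing Lab in 8-bit
buffers; it keeps all three channels on one scale and makes neutral
gray sit at (·, 128, 128).  Conversions assume sRGB primaries, the
IEC 61966-2-1 transfer function, and the D65 white point — i.e. ordinary
consumer-camera output.  No color-constancy or white-balance correction
is attempted (out of scope); the acquisition protocol (diffuse morning
light, white cloth) is assumed to control illumination.

### Segmentation

*Background*: a pixel is background when `V >= white_thresh` (default
0.85) and `S <= sat_thresh` (default 0.15) in HSV.  The defaults
tolerate a shaded white cloth; both are configurable.  The foreground is
the largest connected component of the complement, hole-filled.

*Disk removal*: disk florets are distinguished from petals by texture,
not color.  The texture statistic is the local population standard
deviation over a `window × window` neighborhood (default 5×5, reflection
padding).  `texture_energy_map` optionally histogram-equalizes its input
first (the default contract, useful when comparing texture across
differently exposed photographs) — but `segment_disk` deliberately
thresholds the **raw-amplitude** map after percentile contrast
stretching (2nd–98th).  The reason is structural: global rank
equalization redistributes intensities by pixel mass, which caps the
local standard deviation attainable inside any region at roughly that
region's area fraction.  A compact disk occupying ~10 % of the image can
therefore never exceed an amplitude threshold on a rank-equalized map,
no matter how strong its speckle; on the raw map the disk's local
deviation exceeds smooth petals by an order of magnitude.  The threshold
is Otsu's method over foreground texture values (a quantile override is
available), followed by morphological closing then opening (disk-shaped
structuring element, radius 2), largest-component selection, hole
filling, and erosion by `window // 2` pixels to undo the half-window
smear the std filter produces at region boundaries.

*Gamut filter*: the optional yellow–red HSV gate keeps
`17.99° <= H <= 66.95°` and `S >= 0.125 · S_max`.  `S_max` defaults to
the maximum saturation over the evaluated pixels rather than the
theoretical 1.0, which makes the 12.5 % rule robust to exposure; a flag
switches to the absolute convention.  The gate is **off** by default in
the pipeline because purple and reddish-brown are legitimate categories
that it would delete.

### Clustering and classification

k-means (k = 3 by default, seeded, `n_init=10`) runs on (a8, b8) only;
lightness is excluded so that shading gradients do not split one petal
color into several clusters.  Two degeneracy guards reduce the effective
cluster count: fewer distinct chroma values than k, and post-hoc fusion
of centers closer than `merge_radius` (default 8 Lab8 units) — forcing
k = 3 onto a one- or two-color flower otherwise splits a tight color
blob into arbitrary halves and makes "the two dominant clusters"
meaningless.  The two largest (post-merge) clusters are reported as the
dominant colors.

Pixel classification is independent of the clustering: every ray pixel
goes to the category with the nearest palette mean vector, Euclidean on
(a8, b8) by default, with a `use_L` flag to include lightness.  The
ab-plane default extends the same illumination-invariance rationale used
for clustering; it is a genuine open choice and the flag preserves the
alternative.  Ties break to the lowest category index (descriptor
order).  The reported *mean vector* is the mean over **all** ray pixels,
not over the top cluster, so it summarizes the whole flower.

A flower is judged *multicolored* when at least two categories each
exceed a threshold (default 20 % — chosen so that a flower with three
colors near 30/22/21 % is comfortably flagged while a 90/10 flower is
not).  Multicolored is a derived judgment, never a palette class.

### Reference palette

The palette is the ordered map of the seven categories to mean Lab8
vectors, built by pooling masked exemplar pixels per category
(order-invariant arithmetic mean; all three channels are stored even
though classification may ignore L).  Exactly 7 entries, pairwise
distinct, values in [0, 255] — violations raise.  JSON persistence
serializes vectors as decimal text and round-trips exactly.  The default
palette is built from **synthetic** flat-color swatches (one plausible
sRGB color per category name, declared in
`flocia.palette.DEFAULT_SWATCH_RGB`); it is not calibrated against any
official descriptor scan, and any real calibration set can be swapped in
via `flocia palette build`.

### Evaluation statistics

Accuracy is `trace/total` of a square count matrix.  Per-category
precision is the diagonal cell over the predicted-column sum; a category
never predicted is reported as undefined (`None`), distinct from 0.  A
row-oriented (recall-like) reading can be obtained by transposing the
matrix.  Fleiss' κ follows the standard algebra
(`P_i = (Σ_j n_ij² − n)/(n(n−1))`, `P̄_e = Σ_j p_j²`,
`κ = (P̄ − P̄_e)/(1 − P̄_e)`); when all mass falls in one category
(`P̄_e = 1`) the statistic is 1 under unanimity and NaN otherwise.  The
implementation is cross-checked against
`statsmodels.stats.inter_rater.fleiss_kappa` in the test suite.  κ
requires one category per rater per subject; how multi-color answers
from human raters should be collapsed to a single label is left to the
caller.  Strength-of-agreement bands are left-closed/right-open
([0.4, 0.6) → "moderate") with the top band closed at 1.0, so a boundary
value belongs to the stronger band; κ ≤ 0 is labeled "poor/none".

## Synthetic data

`generate_flower` renders a scalloped ring of petals (rounded wedges,
12 % lobe depth, 16 lobes) around a central disk on a near-white
background, at 256×256 by default — large enough for stable texture and
cluster statistics while keeping a 20-fixture acceptance run in seconds.
Petal colors are the palette swatch colors, assigned by angular sector
in the requested proportions; ground-truth fractions are measured from
the rendered mask, so they agree with the request to within pixel
quantization (≤ 1 point).  Petal chroma noise is a Gaussian random field
on (a8, b8) with σ = 3 Lab8 units and a **3-pixel spatial correlation
length**: real petal color varies smoothly, and spatially white noise
would be indistinguishable from disk speckle under any windowed-variance
statistic.  Lightness carries a mild radial shading gradient (−8 % at
the rim) to stress the ab-plane design.  The disk is a dark base color
with per-pixel uniform speckle (±60 8-bit units), i.e. genuinely
high-frequency texture.  Fixed spec + seed gives byte-identical output.

What the fixtures do **not** emulate: specular highlights, shadows cast
on the backdrop, petal overlap and translucency, chromatic aberration,
JPEG artifacts, or multi-flower scenes.  Passing the recovery tests
therefore demonstrates the pipeline's internal correctness and its
robustness to smooth chroma noise and shading — not performance on field
photographs, which additionally depends on exposure control and palette
calibration.

`generate_ratings` draws a uniform true category per subject; each rater
reports it with probability `agreement`, else a uniform other category.
`agreement = 1/k` makes ratings independent and uniform, the chance
model under which κ concentrates at 0.

## Numerical choices and degenerate inputs

- Windowed variance is computed as `E[x²] − E[x]²` via uniform filters
  (clamped at 0 before the square root); the suite verifies equality
  with a direct per-neighborhood loop at 1e-12.
- Reflection padding everywhere (scipy convention, edge pixel
  duplicated); row-major, 0-based pixel-center coordinates.
- All-white images yield empty masks and a degenerate zero-pixel report
  with a `DegenerateInputWarning`, never an exception.
- Percentages use exact integer counts, so conservation
  (Σ = 100 ± 0.01) holds by construction; the report validates it.
- Every stochastic step (k-means init, rendering noise, plot
  subsampling) takes an explicit integer seed; identical seed + input
  gives identical output, which the suite asserts.

## Known limitations

- The default palette is synthetic; absolute category boundaries on real
  photographs require rebuilding the palette from calibrated exemplars.
- Texture thresholding assumes the disk is the single most textured
  connected region; heavily textured petals (e.g. strong venation at
  high resolution) could be mistaken for disk.
- One flower per image; no occlusion or instance handling.
- κ is reported without confidence intervals.
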