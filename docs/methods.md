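# Methods

## Measurement model

A whole-colony image is reduced to a single filamentation index. The
colony is modelled as a bright central mass with thin filamentous
(pseudohyphal) protrusions on a darker agar background. Two boundaries are
measured on the binarized image: the external boundary of the whole
void-filled colony component (enclosed area *A*_outer, px²) and the
boundary of the central mass after protrusions are stripped by
morphological opening (*A*_inner, px²). The index

    f = (A_outer − A_inner) / A_inner

is a dimensionless fraction, matching the magnitudes of published
composite tables; the CLI's `--percent` switch multiplies reported values
by 100 for a percent-change reading.
*f* ≥ 0 by construction because opening is anti-extensive: the inner mask
is always a subset of the outer one. With a pixel pitch (the reference
imaging setup is 2.2 µm/px at 2.5× total magnification), areas are also
reported in µm² via pitch².

### Stage choices and parameters

| parameter | default | units | rationale |
|---|---|---|---|
| `resolution` | 2560 × 1920 | px | fixed working resolution; inputs are scaled (aspect-preserving) and padded with the image's own border level, since anisotropic stretch would bias the area ratio. Downscaling is anti-aliased, upscaling bilinear, to avoid aliasing thin filaments |
| `gaussian_kernel` | 5 | px | square smoothing kernel applied before thresholding |
| `gaussian_sigma` | 1.1 | px | the kernel width is conventional for a 5 × 5 kernel; exposed in config |
| `threshold` | `"auto"` | intensity | Otsu's between-class-variance criterion by exhaustive scan of all 256 integer cuts; on plateaus (clean bimodal images) the plateau midpoint is recorded so the logged threshold sits between the class levels. Manual thresholds are honoured for operator-controlled runs |
| `polarity` | foreground-bright | — | colonies brighter than agar; `foreground-dark` inverts |
| `max_void_px` | unlimited | px² | size cap for filling enclosed background pockets; border-connected background is agar and never filled |
| `opening_radius_px` | 8 | px | disc radius of the opening that isolates the central mass; removes protrusions thinner than ≈ 2·radius at working resolution |
| `pixel_pitch_um` | none | µm/px | set to 2.2 for the reference microscope |

The central-mass contour is not uniquely defined by a binary image alone;
this implementation derives it by morphological opening with a disc
structuring element because the operation is deterministic, parameterized
by a single interpretable radius, and removes exactly the structures
thinner than the element. The opening is computed with two exact Euclidean
distance transforms (erode at radius r, dilate at radius r, intersect with
the original mask), which is equivalent to a disc structuring element and
fast on multi-megapixel masks. `opening_radius_px = 0` degenerates to
inner = outer (f = 0) and is allowed but documented as degenerate. When an
image contains a second foreground component of comparable size (a
neighbouring colony), the largest is measured and the record is flagged
for manual review.

Gray conversion uses the Rec.601 weights (0.299, 0.587, 0.114) applied
according to the recorded channel order — BGR/RGB is an explicit tag on
the image container, never assumed. Binarization that yields an empty or
full-frame foreground raises a segmentation failure, the batch analogue of
rejecting an unusable photograph; in batch runs such images are skipped
and counted, not fatal.

## Outlier screening

Per experimental group (strain × compound × concentration), modified
z-scores M_i = 0.6745 (x_i − median)/MAD are computed; values with
|M_i| > 3.5 (strict) are excluded in a single pass. When MAD = 0 the scale
falls back to 1.253314 × the mean absolute deviation about the median;
when that is also 0 all scores are 0 and nothing is excluded. Groups with
fewer than 3 raw values are summarized unscreened and flagged.

Two behaviours of this rule are properties, not bugs, and are asserted as
such in the tests:

* **Non-idempotence.** Removing the upper tail shifts the median and MAD,
  so re-screening the kept values can find more outliers. On mildly skewed
  lognormal groups a second pass finds nothing in ≳ 95% of groups, but the
  rate degrades steeply with skewness (at lognormal σ ≈ 0.7 fewer than
  half of groups are stable). Screening here is single-pass by design; an
  `iterative` mode on `ModifiedZScoreFilter` re-screens until stable for
  users who want the fixed point.
* **Trimming bias.** On right-skewed data the screen preferentially trims
  the upper tail, so post-exclusion means sit a few percent below the
  distribution mean (≈ 5% for lognormal groups with cv ≈ 0.6). Published
  post-exclusion group means inherit the same bias, so simulating from
  them and re-screening compounds it slightly; the summaries are still
  within ~0.03 of the design means in the shipped designs.

## Nonparametric inference

The omnibus test is Kruskal–Wallis on pooled mid-ranks with the standard
tie correction: H = [12/(N(N+1)) Σ nᵢ(R̄ᵢ − (N+1)/2)²] / [1 − Σ(t³−t)/(N³−N)],
referred to χ² with k − 1 df. Fully degenerate input (all values tied)
raises. Dunn's pairwise comparisons use the same pooled mid-ranks with
se = √[(N(N+1)/12 − Σ(t³−t)/(12(N−1)))(1/nᵢ + 1/nⱼ)], two-sided normal
p-values, and Bonferroni adjustment p_adj = min(1, p·k(k−1)/2); Holm
step-down is available for users who find plain Bonferroni too
conservative, and `none` disables adjustment. Pairs are ordered lower
concentration first with diff = R̄_low − R̄_high, so induction at higher
doses appears as negative statistics. On continuous (f-measure-like) data
the tie terms are far below the third decimal, which is why the no-tie
closed form reproduces published standard errors exactly at the published
group sizes. Full-precision p-values are kept internally; rounding to
report precision happens only at the output layer.

## Synthetic data: what it emulates, what it does not

`render_colony` draws an idealized colony — a filled disc of known radius
plus straight radial rectangles for filaments (small angular jitter
optional via the spec's angles), bright foreground on dark agar, optional
additive Gaussian pixel noise clipped to [0, 255] — and returns exact
pixel-count ground truth from the noiseless mask: a_inner counts disc
pixels, a_outer counts pixels inside the filled external boundary of
disc ∪ filaments. Enclosed pockets between filaments count toward a_outer
only when fully surrounded by foreground, mirroring the analyzer's
hole-filling stage, so generator and pipeline share one definition of the
outer area. Zero-length filaments are no-ops; filaments whose inner end
lies outside the disc are rejected (ground truth for a disconnected
component is undefined under the single-colony model).

The generator deliberately does **not** model photorealistic colony
texture, blur/vignetting, agar artifacts, or curved/branching filaments —
straight spokes suffice to exercise the contour logic while keeping
ground truth exact. Passing tests on synthetic colonies therefore
demonstrate that the measurement chain is correct and well-calibrated on
its own geometric model; they do not certify segmentation quality on real
photographs, where threshold choice and debris handling dominate.

`simulate_fmeasures` draws per-group samples from a positive-support
family moment-matched to target (mean, sd): lognormal by default (assay
SDs scale with means and f ≥ 0), gamma, or left-truncated normal
(infeasible when sd/mean ≥ 1, reported as an error naming the group).
Groups with sd = 0 are constants. With probability `outlier_rate` a draw
is multiplied by `outlier_scale` and marked, for screening fixtures. The
shipped default designs carry the reference study's panel structure —
strain × compound panels at 0/10/50/100/200 µM with the published
post-exclusion group sizes, means and SDs — and panel seeds are offset so
panels are independent but jointly reproducible.

A two-moment simulation cannot carry every published rank statistic: where
a published control and low-dose mean differ by ~20%, moment-matched
samples separate in rank more often than the original data did (the
published pair was non-significant). The qualitative-conclusion
calibration therefore uses the panel whose control and 10 µM moments are
nearly identical, and the strong ≥ 50 µM contrasts are verified on the
anchor panel as well.

## Numerical and degenerate-input choices

* Coordinates are 0-based (x, y) = (column, row); areas are filled-pixel
  counts in px². Boundary polygons are sub-pixel 0.5-level traces whose
  shoelace areas agree with pixel counts within ~2% for foregrounds
  ≥ 500 px (asserted as a property).
* Gaussian blur uses a normalized separable kernel with edge replication,
  so constants are fixed points and mean intensity is preserved up to
  rounding; σ ≤ 0 degenerates to the identity.
* Standardization of already-conforming images is a strict no-op.
* All randomness flows through `numpy.random.default_rng` seeds recorded
  in outputs; identical seeds give byte-identical CSVs.
* Report-layer rounding is 3 decimals, matching the resolution of
  published statistical tables.

## Problem sizes in tests

The test and calibration suites run the pipeline at reduced working
resolutions (260–440 px frames, matched to the synthetic geometry) and use
20-colony recovery batches, 200-replicate qualitative calibrations and
1000-replicate type-I calibrations; these sizes give stable rates (binomial
se ≤ 2 percentage points on the calibrated quantities) while keeping the
default suite fast.

## Known limitations

* The inner/outer boundary definition assumes a single dominant colony;
  touching colonies are not split, only flagged.
* Manual per-plate thresholds used in any original assay are generally
  unpublished, so per-colony reproduction of published f values is not
  attempted — only the statistical machinery downstream of f is anchored
  to published numbers.
* The opening radius couples to filament thickness at working resolution;
  protrusions wider than ≈ 2·radius are counted as part of the central
  mass.
* Chi-square and normal reference distributions are asymptotic; for tiny
  groups (N ≤ 8) the tests' exact permutation oracle shows the H statistic
  is right even where the asymptotic p is coarse.
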