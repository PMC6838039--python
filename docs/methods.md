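# Methods

## Stain model

The toolkit treats a brightfield H&E image as a Beer–Lambert absorption
render: `I_c = I0_c · exp(−od_c)` per channel, with `od = V·S` for a 3×2
unit-column stain matrix `V` (hematoxylin, eosin) and per-pixel
concentrations `S ≥ 0` in OD units. Design choices:

* Intensities are clamped to `[1, I0]` before the log, so OD is finite and
  non-negative; the brightfield default is 255 per channel (overridable) —
  no automatic brightfield estimation is attempted.
* `V` is 3×2, so the deconvolution "inverse" is the Moore–Penrose
  pseudo-inverse: `S = V⁺·od` is the least-squares solution and `V·S` the
  orthogonal projection of the OD vector onto the stain plane. Small negative
  concentrations (projection residual artifacts) are retained in `S` but
  clipped to zero on recomposition.
* Stain estimation follows the SVD/angular-extremes approach: pixels with
  OD magnitude below 0.15 (near-brightfield) are discarded, the remaining
  cloud is reduced to its top-2 singular plane, and the stain vectors are
  read at the 1st/99th percentiles of the projected angle distribution. Both
  thresholds are configurable. Degeneracy (too few foreground pixels,
  rank-1 cloud, vanishing angular spread) raises a typed error rather than
  returning a junk matrix. Hematoxylin is identified as the column with the
  larger blue OD component (green breaks ties) — stable because hematoxylin
  is always the bluer chromophore in practice.
* Ruderman lαβ uses the published RGB→LMS constants, natural logs with an
  epsilon clamp of 1e-6 (so black pixels stay finite), and the convention
  that α is the red–green opponent channel `(log L − log M)/√2` and β the
  yellow–blue channel `(log L + log M − 2·log S)/√6` — the channel meanings
  the AMCE metric expects. The inverse uses exact matrix inverses so the
  round trip is within one 8-bit level.
* HSV hue is reported in degrees `[0, 360)`. Hue is undefined at zero
  saturation; such pixels are excluded from hue statistics through an
  explicit chromaticity mask rather than being assigned an arbitrary hue.

## Normalizers

All four methods share a `fit_reference(ref, method) → model` /
`normalize(query, model)` contract; models are JSON-serializable and
deterministic.

* **HS** builds 256-bin reference histograms per channel; normalization maps
  each query level to the smallest reference level whose CDF reaches the
  query CDF. Matching a query against its own histogram reproduces the image
  exactly, and a constant reference collapses each channel to that constant.
* **RH** matches per-channel mean and standard deviation in lαβ. Query
  channels with (numerically) zero variance get an offset-only map;
  references with zero variance in any channel are rejected at fit time
  (tolerance 1e-9, since float matrix arithmetic never yields exactly 0).
* **MC** rescales each stain's robust maximum concentration — the 99th
  percentile, configurable; a plain maximum would be noise-dominated — to
  the reference's, and recomposes with the *reference* stain matrix, so the
  output inherits the reference's stain chemistry exactly.
* **KH** maps each stain-concentration channel through a monotone quantile
  function (257 probability points, linear interpolation) onto the reference
  channel's distribution. This preserves the defining property of
  stain-specific color transfer — stain-channel statistics mapped to the
  reference — with a simple, reproducible estimator in place of the original
  spline regression over learned color descriptors; it is therefore labelled
  "KH-style".
* Externally normalized images (e.g. adversarially trained translators) are
  supported as a pass-through: they enter the pipeline as ordinary RGB
  directories downstream of normalization. No adversarial training is
  performed here.
* All normalizers clamp to `[0, 255]` and round half-up, fixed for
  reproducibility.

## Quality metrics

NMI and NMH are per-image ratios `median/P95` of, respectively, the
per-pixel RGB mean and the chromatic HSV hue. Medians and percentiles use
linear interpolation between order statistics. Hue is treated as linear
degrees, not circularly — with H&E the hues of interest live between blue
(240°) and pink (~300–330°), far from the wrap point; the circular caveat
matters only for near-red hues. A zero 95th percentile (all-black image for
NMI, all hues exactly 0° for NMH) makes the ratio undefined and raises an
error; population reports record such images as missing and exclude them
from the CV with a logged count.

AMCE pools window means (64×64 non-overlapping windows by default, partial
edge windows discarded) per image set into one ordered list per set,
truncates both lists to the shorter length, and takes the absolute
difference of the list means — per opponent channel. With sets of unequal
sizes this pooling is the only unambiguous reading; per-image AMCE columns
in a population report score each image against the full target set so that
a CV over images is defined. CD excludes windows with zero mean from both
sums symmetrically and uses population (ddof 0) window standard deviations.
CVs use the sample (n−1) standard deviation, appropriate for the small
populations these reports summarize; the CV of CD can be unstable when mean
CD is near zero, and is reported as-is.

## Segmentation utilities

Ternary probability maps are HxWx3 arrays in `[0,1]`; softmax maps sum to
one, sigmoid-style maps need not. Class extraction is per-pixel argmax with
ties broken toward the lower class index (background before boundary before
nuclei — the conservative call). The ensemble is the arithmetic mean,
computed as `first + mean(deviations from first)` so that averaging
identical maps is exactly idempotent in floating point; it agrees with the
naive mean to ~1e-16 and is order-invariant to the same precision.

Binarization acts on the nuclei channel: Otsu's 256-bin threshold (strictly
greater-than) or a fixed threshold (≥, default 0.5). Otsu on a constant
channel is undefined and falls back to the fixed 0.5 with a warning.

Post-processing applies, in order: 3×3 binary median filter, morphological
closing with a disk of radius 2, hole filling (4-connected background), and
removal of 8-connected components strictly smaller than 30 px (defaults
sized for nuclei at roughly 40× magnification; both configurable). A single
pass of this chain is not a projection — the median filter shaves convex
corner pixels that the closing restores — so the pass is iterated until the
mask is stable (typically one or two extra passes, bounded at 50), which
makes the operation idempotent and leaves no enclosed holes and no
undersized components.

Overlap evaluation is pixel-level: DSC, Jaccard, extra fraction, precision,
recall from exact confusion tallies. An empty ground-truth mask makes every
ratio undefined and raises; an empty *prediction* is reported with
precision 0 and an explicit flag so population aggregation stays total.
Aggregation uses sample standard deviations and logs excluded missing
values.

## Patch preparation

Two protocols: strided center-label crops (default 51×51, stride 7; the
label is the ternary class of the center pixel) and non-overlapping one-hot
tiles (default 256×256). Trailing partial strips are discarded rather than
padded or mirrored — the simplest deterministic convention; published patch
counts from real datasets depend on unstated border handling and are not
treated as contractual. Coordinates are 0-based (row, col), origins
top-left, row-major order. Rotation augmentation yields the original plus
three clockwise right-angle rotations (`(r,c) → (c, H−1−r)`), rotating
labels identically. Recombination pastes tiles by origin, rejects overlaps,
and fills uncovered trailing strips with background probability one,
returning a coverage mask.

## Synthetic data generator

The generator is the test substrate: every downstream check is closed-loop
against known ground truth. A scene places non-overlapping random ellipses
(rejection sampling with a separation margin so each nucleus keeps its own
boundary ring; a placement shortfall raises an error carrying the achieved
count), surrounds each with a 2-px boundary ring, and adds unstained
lumen/whitespace ellipses. Concentrations: hematoxylin 0.5 OD inside nuclei
(with a 20% darker rim, as chromatin accumulates at the envelope) against a
0.12 OD stromal leak; eosin 0.40 OD in stroma against 0.04 in nuclei; each
stain modulated by an independent smooth multiplicative texture (sd 0.45,
correlation length ~6 px). These levels were chosen from the estimation
geometry: the angular extremes of the OD cloud sit within ~2° of the true
stain vectors (cross-stain contamination at the 1%-percentile pixels is a
few percent), while the stromal hue mode is wide enough that hue statistics
respond to staining differences. Rendering is Beer–Lambert with additive
Gaussian OD noise (sd 0.02, a mild level that leaves per-pixel angular
noise around 3°). Defaults: 192×192 px, 24 nuclei of radius 9–14
(≈25% nuclear fraction — dense, tumor-like cellularity), brightfield 255.

The multicenter simulator is a designed experiment over laboratory
protocols rather than an iid sample: centers sit at evenly spaced levels of
a severity axis controlling global absorbance (±30%; section thickness and
overall stain uptake) and, anti-aligned so the effects compound rather than
cancel, hematoxylin-vs-eosin imbalance (±20%). Each center additionally
gets a stain matrix perturbed by per-channel scanner gains — the dominant
cross-scanner effect, and channel-monotone on intensities, so it lies in
the correctable space of all four normalizers — with a fixed gain direction
per center and the gain magnitude calibrated by bisection so the largest
stain-vector rotation stays within the requested jitter bound (15° by
default). Scenes within a center vary in cellularity (nucleus count drawn
between 75% and 100% of the base), as ROI crops of real tissue do. The seed
drives all content, textures and noise through per-operation random streams
derived from `(seed, operation code)`, so regenerating one stage never
perturbs another and scenes are bit-identical across runs and platforms.

The simulated predictor flips each pixel's true class with probability
`flip_prob` and emits probability mass `sharpness` on the (possibly
flipped) class, the remainder spread over per-pixel random noise — softmax
(sum-to-one) or sigmoid (independent channels) style. It is a stand-in for
a trained network whose errors are independent across ensemble members,
which is the regime in which probability averaging provably helps; real
CNN errors are spatially and mutually correlated, so ensemble gains
measured here are an upper bound on what correlated real models would give.

### What passing tests do and do not show

The generator emulates the *color* structure of multicenter H&E —
absorption physics, stain chemistry spread, scanner gains, whitespace,
cellularity variation — but not tissue morphology (no touching/overlapping
nuclei, no organ-specific texture), no chromatic aberration or focus
artifacts, and predictor errors are iid. Passing the population contract
shows each normalizer removes the between-center color variation this
generator produces; it does not certify performance on any specific real
dataset or scanner.

## Numerical conventions

Percentiles/medians: linear interpolation. Rounding to 8-bit: half-up. CV:
sample std / mean. Window statistics in CD: ddof 0. Probabilities clipped to
`[0,1]` after ensembling. Stain columns unit-norm to 1e-9. Report floats are
written with 6 significant digits, and each CSV has a JSON mirror. Problem
sizes used by the acceptance script — 100 round-trip images, 100 recovery
renders, a 3×10 multicenter set, 20 ensemble scenes, 100 post-processing
masks, a 160-px pipeline run — were chosen as the smallest sizes at which
the measured quantities are stable, and complete in under a minute on one
CPU.
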