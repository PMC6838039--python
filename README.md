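# henorm

Color normalization and nuclei-segmentation evaluation for H&E
histopathology.

Whole-slide images of hematoxylin-and-eosin (H&E) stained tissue vary
drastically in color between laboratories: stain lots, section thickness,
staining protocol and scanner optics all shift the appearance of the same
tissue. Anyone building or evaluating automated nuclei segmentation on
multicenter data faces two recurring questions — *how much does color
normalization actually standardize a dataset?* and *does it help the
segmentation downstream?* `henorm` provides the quantitative machinery to
answer both: the physics of stain color, four classical reference-based
normalizers, a color-constancy metric suite, ternary probability-map
ensembling with morphological clean-up, pixel-overlap scoring, patch
preparation for CNN training, and a seeded synthetic multicenter H&E
generator so that every component is testable against known ground truth.

## The model

Brightfield H&E images form by absorption (Beer–Lambert): with brightfield
intensity `I0`, the transmitted image is

```
I = I0 · exp(−V·S),        OD = −ln(I / I0) = V·S
```

where the columns of the 3×2 stain matrix `V` are the unit optical-density
colors of hematoxylin and eosin and `S` holds per-pixel stain
concentrations. Stain contributions add linearly in OD space, so `V` can be
estimated per image (SVD of the foreground OD cloud + angular-percentile
extremes, after Macenko) and `S` recovered by least squares (`V⁺·OD`).

Normalizers (one `fit_reference` / `normalize` contract):

* **HS** — histogram specification: per-channel monotone CDF matching;
* **RH** — Reinhard color transfer: mean/std matching in Ruderman lαβ;
* **MC** — Macenko spectral matching: deconvolve with the query's own
  estimated `V`, rescale each stain's robust (99th-percentile) maximum
  concentration to the reference's, recompose with the reference `V`;
* **KH** — Khan-style stain-specific mapping: monotone quantile mapping of
  each stain-concentration channel onto the reference distribution, then
  recomposition with the reference `V`.

Population quality is judged by the coefficient of variation (CV = sample
std / mean) of per-image metrics:

* **NMI** `= median(A)/P95(A)` with `A` the per-pixel RGB mean — intensity
  constancy;
* **NMH** `= median(H)/P95(H)` over chromatic HSV hue — color constancy;
* **AMCE** — |difference of window-mean opponent channels (α red–green,
  β yellow–blue)| between a target and a processed set — likeness to the
  reference;
* **CD** — window-mean grayscale σ/μ of normalized minus un-normalized —
  contrast change.

Segmentation utilities cover the ternary (background / nucleus boundary /
nucleus) scheme: probability-map ensembling `E = (1/N)ΣPₙ`, Otsu or fixed
binarization of the nuclei channel, a median→closing→hole-fill→small-object
post-processing chain, and pixel-overlap scores
`DSC = 2TP/(2TP+FP+FN)`, `JAC = |L∩P|/|L∪P|`, `EF = FP/(TP+FN)`,
precision and recall.

## Worked example

`examples/color_normalization.py` simulates three imaging centers
(10 ROIs each, stain matrices perturbed up to 15°, differing absorbance and
H/E balance), normalizes them to one reference and prints:

```
un-normalized: CV(NMI) = 0.0412, CV(NMH) = 0.0178
HS: CV(NMI) = 0.0095, CV(NMH) = 0.0071, AMCE(alpha) = 0.0003, CD = +0.0089
RH: CV(NMI) = 0.0191, CV(NMH) = 0.0123, AMCE(alpha) = 0.0002, CD = +0.0100
MC: CV(NMI) = 0.0177, CV(NMH) = 0.0019, AMCE(alpha) = 0.0017, CD = +0.0049
KH: CV(NMI) = 0.0166, CV(NMH) = 0.0009, AMCE(alpha) = 0.0000, CD = +0.0086
```

Every method shrinks the population CV of both NMI and NMH relative to the
un-normalized set — the deconvolution-based methods (MC, KH) standardize hue
hardest — and all show a small contrast gain (positive CD). The other
examples demonstrate stain-vector recovery (angular errors ~0.4–2.1° against
the known ground-truth matrix), ensemble segmentation (six simulated
predictors at 15% label-flip noise: single-model DSC ≈ 0.976, ensemble
DSC ≈ 0.998), and patch preparation (a 300×300 ROI yields 1,296 center-label
patches at size 51 / stride 7, matching the closed-form count).

A thin CLI mirrors the workflow (`henorm synth / normalize / qc / ensemble /
postprocess / evaluate / pipeline`); every subcommand writes a JSON config
echo beside its outputs so runs are exactly reproducible.

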