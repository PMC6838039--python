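"""Color-normalization quality metrics: NMI, NMH, AMCE, CD, and their
population coefficient of variation.

Each per-image metric is a scalar; the quality of a normalization method is
judged at population level through the coefficient of variation
``CV = std / mean`` (sample standard deviation) of the metric across the
image set — a consistent population has a low CV.

* **NMI** (normalized median intensity): median of the per-pixel channel
  mean, divided by its 95th percentile. Intensity constancy.
* **NMH** (normalized median hue): the same statistic on the HSV hue channel
  over chromatic pixels. Color constancy; hue is treated as linear degrees
  in [0, 360), not circularly.
* **AMCE** (absolute mean color error): absolute difference between the
  window-mean alpha (resp. beta) opponent-channel averages of a target set
  and a processed set. Likeness to the reference.
* **CD** (contrast difference): window-averaged grayscale sigma/mu of the
  normalized image minus that of the un-normalized image. Positive means
  contrast gain.

Medians/percentiles use linear interpolation between order statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .color import rgb_to_hue, rgb_to_lab
from .errors import InvalidInputError, UndefinedMetricError

__all__ = [
    "nmi",
    "nmh",
    "amce",
    "cd",
    "population_report",
    "PopulationReport",
    "DEFAULT_WINDOW",
]

logger = logging.getLogger(__name__)

DEFAULT_WINDOW = 64

_METRIC_COLUMNS = ("nmi", "nmh", "cd", "amce_alpha", "amce_beta")


def _intensity(img) -> np.ndarray:
    """A(i): per-pixel mean of the R, G, B channels."""
    arr = np.asarray(img, dtype=float)
    if arr.ndim != 3 or arr.shape[-1] != 3:
        raise InvalidInputError("expected an HxWx3 RGB image")
    return arr.mean(axis=-1)


def nmi(img) -> float:
    """Normalized median intensity: median(A) / P95(A)."""
    a = _intensity(img).ravel()
    p95 = np.percentile(a, 95)
    if p95 <= 0:
        raise UndefinedMetricError("NMI undefined: 95th intensity percentile is 0")
    return float(np.median(a) / p95)


def nmh(img) -> float:
    """Normalized median hue over chromatic pixels: median(H) / P95(H)."""
    hues = rgb_to_hue(img).chromatic_hues()
    if hues.size == 0:
        raise UndefinedMetricError("NMH undefined: image is fully achromatic")
    p95 = np.percentile(hues, 95)
    if p95 <= 0:
        raise UndefinedMetricError("NMH undefined: 95th hue percentile is 0")
    return float(np.median(hues) / p95)


def _window_means(channel: np.ndarray, w: int) -> np.ndarray:
    """Means of non-overlapping w x w windows, row-major; partial edge
    windows discarded."""
    if w < 1:
        raise InvalidInputError("window_size must be >= 1")
    H, W = channel.shape
    nh, nw = H // w, W // w
    if nh == 0 or nw == 0:
        return np.empty(0)
    trimmed = channel[: nh * w, : nw * w]
    return trimmed.reshape(nh, w, nw, w).mean(axis=(1, 3)).ravel()


def _pooled_window_means(images, w: int, channel_idx: int) -> np.ndarray:
    means = []
    for img in images:
        lab = rgb_to_lab(img)
        means.append(_window_means(lab[..., channel_idx], w))
    if not means:
        return np.empty(0)
    return np.concatenate(means)


def amce(target_set, processed_set, window_size: int = DEFAULT_WINDOW):
    """Absolute mean color error in the alpha and beta opponent channels.

    Window means are pooled per set (row-major within each image, images in
    list order) and the two pooled lists are truncated to the shorter length
    W before the means are differenced.
    """
    target_set = list(target_set)
    processed_set = list(processed_set)
    if not target_set or not processed_set:
        raise InvalidInputError("AMCE needs non-empty target and processed sets")
    out = []
    for idx in (1, 2):  # alpha, beta
        tar = _pooled_window_means(target_set, window_size, idx)
        proc = _pooled_window_means(processed_set, window_size, idx)
        W = min(tar.size, proc.size)
        if W == 0:
            raise InvalidInputError(
                f"window_size {window_size} leaves no full windows"
            )
        out.append(float(abs(tar[:W].mean() - proc[:W].mean())))
    return tuple(out)


def cd(normalized, unnormalized, window_size: int = DEFAULT_WINDOW) -> float:
    """Contrast difference: window-mean sigma/mu (grayscale) of the
    normalized image minus the un-normalized image.

    Windows whose mean is zero in either image are excluded from both sums.
    """
    a_n = _intensity(normalized)
    a_u = _intensity(unnormalized)
    if a_n.shape != a_u.shape:
        raise InvalidInputError("CD requires images of identical dimensions")
    w = window_size
    if w < 1:
        raise InvalidInputError("window_size must be >= 1")
    H, W = a_n.shape
    nh, nw = H // w, W // w
    if nh == 0 or nw == 0:
        raise InvalidInputError(f"window_size {w} leaves no full windows")

    def _stats(a):
        t = a[: nh * w, : nw * w].reshape(nh, w, nw, w)
        return t.mean(axis=(1, 3)).ravel(), t.std(axis=(1, 3)).ravel()

    mu_n, sd_n = _stats(a_n)
    mu_u, sd_u = _stats(a_u)
    keep = (mu_n > 0) & (mu_u > 0)
    if not np.any(keep):
        raise UndefinedMetricError("CD undefined: every window has zero mean")
    return float((sd_n[keep] / mu_n[keep]).mean() - (sd_u[keep] / mu_u[keep]).mean())


def _cv(values: np.ndarray) -> float:
    mean = values.mean()
    std = values.std(ddof=1) if values.size > 1 else 0.0
    return float(std / mean) if mean != 0 else float("nan")


@dataclass
class PopulationReport:
    """Per-image metric table plus mean/std/CV per metric.

    ``per_image`` is indexed by image_id with columns nmi, nmh, cd,
    amce_alpha, amce_beta (NaN where undefined or not requested);
    ``summary`` has rows mean/std/cv; ``missing`` counts undefined values
    per metric.
    """

    per_image: pd.DataFrame
    summary: pd.DataFrame
    missing: dict

    def cv(self, metric: str) -> float:
        return float(self.summary.loc["cv", metric])


def population_report(
    images,
    image_ids=None,
    unnormalized=None,
    target_set=None,
    window_size: int = DEFAULT_WINDOW,
) -> PopulationReport:
    """Compute per-image NMI/NMH (and CD / AMCE where inputs are given) and
    the population mean, sample standard deviation and CV of each metric.

    CD needs ``unnormalized`` paired by position with ``images``; the
    per-image AMCE columns score each image against the pooled ``target_set``.
    Undefined metrics are recorded as missing and excluded from the CV, with
    a logged count.
    """
    images = list(images)
    if not images:
        raise InvalidInputError("population_report needs at least one image")
    if image_ids is None:
        image_ids = [f"img_{i:04d}" for i in range(len(images))]
    image_ids = list(image_ids)
    if len(image_ids) != len(images):
        raise InvalidInputError("image_ids must align with images")
    if unnormalized is not None:
        unnormalized = list(unnormalized)
        if len(unnormalized) != len(images):
            raise InvalidInputError("unnormalized set must pair with images")

    order = np.argsort(image_ids, kind="stable")
    rows = {}
    missing = {m: 0 for m in _METRIC_COLUMNS}
    for k in order:
        img, iid = images[k], image_ids[k]
        rec = {}
        for name, fn in (("nmi", nmi), ("nmh", nmh)):
            try:
                rec[name] = fn(img)
            except UndefinedMetricError:
                rec[name] = np.nan
                missing[name] += 1
        if unnormalized is not None:
            try:
                rec["cd"] = cd(img, unnormalized[k], window_size)
            except UndefinedMetricError:
                rec["cd"] = np.nan
                missing["cd"] += 1
        else:
            rec["cd"] = np.nan
        if target_set is not None:
            a, b = amce(target_set, [img], window_size)
            rec["amce_alpha"], rec["amce_beta"] = a, b
        else:
            rec["amce_alpha"] = rec["amce_beta"] = np.nan
        rows[iid] = rec

    per_image = pd.DataFrame.from_dict(rows, orient="index")[list(_METRIC_COLUMNS)]
    per_image.index.name = "image_id"
    for m, n in missing.items():
        if n:
            logger.warning("%d image(s) with undefined %s excluded from CV", n, m)

    summary = pd.DataFrame(index=["mean", "std", "cv"], columns=list(_METRIC_COLUMNS),
                           dtype=float)
    for m in _METRIC_COLUMNS:
        vals = per_image[m].dropna().to_numpy(dtype=float)
        if vals.size == 0:
            continue
        summary.loc["mean", m] = vals.mean()
        summary.loc["std", m] = vals.std(ddof=1) if vals.size > 1 else 0.0
        summary.loc["cv", m] = _cv(vals)
    return PopulationReport(per_image=per_image, summary=summary, missing=missing)
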