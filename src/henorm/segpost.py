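"""Ternary probability-map handling: ensembling, binarization,
morphological post-processing.

Probability maps are HxWx3 float arrays in [0, 1] with channels ordered
(background, boundary, nuclei). Channels need not sum to one: sigmoid-style
per-channel outputs are as valid as softmax outputs. Ensembling is the plain
arithmetic mean of the per-model maps, so agreement between models sharpens
the output and disagreement attenuates it.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.morphology import closing, disk, remove_small_objects

from .errors import InvalidInputError, InvalidParameterError

__all__ = [
    "BACKGROUND",
    "BOUNDARY",
    "NUCLEI",
    "argmax_classes",
    "ensemble",
    "binarize",
    "postprocess",
    "count_enclosed_holes",
]

BACKGROUND, BOUNDARY, NUCLEI = 0, 1, 2


def _check_probs(p) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.ndim != 3 or p.shape[-1] != 3:
        raise InvalidInputError("probability map must be HxWx3")
    if p.min() < 0 or p.max() > 1:
        raise InvalidInputError("probabilities must lie in [0, 1]")
    return p


def argmax_classes(probs) -> np.ndarray:
    """Hard ternary labels: per-pixel index of the maximal channel.

    Ties break toward the lower class index (background < boundary < nuclei),
    i.e. conservatively away from calling a nucleus.
    """
    return np.argmax(_check_probs(probs), axis=-1).astype(np.uint8)


def ensemble(maps) -> np.ndarray:
    """Average a list of equally-shaped probability maps channel-wise.

    The mean of per-model class probabilities is itself a probability map;
    it is idempotent on identical inputs and order-invariant.
    """
    maps = [np.asarray(m, dtype=float) for m in maps]
    if not maps:
        raise InvalidInputError("ensemble needs at least one probability map")
    shape = maps[0].shape
    if any(m.shape != shape for m in maps):
        raise InvalidInputError("all probability maps must share one shape")
    # mean as first + mean deviation: exactly idempotent on identical maps
    dev = np.zeros(shape, dtype=float)
    for m in maps[1:]:
        dev += m - maps[0]
    mean = maps[0] + dev / len(maps)
    return _check_probs(np.clip(mean, 0.0, 1.0))


def binarize(probs, method: str = "otsu", threshold: float = 0.5) -> np.ndarray:
    """Threshold the nuclei channel of a ternary probability map.

    ``otsu`` picks the 256-bin between-class-variance-maximizing threshold
    (pixels strictly above it are foreground); on a constant channel it falls
    back to the fixed threshold 0.5 with a warning. ``fixed`` keeps pixels
    ``>= threshold``.
    """
    channel = _check_probs(probs)[..., NUCLEI]
    if method == "fixed":
        if not (0.0 < threshold < 1.0):
            raise InvalidParameterError("fixed threshold must lie in (0, 1)")
        return channel >= threshold
    if method != "otsu":
        raise InvalidParameterError("binarize method must be 'otsu' or 'fixed'")
    if np.ptp(channel) == 0:
        warnings.warn(
            "Otsu undefined on a constant nuclei channel; falling back to "
            "fixed threshold 0.5",
            stacklevel=2,
        )
        return channel >= 0.5
    return channel > threshold_otsu(channel, nbins=256)


def postprocess(mask, min_object_px: int = 30, se_radius: int = 2,
                max_passes: int = 50) -> np.ndarray:
    """Clean a binary nuclei mask: 3x3 median filter, morphological closing
    (disk of ``se_radius``), hole filling, then removal of connected
    components smaller than ``min_object_px`` pixels (8-connectivity).

    A single filter-close-fill-remove pass can disagree with itself at
    convex corners (the median filter shaves pixels that closing restores),
    so the pass is repeated until the mask is stable — usually one or two
    extra passes — making the operation idempotent. The result has no
    enclosed holes and no undersized component.
    """
    out = np.asarray(mask).astype(bool)
    if out.ndim != 2:
        raise InvalidInputError("mask must be HxW")
    for _ in range(max_passes):
        new = ndimage.median_filter(out.astype(np.uint8), size=3).astype(bool)
        new = closing(new, disk(se_radius))
        new = ndimage.binary_fill_holes(new)
        # components strictly smaller than min_object_px are dropped
        new = remove_small_objects(new, max_size=min_object_px - 1, connectivity=2)
        if np.array_equal(new, out):
            return new
        out = new
    return out


def count_enclosed_holes(mask) -> int:
    """Number of background components (4-connectivity) not touching the
    image border — zero after :func:`postprocess`."""
    mask = np.asarray(mask).astype(bool)
    bg_labels, n = ndimage.label(~mask)  # default structure = 4-connectivity
    if n == 0:
        return 0
    border = np.unique(
        np.concatenate(
            [bg_labels[0, :], bg_labels[-1, :], bg_labels[:, 0], bg_labels[:, -1]]
        )
    )
    border = set(border.tolist()) - {0}
    return int(n - len(border))
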