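"""Dataset preparation: patch extraction, rotation augmentation,
recombination.

Two patching protocols are provided, matching the two CNN training styles
they feed:

* center-label patches — dense ``size x size`` crops on a regular stride,
  each labeled by the ternary class of its center pixel (patch-classification
  training);
* dense patches — non-overlapping ``size x size`` tiles with per-pixel
  one-hot ternary labels (fully-convolutional training). Trailing partial
  strips are discarded.

Coordinates are 0-based (row, col) with the origin at the patch's top-left.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidInputError

__all__ = [
    "CenterLabelPatch",
    "DensePatch",
    "extract_center_patches",
    "extract_dense_patches",
    "augment_rotations",
    "recombine",
    "center_patch_count",
    "dense_patch_count",
]


@dataclass(frozen=True)
class CenterLabelPatch:
    pixels: np.ndarray  # size x size x 3 uint8
    center_label: int  # ternary class of the center pixel
    origin: tuple  # (row, col) of the top-left corner in the source


@dataclass(frozen=True)
class DensePatch:
    pixels: np.ndarray  # size x size x 3 uint8
    labels: np.ndarray  # size x size x 3 one-hot
    origin: tuple


def _check_pair(img, labels):
    img = np.asarray(img)
    labels = np.asarray(labels)
    if img.ndim != 3 or img.shape[-1] != 3:
        raise InvalidInputError("image must be HxWx3")
    if labels.shape != img.shape[:2]:
        raise InvalidInputError("label map must align with the image")
    return img, labels


def center_patch_count(height: int, width: int, size: int = 51, stride: int = 7) -> int:
    """Closed-form number of full-fit strided patches."""
    if height < size or width < size:
        return 0
    return ((height - size) // stride + 1) * ((width - size) // stride + 1)


def dense_patch_count(height: int, width: int, size: int = 256) -> int:
    """Closed-form number of non-overlapping tiles (partials discarded)."""
    return (height // size) * (width // size)


def extract_center_patches(img, labels, size: int = 51, stride: int = 7):
    """Strided crops labeled by their center pixel's ternary class.

    Origins run over ``(r*stride, c*stride)`` for every full-fit position, in
    deterministic row-major order.
    """
    img, labels = _check_pair(img, labels)
    H, W = labels.shape
    if H < size or W < size:
        raise InvalidInputError(f"image {H}x{W} smaller than patch size {size}")
    half = size // 2
    out = []
    for r in range(0, H - size + 1, stride):
        for c in range(0, W - size + 1, stride):
            out.append(
                CenterLabelPatch(
                    pixels=img[r : r + size, c : c + size],
                    center_label=int(labels[r + half, c + half]),
                    origin=(r, c),
                )
            )
    return out


def one_hot(labels, n_classes: int = 3) -> np.ndarray:
    """One-hot encode a ternary label map to HxWx3."""
    labels = np.asarray(labels)
    return np.eye(n_classes, dtype=np.uint8)[labels]


def extract_dense_patches(img, labels, size: int = 256):
    """Non-overlapping tiles with per-pixel one-hot labels, row-major;
    trailing partial strips are discarded."""
    img, labels = _check_pair(img, labels)
    H, W = labels.shape
    if H < size or W < size:
        raise InvalidInputError(f"image {H}x{W} smaller than patch size {size}")
    encoded = one_hot(labels)
    out = []
    for r in range(0, (H // size) * size, size):
        for c in range(0, (W // size) * size, size):
            out.append(
                DensePatch(
                    pixels=img[r : r + size, c : c + size],
                    labels=encoded[r : r + size, c : c + size],
                    origin=(r, c),
                )
            )
    return out


def _rot_cw(arr: np.ndarray, k: int) -> np.ndarray:
    """Clockwise right-angle rotation: (r, c) -> (c, H-1-r) for k = 1."""
    return np.rot90(arr, k=-k)


def augment_rotations(patch):
    """The patch plus its 90/180/270-degree rotations (labels rotated
    identically; the center label of a center-label patch is unchanged)."""
    if isinstance(patch, CenterLabelPatch):
        h, w = patch.pixels.shape[:2]
        if h != w:
            raise InvalidInputError("rotation augmentation needs square patches")
        return [
            CenterLabelPatch(
                pixels=_rot_cw(patch.pixels, k),
                center_label=patch.center_label,
                origin=patch.origin,
            )
            for k in range(4)
        ]
    if isinstance(patch, DensePatch):
        h, w = patch.pixels.shape[:2]
        if h != w:
            raise InvalidInputError("rotation augmentation needs square patches")
        return [
            DensePatch(
                pixels=_rot_cw(patch.pixels, k),
                labels=_rot_cw(patch.labels, k),
                origin=patch.origin,
            )
            for k in range(4)
        ]
    raise InvalidInputError("augment_rotations expects a patch dataclass")


def recombine(patches, canvas_shape):
    """Paste per-patch ternary maps back onto a canvas by origin.

    Accepts :class:`DensePatch` items (their one-hot labels are pasted) or
    ``(origin, HxWx3 array)`` pairs, e.g. per-patch probability maps.
    Overlapping tiles are an error; uncovered trailing strips are filled with
    background probability 1 and reported through the returned coverage mask.

    Returns ``(probs, covered)``.
    """
    H, W = canvas_shape
    probs = np.zeros((H, W, 3), dtype=float)
    probs[..., 0] = 1.0
    covered = np.zeros((H, W), dtype=bool)
    for item in patches:
        if isinstance(item, DensePatch):
            origin, tile = item.origin, np.asarray(item.labels, dtype=float)
        else:
            origin, tile = item
            tile = np.asarray(tile, dtype=float)
        r, c = origin
        h, w = tile.shape[:2]
        if r < 0 or c < 0 or r + h > H or c + w > W:
            raise InvalidInputError(f"patch at {origin} exceeds the canvas")
        if covered[r : r + h, c : c + w].any():
            raise InvalidInputError(f"patch at {origin} overlaps a previous tile")
        probs[r : r + h, c : c + w] = tile
        covered[r : r + h, c : c + w] = True
    return probs, covered
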