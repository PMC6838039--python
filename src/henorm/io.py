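"""Image and report I/O.

Images are 8-bit RGB PNG/TIFF; ternary probability maps travel as 32-bit
3-channel TIFF; binary masks as 8-bit PNG with {0, 255}; label maps as 8-bit
PNG with class indices {0, 1, 2}. Reports are CSV plus a JSON mirror, floats
written with 6 significant digits.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile
from PIL import Image

from .errors import InvalidInputError

__all__ = [
    "read_rgb",
    "write_rgb",
    "read_prob_map",
    "write_prob_map",
    "read_mask",
    "write_mask",
    "read_label_map",
    "write_label_map",
    "list_images",
    "write_report",
    "fmt",
]

_IMAGE_SUFFIXES = (".png", ".tif", ".tiff")


def read_rgb(path) -> np.ndarray:
    """Read an image as HxWx3 uint8, dropping any alpha channel."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = np.asarray(Image.open(path).convert("RGB"))
    arr = np.asarray(arr)
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.shape[-1] == 4:
        arr = arr[..., :3]
    if arr.ndim != 3 or arr.shape[-1] != 3:
        raise InvalidInputError(f"{path} is not an RGB image")
    return arr.astype(np.uint8)


def write_rgb(path, img) -> None:
    img = np.asarray(img, dtype=np.uint8)
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, img)
    else:
        Image.fromarray(img, mode="RGB").save(path)


def read_prob_map(path) -> np.ndarray:
    arr = tifffile.imread(Path(path)).astype(float)
    if arr.ndim == 3 and arr.shape[0] == 3 and arr.shape[-1] != 3:
        arr = np.moveaxis(arr, 0, -1)
    if arr.ndim != 3 or arr.shape[-1] != 3:
        raise InvalidInputError(f"{path} is not a 3-channel probability map")
    return arr


def write_prob_map(path, probs) -> None:
    tifffile.imwrite(Path(path), np.asarray(probs, dtype=np.float32),
                     photometric="rgb")


def read_mask(path) -> np.ndarray:
    return np.asarray(Image.open(path).convert("L")) > 127


def write_mask(path, mask) -> None:
    arr = (np.asarray(mask).astype(np.uint8) * 255)
    Image.fromarray(arr, mode="L").save(Path(path))


def read_label_map(path) -> np.ndarray:
    arr = np.asarray(Image.open(path).convert("L"))
    if arr.max() > 2:
        raise InvalidInputError(f"{path} holds values outside the ternary classes")
    return arr.astype(np.uint8)


def write_label_map(path, labels) -> None:
    Image.fromarray(np.asarray(labels, dtype=np.uint8), mode="L").save(Path(path))


def list_images(directory) -> list:
    """Deterministic (sorted) list of image paths in a directory."""
    directory = Path(directory)
    if not directory.is_dir():
        raise InvalidInputError(f"{directory} is not a directory")
    return sorted(
        p for p in directory.iterdir() if p.suffix.lower() in _IMAGE_SUFFIXES
    )


def fmt(x) -> str:
    """Fixed 6-significant-digit float formatting for reports."""
    if x is None or (isinstance(x, float) and np.isnan(x)):
        return "NA"
    return format(float(x), ".6g")


def write_report(path_stem, frame) -> None:
    """Write a DataFrame as <stem>.csv plus a JSON mirror <stem>.json with
    6-significant-digit floats."""
    path_stem = Path(path_stem)
    out = frame.copy()
    for col in out.columns:
        if out[col].dtype.kind == "f":
            out[col] = out[col].map(fmt)
    out.to_csv(path_stem.with_suffix(".csv"))
    payload = json.loads(out.to_json(orient="index"))
    with open(path_stem.with_suffix(".json"), "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
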