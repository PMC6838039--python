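"""Reference-based color normalization: HS, RH, MC, KH-style.

All four classical methods share one contract: :func:`fit_reference` distills
a reference image into a :class:`ReferenceModel`, and :func:`normalize` maps
any query image onto the reference's color distribution. The methods are

* **HS** — histogram specification: each RGB channel's empirical CDF is
  matched to the reference channel's CDF by a monotone 256-entry lookup.
* **RH** — Reinhard color transfer: per-channel mean/std matching in
  Ruderman l-alpha-beta space.
* **MC** — Macenko spectral matching: deconvolve the query with its own
  estimated stain matrix, rescale each stain so its robust maximum
  concentration equals the reference's, recompose with the *reference*
  stain matrix.
* **KH** — stain-specific color transfer in the spirit of Khan: deconvolve
  the query, map each stain-concentration channel onto the reference
  channel's distribution by a monotone quantile mapping, recompose with
  the reference stain matrix.

Externally normalized images (e.g. GAN output) enter the pipeline as a
pass-through: they are plain RGB directories downstream of this module.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from . import stain
from .color import lab_to_rgb, rgb_to_lab
from .errors import (
    DegenerateReferenceError,
    InvalidParameterError,
)

__all__ = ["ReferenceModel", "fit_reference", "normalize", "METHODS"]

METHODS = ("hs", "rh", "mc", "kh")

_QUANTILE_GRID = np.linspace(0.0, 100.0, 257)  # probability grid for KH maps


@dataclass
class ReferenceModel:
    """Statistics of a reference image for one normalization method."""

    method: str
    params: dict = field(default_factory=dict)
    background: float = stain.DEFAULT_BACKGROUND

    def to_json(self, path=None) -> str:
        payload = {
            "method": self.method,
            "background": self.background,
            "params": {
                k: (v.tolist() if isinstance(v, np.ndarray) else v)
                for k, v in self.params.items()
            },
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "ReferenceModel":
        try:
            payload = json.loads(source)
        except (json.JSONDecodeError, TypeError):
            with open(source) as fh:
                payload = json.load(fh)
        params = {k: np.asarray(v) if isinstance(v, list) else v
                  for k, v in payload["params"].items()}
        return cls(method=payload["method"], params=params,
                   background=payload.get("background", stain.DEFAULT_BACKGROUND))


def _as_uint8_rgb(img) -> np.ndarray:
    arr = np.asarray(img)
    if arr.ndim != 3 or arr.shape[-1] != 3:
        raise InvalidParameterError("expected an HxWx3 RGB image")
    return arr.astype(np.uint8, copy=False)


def _channel_histograms(img: np.ndarray) -> np.ndarray:
    return np.stack(
        [np.bincount(img[..., c].ravel(), minlength=256) for c in range(3)]
    )


def fit_reference(
    ref,
    method: str,
    background: float = stain.DEFAULT_BACKGROUND,
    od_threshold: float = 0.15,
    angular_percentile: float = 1.0,
    robust_max_percentile: float = 99.0,
) -> ReferenceModel:
    """Fit a deterministic reference model for one of HS/RH/MC/KH."""
    method = method.lower()
    if method not in METHODS:
        raise InvalidParameterError(f"unknown method {method!r}; use one of {METHODS}")
    ref = _as_uint8_rgb(ref)

    if method == "hs":
        params = {"histograms": _channel_histograms(ref)}
    elif method == "rh":
        lab = rgb_to_lab(ref).reshape(-1, 3)
        mean = lab.mean(axis=0)
        std = lab.std(axis=0, ddof=0)
        if np.any(std <= 1e-9):
            raise DegenerateReferenceError(
                "reference has zero variance in an l-alpha-beta channel"
            )
        params = {"mean": mean, "std": std}
    else:  # mc / kh need the reference stain decomposition
        od = stain.rgb_to_od(ref, background)
        V = stain.estimate_stain_matrix(od, od_threshold, angular_percentile)
        conc = stain.deconvolve(od, V)
        flat = conc.reshape(-1, 2)
        if method == "mc":
            params = {
                "stain_matrix": V,
                "robust_max": np.percentile(flat, robust_max_percentile, axis=0),
                "robust_max_percentile": robust_max_percentile,
            }
        else:
            params = {
                "stain_matrix": V,
                "quantile_grid": _QUANTILE_GRID,
                "quantiles": np.percentile(flat, _QUANTILE_GRID, axis=0),
            }
    model = ReferenceModel(method=method, params=params, background=background)
    model.params.setdefault("od_threshold", od_threshold)
    model.params.setdefault("angular_percentile", angular_percentile)
    return model


def _normalize_hs(query: np.ndarray, model: ReferenceModel) -> np.ndarray:
    ref_hist = np.asarray(model.params["histograms"], dtype=float)
    out = np.empty_like(query)
    for c in range(3):
        q_hist = np.bincount(query[..., c].ravel(), minlength=256).astype(float)
        q_cdf = np.cumsum(q_hist) / q_hist.sum()
        r_cdf = np.cumsum(ref_hist[c]) / ref_hist[c].sum()
        # smallest reference level whose CDF reaches the query CDF
        lut = np.searchsorted(r_cdf, q_cdf, side="left").clip(0, 255)
        out[..., c] = lut.astype(np.uint8)[query[..., c]]
    return out


def _normalize_rh(query: np.ndarray, model: ReferenceModel) -> np.ndarray:
    lab = rgb_to_lab(query)
    flat = lab.reshape(-1, 3)
    q_mean = flat.mean(axis=0)
    q_std = flat.std(axis=0, ddof=0)
    # zero-variance query channels get an offset-only map (no rescaling)
    usable = q_std > 1e-9
    scale = np.where(usable,
                     np.asarray(model.params["std"]) / np.where(usable, q_std, 1.0),
                     1.0)
    shifted = (lab - q_mean) * scale + np.asarray(model.params["mean"])
    return lab_to_rgb(shifted)


def _query_decomposition(query: np.ndarray, model: ReferenceModel):
    od = stain.rgb_to_od(query, model.background)
    V_q = stain.estimate_stain_matrix(
        od,
        od_threshold=model.params.get("od_threshold", 0.15),
        angular_percentile=model.params.get("angular_percentile", 1.0),
    )
    return stain.deconvolve(od, V_q)


def _normalize_mc(query: np.ndarray, model: ReferenceModel) -> np.ndarray:
    conc = _query_decomposition(query, model)
    flat = conc.reshape(-1, 2)
    pct = model.params.get("robust_max_percentile", 99.0)
    q_max = np.percentile(flat, pct, axis=0)
    ref_max = np.asarray(model.params["robust_max"], dtype=float)
    scale = np.where(q_max > 0, ref_max / np.where(q_max > 0, q_max, 1.0), 1.0)
    return stain.recompose(
        np.asarray(model.params["stain_matrix"], dtype=float),
        conc * scale,
        model.background,
    )


def _normalize_kh(query: np.ndarray, model: ReferenceModel) -> np.ndarray:
    conc = _query_decomposition(query, model)
    flat = conc.reshape(-1, 2)
    grid = np.asarray(model.params["quantile_grid"], dtype=float)
    ref_q = np.asarray(model.params["quantiles"], dtype=float)  # (grid, 2)
    mapped = np.empty_like(flat)
    for s in range(2):
        q_q = np.percentile(flat[:, s], grid)
        # monotone quantile map: query value -> quantile level -> reference value
        mapped[:, s] = np.interp(flat[:, s], q_q, ref_q[:, s])
    return stain.recompose(
        np.asarray(model.params["stain_matrix"], dtype=float),
        mapped.reshape(conc.shape),
        model.background,
    )


_DISPATCH = {
    "hs": _normalize_hs,
    "rh": _normalize_rh,
    "mc": _normalize_mc,
    "kh": _normalize_kh,
}


def normalize(query, model: ReferenceModel) -> np.ndarray:
    """Apply a fitted reference model to a query image.

    Deterministic in (query, model); output is a uint8 RGB image clamped to
    [0, 255].
    """
    if model.method not in _DISPATCH:
        raise InvalidParameterError(f"model has unknown method {model.method!r}")
    return _DISPATCH[model.method](_as_uint8_rgb(query), model)
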