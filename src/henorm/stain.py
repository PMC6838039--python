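"""Beer-Lambert stain model: optical density, stain matrices, deconvolution.

A brightfield H&E image forms by absorption: the transmitted intensity is
``I = I0 * exp(-V @ S)`` where the columns of the 3x2 stain matrix ``V`` are
the unit optical-density (OD) colors of hematoxylin and eosin and ``S`` holds
the per-pixel stain concentrations. Taking ``-log`` moves the image into OD
space, where stain contributions add linearly, so concentrations are
recovered by (least-squares) inversion of ``V``.

Stain vectors are estimated per image with the SVD/angular-extremes approach
of Macenko: foreground OD pixels are projected onto their dominant singular
plane and the vectors at the extreme percentiles of the projected angle
distribution are taken as the pure stains.
"""

from __future__ import annotations

import json

import numpy as np

from .errors import DegenerateStainError, InvalidParameterError

__all__ = [
    "DEFAULT_BACKGROUND",
    "rgb_to_od",
    "od_to_rgb",
    "estimate_stain_matrix",
    "deconvolve",
    "recompose",
    "validate_stain_matrix",
    "stain_matrix_to_json",
    "stain_matrix_from_json",
    "stain_angles_deg",
]

#: Default per-channel brightfield intensity (saturated 8-bit white).
DEFAULT_BACKGROUND = 255.0

# Published H&E OD unit vectors (hematoxylin, eosin) as matrix columns.
DEFAULT_HE_MATRIX = np.array(
    [[0.65, 0.07], [0.70, 0.99], [0.29, 0.11]], dtype=float
)
DEFAULT_HE_MATRIX /= np.linalg.norm(DEFAULT_HE_MATRIX, axis=0, keepdims=True)


def _check_background(background) -> np.ndarray:
    bg = np.broadcast_to(np.asarray(background, dtype=float), (3,)).copy()
    if np.any(bg < 1.0) or np.any(bg > 255.0):
        raise InvalidParameterError(
            f"background intensities must lie in [1, 255], got {bg}"
        )
    return bg


def rgb_to_od(img, background=DEFAULT_BACKGROUND) -> np.ndarray:
    """Convert an 8-bit RGB image to optical density.

    ``od[c] = ln(background[c] / clamp(pixel[c], 1, background[c]))``; zero
    intensities are clamped to 1 so the OD stays finite, and intensities above
    the brightfield clamp to it so the OD stays non-negative.
    """
    bg = _check_background(background)
    pix = np.asarray(img, dtype=float)
    if pix.ndim != 3 or pix.shape[-1] != 3:
        raise InvalidParameterError("expected an HxWx3 RGB image")
    clamped = np.clip(pix, 1.0, bg)
    return np.log(bg / clamped)


def od_to_rgb(od, background=DEFAULT_BACKGROUND) -> np.ndarray:
    """Invert :func:`rgb_to_od`: ``round(background * exp(-od))`` clamped to
    [0, 255], rounding half-up for reproducibility."""
    bg = _check_background(background)
    od = np.asarray(od, dtype=float)
    intens = bg * np.exp(-od)
    return np.clip(np.floor(intens + 0.5), 0, 255).astype(np.uint8)


def validate_stain_matrix(V) -> np.ndarray:
    """Check the StainMatrix invariants: 3x2, unit non-negative columns,
    linearly independent."""
    V = np.asarray(V, dtype=float)
    if V.shape != (3, 2):
        raise DegenerateStainError(f"stain matrix must be 3x2, got {V.shape}")
    norms = np.linalg.norm(V, axis=0)
    if np.any(np.abs(norms - 1.0) > 1e-9):
        raise DegenerateStainError(f"stain columns must be unit norm, got {norms}")
    if np.any(V < 0):
        raise DegenerateStainError("stain columns must be non-negative")
    if np.linalg.cond(V) > 1e8:
        raise DegenerateStainError("stain columns are (near-)collinear")
    return V


def _order_hematoxylin_first(V: np.ndarray) -> np.ndarray:
    # Hematoxylin is the bluer stain: larger blue OD component; ties broken
    # by larger green component.
    key = lambda col: (round(col[2], 12), round(col[1], 12))
    if key(V[:, 0]) >= key(V[:, 1]):
        return V
    return V[:, ::-1]


def estimate_stain_matrix(
    od,
    od_threshold: float = 0.15,
    angular_percentile: float = 1.0,
    min_foreground: int = 50,
) -> np.ndarray:
    """Estimate the 3x2 H&E stain matrix from an OD image (Macenko style).

    Pixels with OD magnitude below ``od_threshold`` (near-brightfield) are
    discarded; the remaining cloud is reduced by SVD to its dominant plane,
    and the stain vectors are read off at the ``angular_percentile`` /
    ``100 - angular_percentile`` extremes of the projected angle
    distribution. Columns are unit-norm, non-negative, hematoxylin first.
    """
    od = np.asarray(od, dtype=float).reshape(-1, 3)
    if not (0 < angular_percentile < 50):
        raise InvalidParameterError("angular_percentile must be in (0, 50)")
    fg = od[np.linalg.norm(od, axis=1) >= od_threshold]
    if fg.shape[0] < min_foreground:
        raise DegenerateStainError(
            f"only {fg.shape[0]} foreground pixels (need >= {min_foreground})"
        )
    _, s, vt = np.linalg.svd(fg, full_matrices=False)
    if s[0] <= 0 or s[1] <= 1e-6 * s[0]:
        raise DegenerateStainError("OD cloud is rank deficient (single stain?)")
    basis = vt[:2]  # 2x3, rows span the dominant plane
    # Orient the first axis toward the data so all angles live in (-pi/2, pi/2).
    if basis[0] @ fg.mean(axis=0) < 0:
        basis = basis * np.array([[-1.0], [1.0]])
    proj = fg @ basis.T
    ang = np.arctan2(proj[:, 1], proj[:, 0])
    lo = np.percentile(ang, angular_percentile)
    hi = np.percentile(ang, 100.0 - angular_percentile)
    if hi - lo < 1e-9:
        raise DegenerateStainError("angular spread vanishes (single stain?)")
    cols = []
    for a in (lo, hi):
        v = basis.T @ np.array([np.cos(a), np.sin(a)])
        if v.sum() < 0:
            v = -v
        v = np.clip(v, 0.0, None)
        n = np.linalg.norm(v)
        if n <= 0:
            raise DegenerateStainError("estimated stain vector collapsed to zero")
        cols.append(v / n)
    V = _order_hematoxylin_first(np.stack(cols, axis=1))
    return validate_stain_matrix(V)


def deconvolve(od, V) -> np.ndarray:
    """Least-squares stain concentrations ``S`` with ``od ~ V @ S`` per pixel.

    ``V`` is 3x2, so the inverse of the mixing model is realized as the
    Moore-Penrose pseudo-inverse; the result is the orthogonal projection
    coefficient pair and may contain small negatives.
    """
    V = validate_stain_matrix(V)
    od = np.asarray(od, dtype=float)
    shape = od.shape[:-1]
    conc = od.reshape(-1, 3) @ np.linalg.pinv(V).T
    return conc.reshape(shape + (2,))


def recompose(V, conc, background=DEFAULT_BACKGROUND) -> np.ndarray:
    """Render concentrations back to 8-bit RGB through the absorption model.

    Negative concentrations (least-squares residual artifacts) are clipped
    to zero before mixing.
    """
    V = validate_stain_matrix(V)
    conc = np.asarray(conc, dtype=float)
    od = np.clip(conc, 0.0, None) @ V.T
    return od_to_rgb(od, background)


def stain_angles_deg(V_est, V_true) -> np.ndarray:
    """Per-column angular error (degrees) between two stain matrices."""
    V_est = np.asarray(V_est, dtype=float)
    V_true = np.asarray(V_true, dtype=float)
    cos = np.abs(np.sum(V_est * V_true, axis=0)) / (
        np.linalg.norm(V_est, axis=0) * np.linalg.norm(V_true, axis=0)
    )
    return np.degrees(np.arccos(np.clip(cos, -1.0, 1.0)))


def stain_matrix_to_json(V, path=None) -> str:
    """Serialize a stain matrix (row-major, labeled) to JSON."""
    V = validate_stain_matrix(V)
    payload = {
        "channels": ["red", "green", "blue"],
        "stains": ["hematoxylin", "eosin"],
        "vectors": V.tolist(),
    }
    text = json.dumps(payload, indent=2)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def stain_matrix_from_json(source) -> np.ndarray:
    """Load a stain matrix from a JSON string or file path."""
    try:
        payload = json.loads(source)
    except (json.JSONDecodeError, TypeError):
        with open(source) as fh:
            payload = json.load(fh)
    return validate_stain_matrix(np.asarray(payload["vectors"], dtype=float))
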