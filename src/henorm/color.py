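"""Auxiliary color spaces: Ruderman l-alpha-beta and HSV hue.

The l-alpha-beta space decorrelates natural-image color by moving RGB through
LMS cone responses, taking logs, and rotating onto a luminance axis (l), a
red-green opponent axis (alpha) and a yellow-blue opponent axis (beta). It is
the working space of Reinhard color transfer and of the AMCE metric. Logs are
natural (base e).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.color import rgb2hsv

__all__ = ["rgb_to_lab", "lab_to_rgb", "rgb_to_hue", "HueImage"]

# RGB -> LMS cone matrix (Ruderman et al. constants).
_RGB2LMS = np.array(
    [
        [0.3811, 0.5783, 0.0402],
        [0.1967, 0.7244, 0.0782],
        [0.0241, 0.1288, 0.8444],
    ]
)
_LMS2RGB = np.linalg.inv(_RGB2LMS)

_S3, _S6, _S2 = np.sqrt(3.0), np.sqrt(6.0), np.sqrt(2.0)
# log-LMS -> (l, alpha, beta) with alpha the red-green opponent channel
# (L - M) and beta the yellow-blue channel (L + M - 2S)
_LMS2LAB = np.array(
    [
        [1.0 / _S3, 1.0 / _S3, 1.0 / _S3],
        [1.0 / _S2, -1.0 / _S2, 0.0],
        [1.0 / _S6, 1.0 / _S6, -2.0 / _S6],
    ]
)
_LAB2LMS = np.linalg.inv(_LMS2LAB)

_LOG_EPS = 1e-6  # clamp before log so black pixels stay finite


def rgb_to_lab(img) -> np.ndarray:
    """Ruderman l-alpha-beta forward transform of an 8-bit RGB image."""
    rgb = np.asarray(img, dtype=float) / 255.0
    lms = rgb @ _RGB2LMS.T
    log_lms = np.log(np.clip(lms, _LOG_EPS, None))
    return log_lms @ _LMS2LAB.T


def lab_to_rgb(lab) -> np.ndarray:
    """Inverse of :func:`rgb_to_lab`, rounded half-up and clamped to 8-bit."""
    lab = np.asarray(lab, dtype=float)
    lms = np.exp(lab @ _LAB2LMS.T)
    rgb = lms @ _LMS2RGB.T
    return np.clip(np.floor(rgb * 255.0 + 0.5), 0, 255).astype(np.uint8)


@dataclass(frozen=True)
class HueImage:
    """HSV hue in degrees [0, 360) plus a chromaticity mask.

    Hue is undefined where saturation is zero; those pixels carry hue 0 and
    ``chromatic`` False, and are excluded from hue statistics.
    """

    hue: np.ndarray
    chromatic: np.ndarray
    saturation: np.ndarray
    value: np.ndarray

    def chromatic_hues(self) -> np.ndarray:
        """Hue values (degrees) of the chromatic pixels only."""
        return self.hue[self.chromatic]


def rgb_to_hue(img) -> HueImage:
    """Standard HSV hue of an 8-bit RGB image, in degrees."""
    rgb = np.asarray(img, dtype=float) / 255.0
    hsv = rgb2hsv(rgb)
    hue = (hsv[..., 0] * 360.0) % 360.0
    sat = hsv[..., 1]
    chromatic = sat > 0
    hue = np.where(chromatic, hue, 0.0)
    return HueImage(hue=hue, chromatic=chromatic, saturation=sat, value=hsv[..., 2])
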