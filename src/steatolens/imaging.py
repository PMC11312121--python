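"""Colour calibration of liver photographs.

Consumer cameras store sRGB-encoded intensities. To reason about surface
colour, images are first linearized by undoing the gamma encoding (a pure
power law with exponent 2.2 by default), then white-balanced against a
neutral grey card placed in the frame, and finally converted to CIE 1976
L*a*b* (D65), where a* captures the green-red axis and b* the blue-yellow
axis. Steatotic livers drift toward lower a* and higher b*.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from skimage import color as _skcolor

logger = logging.getLogger(__name__)

#: Linear sRGB (D65 primaries) -> CIE XYZ, 2-degree observer. Rows are
#: rescaled so that RGB (1,1,1) maps exactly onto the D65 reference white
#: used by the Lab conversion, keeping greys perfectly achromatic.
RGB_TO_XYZ = np.array(
    [
        [0.4124564, 0.3575761, 0.1804375],
        [0.2126729, 0.7151522, 0.0721750],
        [0.0193339, 0.1191920, 0.9503041],
    ]
)
_D65_WHITE = _skcolor.xyz_tristimulus_values(illuminant="D65", observer="2")
RGB_TO_XYZ *= (np.asarray(_D65_WHITE) / RGB_TO_XYZ.sum(axis=1))[:, None]
XYZ_TO_RGB = np.linalg.inv(RGB_TO_XYZ)

DEFAULT_GAMMA = 2.2
#: Canonical diffuse reflectance of a photographic grey card.
GREY_CARD_REFLECTANCE = 0.18


class CalibrationError(ValueError):
    """Raised when the grey card is unusable or inputs violate contracts."""


@dataclass(frozen=True)
class CardEstimate:
    """Robust estimate of the grey-card colour in linear RGB.

    Attributes
    ----------
    colour : ndarray, shape (3,)
        Per-channel median over the card region; all entries in (0, 1].
    roi : tuple
        ``(x, y, w, h)`` rectangle in 0-based pixel coordinates.
    n_pixels : int
        Number of pixels the estimate was computed from.
    """

    colour: np.ndarray
    roi: tuple[int, int, int, int]
    n_pixels: int


@dataclass(frozen=True)
class CalibrationResult:
    """Gains applied by :func:`white_balance`.

    ``gains`` neutralize the illuminant tint (card becomes channel-equal);
    ``exposure_scale`` optionally maps the card to 18 % reflectance so that
    exposure is comparable across photographs.
    """

    gains: tuple[float, float, float]
    exposure_scale: float
    gamma: float = DEFAULT_GAMMA


def _check_rgb(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image, dtype=float)
    if image.ndim != 3 or image.shape[2] != 3:
        raise CalibrationError(f"expected an H x W x 3 image, got shape {image.shape}")
    if not np.isfinite(image).all():
        raise CalibrationError("image contains non-finite values")
    if image.min() < 0 or image.max() > 1:
        raise CalibrationError("channel values must lie in [0, 1]")
    return image


def srgb_decode(image: np.ndarray, gamma: float = DEFAULT_GAMMA) -> np.ndarray:
    """Undo gamma encoding: raise each channel value to the power ``gamma``.

    A pure power law is used rather than the piecewise sRGB transfer
    function; the difference is negligible for this application and the
    power law is exactly invertible by :func:`srgb_encode`.
    """
    if gamma <= 0:
        raise CalibrationError("gamma must be positive")
    return _check_rgb(image) ** gamma


def srgb_encode(image: np.ndarray, gamma: float = DEFAULT_GAMMA) -> np.ndarray:
    """Gamma-encode a linear image (inverse of :func:`srgb_decode`)."""
    if gamma <= 0:
        raise CalibrationError("gamma must be positive")
    return _check_rgb(image) ** (1.0 / gamma)


def estimate_card_colour(
    image: np.ndarray, roi: tuple[int, int, int, int]
) -> CardEstimate:
    """Estimate the grey-card colour as the per-channel median over a ROI.

    The median is robust against specks, glare points and slight ROI
    misplacement. ``roi`` is ``(x, y, w, h)``, top-left origin.
    """
    image = _check_rgb(image)
    x, y, w, h = (int(v) for v in roi)
    H, W = image.shape[:2]
    if w <= 0 or h <= 0:
        raise CalibrationError("card ROI is empty")
    if x < 0 or y < 0 or x + w > W or y + h > H:
        raise CalibrationError(f"card ROI {roi} outside image bounds {W}x{H}")
    patch = image[y : y + h, x : x + w]
    colour = np.median(patch.reshape(-1, 3), axis=0)
    if np.any(colour <= 0):
        raise CalibrationError("card estimate has a zero channel; card unusable")
    return CardEstimate(colour=colour, roi=(x, y, w, h), n_pixels=w * h)


def white_balance(
    image: np.ndarray,
    card: CardEstimate,
    normalize_exposure: bool = True,
    target_reflectance: float = GREY_CARD_REFLECTANCE,
    gamma: float = DEFAULT_GAMMA,
) -> tuple[np.ndarray, CalibrationResult]:
    """Neutralize the illuminant using the grey card.

    Per-channel gains ``c_k = m / g_k`` (``m`` the mean of the card
    channels) map the card colour to the neutral ``(m, m, m)``; if
    ``normalize_exposure``, a further scalar maps the card to
    ``target_reflectance`` so features are comparable across exposures.
    Output is clipped to [0, 1]; the clipped fraction is logged.
    """
    image = _check_rgb(image)
    g = np.asarray(card.colour, dtype=float)
    if np.any(g <= 0):
        raise CalibrationError("card colour has a non-positive channel")
    m = float(g.mean())
    gains = m / g
    exposure_scale = target_reflectance / m if normalize_exposure else 1.0
    out = image * gains * exposure_scale
    clipped = float(np.mean(out > 1.0))
    if clipped > 0.01:
        logger.warning("white_balance clipped %.1f%% of pixels", 100 * clipped)
    out = np.clip(out, 0.0, 1.0)
    return out, CalibrationResult(
        gains=tuple(float(c) for c in gains),
        exposure_scale=float(exposure_scale),
        gamma=gamma,
    )


def rgb_to_lab(image: np.ndarray) -> np.ndarray:
    """Convert a *linear* RGB image to CIE 1976 L*a*b* (D65).

    L* is in [0, 100]; a* and b* are the chromaticity axes.
    """
    image = _check_rgb(image)
    xyz = image @ RGB_TO_XYZ.T
    return _skcolor.xyz2lab(xyz)


def lab_to_linear_rgb(lab: np.ndarray) -> np.ndarray:
    """Render L*a*b* values back to linear RGB, clipped to gamut."""
    xyz = _skcolor.lab2xyz(np.asarray(lab, dtype=float))
    rgb = xyz @ XYZ_TO_RGB.T
    return np.clip(rgb, 0.0, 1.0)


def luminance_stats(
    lab: np.ndarray, mask: np.ndarray
) -> tuple[float, float, float]:
    """Quartiles (Q1, median, Q3) of L* over the masked pixels.

    The interquartile range drives specular-patch rejection: patches whose
    mean luminance falls outside [Q1, Q3] of the liver's luminance are
    discarded.
    """
    lab = np.asarray(lab, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if lab.shape[:2] != mask.shape:
        raise CalibrationError("mask shape does not match image")
    L = lab[..., 0][mask]
    if L.size == 0:
        raise CalibrationError("mask is empty")
    q1, med, q3 = np.percentile(L, [25, 50, 75])
    return float(q1), float(med), float(q3)
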