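"""Liver masks: file input or a baseline colour-threshold segmenter.

The primary path is a user-supplied binary mask PNG. The baseline
segmenter exploits that, after calibration, liver tissue is the reddish
(a* > 0) structure of intermediate luminance in the frame, while drapes
and the grey card are neutral or green-blue.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy import ndimage as ndi
from skimage import morphology


class SegmentationError(ValueError):
    pass


@dataclass(frozen=True)
class LiverMask:
    """Binary liver mask with provenance (``file`` or ``baseline``)."""

    mask: np.ndarray
    area: int
    source: str

    def __post_init__(self) -> None:
        if self.area <= 0:
            raise SegmentationError("liver mask is empty")


def load_mask(path: str | Path, expected_shape: tuple[int, int] | None = None) -> LiverMask:
    """Read a mask PNG (0 = background, nonzero = liver)."""
    arr = np.asarray(iio.imread(path))
    if arr.ndim == 3:
        arr = arr[..., 0]
    mask = arr > 0
    if expected_shape is not None and mask.shape != tuple(expected_shape):
        raise SegmentationError(
            f"mask shape {mask.shape} does not match image shape {tuple(expected_shape)}"
        )
    area = int(mask.sum())
    if area == 0:
        raise SegmentationError(f"mask {path} is empty")
    return LiverMask(mask=mask, area=area, source="file")


def baseline_segment(
    lab: np.ndarray,
    a_min: float = 10.0,
    L_range: tuple[float, float] = (15.0, 85.0),
    min_area_fraction: float = 0.005,
    closing_radius: int = 5,
) -> LiverMask:
    """Segment the liver as the largest reddish connected component.

    Pixels with ``a* > a_min`` and L* within ``L_range`` are candidates;
    the map is morphologically closed and the largest connected component
    kept. Intended for controlled scenes (synthetic fixtures, clean
    operating-field photographs), not as a general-purpose segmenter.
    """
    lab = np.asarray(lab, dtype=float)
    L, a = lab[..., 0], lab[..., 1]
    cand = (a > a_min) & (L >= L_range[0]) & (L <= L_range[1])
    cand = morphology.closing(cand, morphology.disk(closing_radius))
    labels, n = ndi.label(cand)
    if n == 0:
        raise SegmentationError("no liver-like component found")
    sizes = ndi.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    best = int(np.argmax(sizes)) + 1
    area = int(sizes[best - 1])
    if area < min_area_fraction * lab.shape[0] * lab.shape[1]:
        raise SegmentationError(
            f"largest component ({area} px) below minimum area fraction {min_area_fraction}"
        )
    return LiverMask(mask=labels == best, area=area, source="baseline")
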