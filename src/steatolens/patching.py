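"""Random non-overlapping patch sampling with specular rejection.

Steatosis is often unevenly distributed, so the liver is analysed as a
set of randomly placed, non-overlapping square patches rather than as a
whole. Patches dominated by specular highlights (wet-surface glare) carry
no colour information; a patch is kept only if its mean luminance lies
within the interquartile range of the liver's luminance. Rejected draws
are replaced by fresh random draws.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .imaging import luminance_stats
from .segmentation import LiverMask

logger = logging.getLogger(__name__)

SIDE_BOUNDS = (60, 120)
COUNT_BOUNDS = (15, 25)


class PatchingError(ValueError):
    pass


@dataclass(frozen=True)
class PatchPlan:
    """Number and side length of patches for a liver of a given area."""

    n_patches: int
    side: int


@dataclass
class Patch:
    """A sampled square region of the Lab image."""

    row: int
    col: int
    side: int
    lab: np.ndarray = field(repr=False)
    mean_L: float = 0.0
    accepted: bool = True


def plan_patches(area: int) -> PatchPlan:
    """Map liver pixel area to a patch plan.

    ``side = clip(round(sqrt(area)/12), 60, 120)`` and
    ``n = clip(round(area/(7*side^2)), 15, 25)``: a one-megapixel liver
    yields ~21 patches of ~83 px, matching the typical operating point of
    20 patches of 80 px, with the stated ranges as hard bounds.
    """
    if area <= 0:
        raise PatchingError("liver area must be positive")
    side = int(np.clip(round(np.sqrt(area) / 12), *SIDE_BOUNDS))
    n = int(np.clip(round(area / (7 * side * side)), *COUNT_BOUNDS))
    if area < SIDE_BOUNDS[0] ** 2 * COUNT_BOUNDS[0]:
        logger.warning("liver area %d is small; patch plan may be infeasible", area)
    return PatchPlan(n_patches=n, side=side)


def reject_specular(
    patch_mean_L: float, q1: float, q3: float, highlights_only: bool = False
) -> bool:
    """Return True (accepted) iff the patch mean luminance passes the IQR rule.

    Two-sided by default (``q1 <= mean_L <= q3``); with
    ``highlights_only`` only the bright side is enforced, rejecting
    specular glare but keeping shadowed tissue.
    """
    if q1 > q3:
        raise PatchingError("q1 must not exceed q3")
    if highlights_only:
        return patch_mean_L <= q3
    return q1 <= patch_mean_L <= q3


def _boxes_overlap(r1: int, c1: int, s1: int, r2: int, c2: int, s2: int) -> bool:
    return not (r1 + s1 <= r2 or r2 + s2 <= r1 or c1 + s1 <= c2 or c2 + s2 <= c1)


def sample_patches(
    mask: LiverMask | np.ndarray,
    lab: np.ndarray,
    plan: PatchPlan,
    seed: int | np.random.Generator,
    highlights_only: bool = False,
    min_patches: int = 8,
    max_attempts: int | None = None,
) -> list[Patch]:
    """Rejection-sample up to ``plan.n_patches`` accepted patches.

    Each accepted patch lies entirely on the mask, is pairwise disjoint
    from the others, and passes the specular IQR rule. Deterministic
    given the seed. Raises if fewer than ``min_patches`` can be placed
    within ``max_attempts`` draws (default ``50 * n_patches``).
    """
    m = mask.mask if isinstance(mask, LiverMask) else np.asarray(mask, dtype=bool)
    lab = np.asarray(lab, dtype=float)
    if lab.shape[:2] != m.shape:
        raise PatchingError("mask shape does not match image")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    q1, _, q3 = luminance_stats(lab, m)
    s = plan.side
    H, W = m.shape
    if H < s or W < s:
        raise PatchingError("image smaller than patch side")
    if max_attempts is None:
        max_attempts = 50 * plan.n_patches

    # summed-area table for O(1) full-containment checks
    ii = np.pad(m.astype(np.int64), ((1, 0), (1, 0))).cumsum(0).cumsum(1)
    target = s * s

    # draw origins uniformly over the mask's bounding box, not the frame
    rows = np.flatnonzero(m.any(axis=1))
    cols = np.flatnonzero(m.any(axis=0))
    r_lo, r_hi = int(rows[0]), max(int(rows[0]), min(int(rows[-1]) - s + 1, H - s))
    c_lo, c_hi = int(cols[0]), max(int(cols[0]), min(int(cols[-1]) - s + 1, W - s))

    accepted: list[Patch] = []
    L = lab[..., 0]
    for _ in range(max_attempts):
        if len(accepted) >= plan.n_patches:
            break
        r = int(rng.integers(r_lo, r_hi + 1))
        c = int(rng.integers(c_lo, c_hi + 1))
        if ii[r + s, c + s] - ii[r, c + s] - ii[r + s, c] + ii[r, c] != target:
            continue
        if any(_boxes_overlap(r, c, s, p.row, p.col, p.side) for p in accepted):
            continue
        mean_L = float(L[r : r + s, c : c + s].mean())
        if not reject_specular(mean_L, q1, q3, highlights_only=highlights_only):
            continue
        accepted.append(
            Patch(row=r, col=c, side=s, lab=lab[r : r + s, c : c + s], mean_L=mean_L)
        )
    if len(accepted) < min(min_patches, plan.n_patches):
        raise PatchingError(
            f"insufficient valid area: only {len(accepted)} patches placed "
            f"(minimum {min_patches}) after {max_attempts} attempts"
        )
    return accepted
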