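"""Per-patch colour and texture features.

Each patch is summarised by histograms of its L*, a*, b* intensities
(colour) and by histograms of local binary pattern codes computed on each
Lab channel (texture). Steatosis shifts the colour histograms toward
yellow (higher b*, lower a*) and coarsens the texture, which changes the
LBP code distribution. Donor biochemistry can be appended as a
standardized 7-vector.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cases import CLINICAL_FIELDS, DonorRecord
from .patching import Patch


class FeatureError(ValueError):
    pass


@dataclass(frozen=True)
class FeatureConfig:
    """Histogram layout for patch features.

    32 bins per colour channel over the fixed Lab ranges and the full
    256-bin raw LBP histogram per channel give a 864-dimensional image
    descriptor; ``use_clinical`` appends the standardized donor vector
    (age, sex, BMI, AST, ALT, GGT, bilirubin) for 871 dimensions total.
    """

    colour_bins: int = 32
    lbp_bins: int = 256
    L_range: tuple[float, float] = (0.0, 100.0)
    a_range: tuple[float, float] = (-128.0, 127.0)
    b_range: tuple[float, float] = (-128.0, 127.0)
    use_clinical: bool = False
    lbp_channels: tuple[str, ...] = ("L", "a", "b")

    def __post_init__(self) -> None:
        if self.colour_bins < 2 or self.lbp_bins < 2:
            raise FeatureError("bin counts must be >= 2")

    @property
    def n_image_features(self) -> int:
        return 3 * self.colour_bins + len(self.lbp_channels) * self.lbp_bins

    @property
    def n_features(self) -> int:
        return self.n_image_features + (len(CLINICAL_FIELDS) if self.use_clinical else 0)


@dataclass
class PatchFeatures:
    colour_hist: np.ndarray  # (3, colour_bins), each row sums to 1
    lbp_hist: np.ndarray  # (n_channels, lbp_bins), each row sums to 1
    clinical: np.ndarray | None = None

    @property
    def vector(self) -> np.ndarray:
        parts = [self.colour_hist.ravel(), self.lbp_hist.ravel()]
        if self.clinical is not None:
            parts.append(self.clinical)
        return np.concatenate(parts)


def lab_histogram(
    values: np.ndarray, value_range: tuple[float, float], bins: int
) -> np.ndarray:
    """Normalized histogram over equal-width bins on a fixed range.

    Out-of-range values are clipped into the edge bins so that the
    result is always a probability vector.
    """
    values = np.asarray(values, dtype=float).ravel()
    if values.size == 0:
        raise FeatureError("empty input to histogram")
    if bins < 2:
        raise FeatureError("bins must be >= 2")
    lo, hi = value_range
    counts, _ = np.histogram(np.clip(values, lo, hi), bins=bins, range=(lo, hi))
    return counts / counts.sum()


# clockwise from the top-left neighbour; bit i corresponds to offset i
_LBP_OFFSETS = (
    (-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1),
)


def lbp_codes(channel: np.ndarray) -> np.ndarray:
    """Classic 8-neighbour radius-1 local binary patterns.

    For each interior pixel, bit ``i`` is set iff neighbour ``i`` (ordered
    clockwise from the top-left) is >= the centre value; the border is
    excluded. A constant image therefore maps to code 255 and a strict
    local maximum to code 0.
    """
    x = np.asarray(channel, dtype=float)
    if x.ndim != 2 or min(x.shape) < 3:
        raise FeatureError("LBP needs a 2-D grid with side >= 3")
    c = x[1:-1, 1:-1]
    codes = np.zeros(c.shape, dtype=np.uint16)
    h, w = c.shape
    for i, (dr, dc) in enumerate(_LBP_OFFSETS):
        nb = x[1 + dr : 1 + dr + h, 1 + dc : 1 + dc + w]
        codes |= (nb >= c).astype(np.uint16) << i
    return codes.astype(np.uint8)


def lbp_histogram(codes: np.ndarray, bins: int = 256) -> np.ndarray:
    """Normalized histogram of LBP codes."""
    codes = np.asarray(codes).ravel()
    if codes.size == 0:
        raise FeatureError("empty LBP code grid")
    counts = np.bincount(codes, minlength=bins)[:bins]
    return counts / counts.sum()


@dataclass
class ClinicalScaler:
    """Median-centred, std-scaled transform for the donor vector.

    Fitted on training donors only (and stored with the model) so that
    test-set statistics never leak into feature scaling. Missing values
    are imputed with the training median, i.e. map to 0 after centring.
    """

    center: np.ndarray = field(default_factory=lambda: np.zeros(len(CLINICAL_FIELDS)))
    scale: np.ndarray = field(default_factory=lambda: np.ones(len(CLINICAL_FIELDS)))

    @staticmethod
    def raw_vector(donor: DonorRecord) -> np.ndarray:
        vals = []
        for name in CLINICAL_FIELDS:
            v = getattr(donor, name)
            if name == "sex":
                v = None if v is None else (1.0 if str(v).upper().startswith("M") else 0.0)
            vals.append(np.nan if v is None else float(v))
        return np.array(vals)

    @classmethod
    def fit(cls, donors: list[DonorRecord]) -> "ClinicalScaler":
        if not donors:
            raise FeatureError("cannot fit clinical scaler on zero donors")
        raw = np.stack([cls.raw_vector(d) for d in donors])
        center = np.nanmedian(raw, axis=0)
        center = np.where(np.isnan(center), 0.0, center)
        scale = np.nanstd(raw, axis=0)
        scale = np.where((scale == 0) | np.isnan(scale), 1.0, scale)
        return cls(center=center, scale=scale)

    def transform(self, donor: DonorRecord) -> np.ndarray:
        raw = self.raw_vector(donor)
        raw = np.where(np.isnan(raw), self.center, raw)
        return (raw - self.center) / self.scale


def patch_image_features(patch: Patch, cfg: FeatureConfig) -> PatchFeatures:
    """Colour and LBP histograms for one patch (no clinical block)."""
    lab = patch.lab
    ranges = {"L": cfg.L_range, "a": cfg.a_range, "b": cfg.b_range}
    chan = {"L": lab[..., 0], "a": lab[..., 1], "b": lab[..., 2]}
    colour = np.stack(
        [lab_histogram(chan[c], ranges[c], cfg.colour_bins) for c in ("L", "a", "b")]
    )
    lbp = np.stack(
        [lbp_histogram(lbp_codes(chan[c]), cfg.lbp_bins) for c in cfg.lbp_channels]
    )
    return PatchFeatures(colour_hist=colour, lbp_hist=lbp)


def build_features(
    patch: Patch,
    cfg: FeatureConfig,
    donor: DonorRecord | None = None,
    scaler: ClinicalScaler | None = None,
) -> PatchFeatures:
    """Full feature set for one patch, with clinical block if configured."""
    pf = patch_image_features(patch, cfg)
    if cfg.use_clinical:
        if donor is None or scaler is None:
            raise FeatureError("clinical features requested but donor/scaler absent")
        pf.clinical = scaler.transform(donor)
    return pf


def feature_names(cfg: FeatureConfig) -> list[str]:
    names = [
        f"colour_{c}_bin{i}" for c in ("L", "a", "b") for i in range(cfg.colour_bins)
    ]
    names += [
        f"lbp_{c}_code{i}" for c in cfg.lbp_channels for i in range(cfg.lbp_bins)
    ]
    if cfg.use_clinical:
        names += list(CLINICAL_FIELDS)
    return names
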