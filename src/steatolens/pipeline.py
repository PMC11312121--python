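"""End-to-end glue: images in, per-patch feature table out.

``build_patch_table`` runs calibration, masking, patch sampling and
image-feature extraction once per case and caches the result in a
:class:`PatchTable`; training-time concerns (clinical standardization,
labels at a given HS threshold) are applied per split so that no
training statistics leak across cross-validation folds.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np

from .cases import DonorRecord
from .features import (
    ClinicalScaler,
    FeatureConfig,
    patch_image_features,
)
from .imaging import (
    estimate_card_colour,
    luminance_stats,
    rgb_to_lab,
    srgb_decode,
    white_balance,
)
from .patching import plan_patches, sample_patches
from .aggregate_eval import NON_VALID, VALID


class PipelineError(ValueError):
    pass


def calibrate_image(
    image_encoded: np.ndarray,
    card_roi: tuple[int, int, int, int],
    gamma: float = 2.2,
    normalize_exposure: bool = True,
) -> np.ndarray:
    """Gamma-decode, white-balance against the card, and convert to Lab."""
    linear = srgb_decode(image_encoded, gamma)
    card = estimate_card_colour(linear, card_roi)
    balanced, _ = white_balance(linear, card, normalize_exposure=normalize_exposure)
    return rgb_to_lab(balanced)


@dataclass
class PatchTable:
    """Cached per-patch image features for a set of cases."""

    feature_cfg: FeatureConfig  # image-only layout (use_clinical False)
    X_img: np.ndarray  # (n_patches, d_img)
    patch_case: np.ndarray  # (n_patches,) index into cases
    case_ids: list[str]
    donors: list[DonorRecord]
    biopsies: list[list[float]]  # per-case available lobe HS values
    surgeon_hs: list[Optional[float]]
    calibrated: bool = True

    @property
    def n_cases(self) -> int:
        return len(self.case_ids)

    def case_hs_values(self, lobe_rule: str = "mean") -> np.ndarray:
        from .classify import case_hs

        return np.array([case_hs(b, lobe_rule) for b in self.biopsies])

    def case_labels(self, threshold: float, lobe_rule: str = "mean") -> np.ndarray:
        hs = self.case_hs_values(lobe_rule)
        return np.where(hs > threshold, NON_VALID, VALID)

    def donor_labels(self, threshold: float, lobe_rule: str = "mean") -> dict[str, int]:
        labels = self.case_labels(threshold, lobe_rule)
        return {d.donor_id: int(l) for d, l in zip(self.donors, labels)}

    def indices_for(self, donor_ids: Sequence[str]) -> list[int]:
        wanted = set(donor_ids)
        return [i for i, d in enumerate(self.donors) if d.donor_id in wanted]

    def fit_clinical_scaler(self, case_idx: Sequence[int]) -> ClinicalScaler:
        return ClinicalScaler.fit([self.donors[i] for i in case_idx])

    def feature_cfg_with_clinical(self, use_clinical: bool) -> FeatureConfig:
        return replace(self.feature_cfg, use_clinical=use_clinical)

    def case_matrix(
        self,
        case_index: int,
        use_clinical: bool,
        scaler: Optional[ClinicalScaler],
    ) -> np.ndarray:
        """Feature matrix of one case's patches, clinical block appended."""
        rows = self.X_img[self.patch_case == case_index]
        if rows.shape[0] == 0:
            raise PipelineError(f"case {self.case_ids[case_index]} has no patches")
        if not use_clinical:
            return rows
        if scaler is None:
            raise PipelineError("clinical features requested without a fitted scaler")
        clin = scaler.transform(self.donors[case_index])
        return np.hstack([rows, np.tile(clin, (rows.shape[0], 1))])

    def training_matrix(
        self,
        case_idx: Sequence[int],
        threshold: float,
        lobe_rule: str,
        use_clinical: bool,
        scaler: Optional[ClinicalScaler],
    ) -> tuple[np.ndarray, np.ndarray]:
        labels = self.case_labels(threshold, lobe_rule)
        Xs, ys = [], []
        for ci in case_idx:
            Xc = self.case_matrix(ci, use_clinical, scaler)
            Xs.append(Xc)
            ys.append(np.full(Xc.shape[0], labels[ci], dtype=int))
        return np.vstack(Xs), np.concatenate(ys)


def build_patch_table(
    cases: Sequence,
    feature_cfg: FeatureConfig = FeatureConfig(),
    seed: int = 0,
    calibrate: bool = True,
    gamma: float = 2.2,
    highlights_only: bool = False,
) -> PatchTable:
    """Extract patch image features for every case.

    ``cases`` are objects exposing ``image`` (gamma-encoded H x W x 3
    floats), ``mask``, ``card_roi``, ``donor``, per-lobe biopsy fields and
    an optional surgeon estimate (both :class:`~steatolens.synthetic.SyntheticCase`
    and loaded file-backed cases qualify). With ``calibrate=False`` the
    encoded image is used as-is (no gamma decoding, no white balance) —
    the ablation arm for quantifying what calibration buys.
    """
    img_cfg = replace(feature_cfg, use_clinical=False)
    rows, patch_case = [], []
    case_ids, donors, biopsies, surgeons = [], [], [], []
    for i, case in enumerate(cases):
        if calibrate:
            lab = calibrate_image(case.image, case.card_roi, gamma=gamma)
        else:
            lab = rgb_to_lab(case.image)
        mask = case.mask
        plan = plan_patches(int(mask.sum()))
        rng = np.random.default_rng([seed, i])
        patches = sample_patches(
            mask, lab, plan, rng, highlights_only=highlights_only
        )
        for p in patches:
            rows.append(patch_image_features(p, img_cfg).vector)
            patch_case.append(i)
        case_ids.append(case.case_id)
        donors.append(case.donor)
        vals = [
            v
            for v in (case.biopsy_hs_left, case.biopsy_hs_right)
            if v is not None
        ]
        if not vals:
            raise PipelineError(f"case {case.case_id} has no biopsy values")
        biopsies.append(vals)
        surgeons.append(getattr(case, "surgeon_hs_estimate", None))
    return PatchTable(
        feature_cfg=img_cfg,
        X_img=np.asarray(rows),
        patch_case=np.asarray(patch_case),
        case_ids=case_ids,
        donors=donors,
        biopsies=biopsies,
        surgeon_hs=surgeons,
        calibrated=calibrate,
    )
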