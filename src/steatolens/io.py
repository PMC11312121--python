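"""Dataset, model-bundle and report I/O.

The manifest CSV is the single source of truth for a dataset on disk:
one row per case with donor covariates, biopsy values, the card ROI and
relative image/mask paths. Images are 16-bit PNGs (sRGB-encoded), masks
8-bit PNGs with 0 = background.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional

import imageio.v3 as iio
import joblib
import numpy as np
import pandas as pd

from .cases import DonorRecord
from .classify import TrainedModel
from .synthetic import SyntheticCase

MANIFEST_NAME = "manifest.csv"

DONOR_COLUMNS = [
    "donor_id", "age", "sex", "bmi", "ast", "alt", "ggt", "bilirubin",
    "biopsy_hs_left", "biopsy_hs_right", "surgeon_hs",
]


@dataclass
class LoadedCase:
    """A case read back from a dataset directory."""

    donor: DonorRecord
    image: np.ndarray
    mask: np.ndarray
    card_roi: tuple[int, int, int, int]
    biopsy_hs_left: Optional[float]
    biopsy_hs_right: Optional[float]
    surgeon_hs_estimate: Optional[float]
    hs_true: Optional[float] = None

    @property
    def case_id(self) -> str:
        return self.donor.donor_id


def _encode_png8(image: np.ndarray) -> np.ndarray:
    return np.round(np.clip(image, 0, 1) * 255).astype(np.uint8)


def read_image(path: str | Path) -> np.ndarray:
    """Read a PNG as floats in [0, 1] (8- or 16-bit greyscale/RGB)."""
    arr = np.asarray(iio.imread(path))
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    arr = arr[..., :3]
    scale = 65535.0 if arr.dtype == np.uint16 else 255.0
    return arr.astype(float) / scale


def save_dataset(cases: list[SyntheticCase], out_dir: str | Path) -> Path:
    """Write images, masks and the manifest for a synthetic dataset."""
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(parents=True, exist_ok=True)
    rows = []
    for case in cases:
        cid = case.case_id
        img_rel, mask_rel = f"images/{cid}.png", f"masks/{cid}.png"
        iio.imwrite(out / img_rel, _encode_png8(case.image))
        iio.imwrite(out / mask_rel, (case.mask.astype(np.uint8)) * 255)
        d = case.donor
        x, y, w, h = case.card_roi
        rows.append(
            {
                "donor_id": cid, "image": img_rel, "mask": mask_rel,
                "card_x": x, "card_y": y, "card_w": w, "card_h": h,
                "age": d.age, "sex": d.sex, "bmi": d.bmi, "ast": d.ast,
                "alt": d.alt, "ggt": d.ggt, "bilirubin": d.bilirubin,
                "biopsy_hs_left": round(case.biopsy_hs_left, 2),
                "biopsy_hs_right": round(case.biopsy_hs_right, 2),
                "surgeon_hs": round(case.surgeon_hs_estimate, 2),
                "hs_true": round(case.hs_true, 3),
                "gain_r": case.lighting_gains[0],
                "gain_g": case.lighting_gains[1],
                "gain_b": case.lighting_gains[2],
                "exposure": case.exposure,
                "render_seed": case.render_seed,
            }
        )
    pd.DataFrame(rows).to_csv(out / MANIFEST_NAME, index=False)
    return out / MANIFEST_NAME


def _opt(v) -> Optional[float]:
    return None if v is None or (isinstance(v, float) and np.isnan(v)) else float(v)


def donor_from_row(row: pd.Series) -> DonorRecord:
    return DonorRecord(
        donor_id=str(row["donor_id"]),
        age=_opt(row.get("age")),
        sex=None if pd.isna(row.get("sex")) else str(row["sex"]),
        bmi=_opt(row.get("bmi")),
        ast=_opt(row.get("ast")),
        alt=_opt(row.get("alt")),
        ggt=_opt(row.get("ggt")),
        bilirubin=_opt(row.get("bilirubin")),
    )


def load_dataset(dataset_dir: str | Path) -> list[LoadedCase]:
    """Read every case referenced by the manifest."""
    root = Path(dataset_dir)
    manifest = pd.read_csv(root / MANIFEST_NAME)
    cases = []
    for _, row in manifest.iterrows():
        image = read_image(root / row["image"])
        mask_arr = np.asarray(iio.imread(root / row["mask"]))
        if mask_arr.ndim == 3:
            mask_arr = mask_arr[..., 0]
        cases.append(
            LoadedCase(
                donor=donor_from_row(row),
                image=image,
                mask=mask_arr > 0,
                card_roi=(int(row["card_x"]), int(row["card_y"]),
                          int(row["card_w"]), int(row["card_h"])),
                biopsy_hs_left=_opt(row.get("biopsy_hs_left")),
                biopsy_hs_right=_opt(row.get("biopsy_hs_right")),
                surgeon_hs_estimate=_opt(row.get("surgeon_hs")),
                hs_true=_opt(row.get("hs_true")),
            )
        )
    return cases


def save_model(model: TrainedModel, out_dir: str | Path) -> None:
    """Model bundle: JSON metadata next to the serialized estimator."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {
        "kind": model.kind,
        "hs_threshold": model.hs_threshold,
        "lobe_rule": model.lobe_rule,
        "class_weights": {str(k): v for k, v in model.class_weights.items()},
        "grid_point": {k: v for k, v in model.grid_point.items()},
        "seed": model.seed,
        "feature_cfg": asdict(model.feature_cfg),
    }
    (out / "metadata.json").write_text(json.dumps(meta, indent=2, default=str))
    joblib.dump(model, out / "model.joblib")


def load_model(model_dir: str | Path) -> TrainedModel:
    return joblib.load(Path(model_dir) / "model.joblib")


def write_provenance(path: str | Path, config: dict, seed: int) -> None:
    """Record config hash, seed and library versions next to an output."""
    import sklearn

    from . import __version__

    blob = json.dumps(config, sort_keys=True, default=str)
    record = {
        "config": config,
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
        "seed": seed,
        "versions": {
            "steatolens": __version__,
            "numpy": np.__version__,
            "scikit-learn": sklearn.__version__,
            "python": platform.python_version(),
        },
    }
    Path(path).write_text(json.dumps(record, indent=2, default=str))
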