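"""Core records: donors, photographs, and liver cases."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

CLINICAL_FIELDS = ("age", "sex", "bmi", "ast", "alt", "ggt", "bilirubin")


@dataclass(frozen=True)
class DonorRecord:
    """Donor demographics and liver biochemistry.

    ``sex`` is ``"M"`` or ``"F"``; enzymes (AST, ALT, GGT) in IU/L,
    bilirubin in mg/dL, BMI in kg/m2. Missing values are ``None`` and
    are median-imputed at feature-building time.
    """

    donor_id: str
    age: Optional[float] = None
    sex: Optional[str] = None
    bmi: Optional[float] = None
    ast: Optional[float] = None
    alt: Optional[float] = None
    ggt: Optional[float] = None
    bilirubin: Optional[float] = None


@dataclass
class Photo:
    """One photograph of a liver: path or in-memory array plus metadata."""

    image_path: Optional[str] = None
    mask_path: Optional[str] = None
    card_roi: Optional[tuple[int, int, int, int]] = None
    lobe: Optional[str] = None
    timing: str = "pre-biopsy"


@dataclass
class LiverCase:
    """One donor's photographs and ground truth.

    Biopsy steatosis percentages are recorded per lobe; the surgeon's
    visual estimate is optional.
    """

    donor: DonorRecord
    photos: list[Photo] = field(default_factory=list)
    biopsy_hs_left: Optional[float] = None
    biopsy_hs_right: Optional[float] = None
    surgeon_hs_estimate: Optional[float] = None

    @property
    def case_id(self) -> str:
        return self.donor.donor_id

    def biopsy_values(self) -> list[float]:
        return [v for v in (self.biopsy_hs_left, self.biopsy_hs_right) if v is not None]
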