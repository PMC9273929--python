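"""Diagnostic category assignment for QCT vBMD and DXA T-scores.

Three-way categories (normal / osteopenia / osteoporosis) under the ACR
volumetric criteria for QCT and the WHO T-score criteria for DXA, plus
the clinical composite DXA label (lower of spine and hip T-scores).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Optional

from .config import ClassificationConfig
from .errors import PLQCTError

if TYPE_CHECKING:  # pragma: no cover
    from .calibration import CalibrationModel
    from .roi_selection import ROIStats

CATEGORIES = ("normal", "osteopenia", "osteoporosis")

NORMAL = "normal"
OSTEOPENIA = "osteopenia"
OSTEOPOROSIS = "osteoporosis"


def classify_qct(vbmd_mgcc: float,
                 config: ClassificationConfig | None = None) -> str:
    """Categorize a volumetric BMD value (mg/cc).

    Osteoporosis strictly below the lower threshold (default 80 mg/cc);
    osteopenia on the closed interval up to the upper threshold (default
    120 mg/cc); normal above. The boundary convention is configurable in
    spirit but fixed here: 80.0 itself is osteopenia, 120.0 is
    osteopenia.
    """
    cfg = config or ClassificationConfig()
    if not math.isfinite(vbmd_mgcc):
        raise PLQCTError("non-finite vBMD", stage="classification")
    if vbmd_mgcc < cfg.qct_osteoporosis_mgcc:
        return OSTEOPOROSIS
    if vbmd_mgcc <= cfg.qct_osteopenia_upper_mgcc:
        return OSTEOPENIA
    return NORMAL


def classify_dxa(t_score: float,
                 config: ClassificationConfig | None = None) -> str:
    """Categorize a DXA T-score under the WHO criteria.

    T <= -2.5 is osteoporosis; -2.5 < T <= -1.0 is osteopenia; above
    -1.0 is normal.
    """
    cfg = config or ClassificationConfig()
    if not math.isfinite(t_score):
        raise PLQCTError("non-finite T-score", stage="classification")
    if t_score <= cfg.dxa_osteoporosis_t:
        return OSTEOPOROSIS
    if t_score <= cfg.dxa_osteopenia_t:
        return OSTEOPENIA
    return NORMAL


@dataclass
class DXALabel:
    """Composite DXA diagnosis: the lower of the available site T-scores."""

    patient_id: str
    spine_t: Optional[float]
    hip_t: Optional[float]
    composite_t: float
    category: str


def composite_dxa_label(spine_t: Optional[float], hip_t: Optional[float],
                        patient_id: str = "",
                        config: ClassificationConfig | None = None) -> DXALabel:
    """Clinical composite: diagnose on the lower of spine and hip T-scores.

    Raises if both sites are absent (no DXA reference available).
    """
    available = [t for t in (spine_t, hip_t) if t is not None]
    if not available:
        raise PLQCTError("no DXA reference", stage="classification")
    composite = min(available)
    return DXALabel(patient_id=patient_id, spine_t=spine_t, hip_t=hip_t,
                    composite_t=composite,
                    category=classify_dxa(composite, config))


@dataclass
class BMDResult:
    """One volume's phantom-less QCT measurement, with full audit trail."""

    patient_id: str
    vbmd_mgcc: float
    category: str
    roi_stats: dict = field(default_factory=dict)     # label -> ROIStats
    calibration: "Optional[CalibrationModel]" = None
    flags: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        cal = self.calibration
        stats = {k: {"mean_hu": s.mean_hu, "sd_hu": s.sd_hu,
                     "n_voxels": s.n_voxels, "trimmed": s.trimmed}
                 for k, s in self.roi_stats.items()}
        return {
            "patient_id": self.patient_id,
            "vbmd_mgcc": self.vbmd_mgcc,
            "category": self.category,
            "roi_stats": stats,
            "calibration": None if cal is None else {
                "slope": cal.slope, "intercept": cal.intercept,
                "hu_fat": cal.hu_fat, "hu_muscle": cal.hu_muscle,
                "rho_fat": cal.rho_fat, "rho_muscle": cal.rho_muscle,
            },
            "flags": list(self.flags),
        }

    def to_csv_row(self) -> dict:
        """Flat one-row form (patient_id, vbmd, category, HU inputs, line)."""
        cal = self.calibration
        trab = self.roi_stats.get("trabecular")
        return {
            "patient_id": self.patient_id,
            "vbmd_mgcc": self.vbmd_mgcc,
            "category": self.category,
            "hu_trab": None if trab is None else trab.mean_hu,
            "hu_fat": None if cal is None else cal.hu_fat,
            "hu_muscle": None if cal is None else cal.hu_muscle,
            "slope": None if cal is None else cal.slope,
            "intercept": None if cal is None else cal.intercept,
            "flags": ";".join(self.flags),
        }
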