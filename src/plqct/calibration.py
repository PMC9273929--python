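"""Internal two-tissue calibration: Hounsfield units to vBMD.

Phantom-less QCT replaces the external reference phantom with two
in-scan tissues of known equivalent density. With fat and muscle ROI
attenuations ``H_fat`` and ``H_muscle`` and configured reference
equivalent densities ``rho_fat`` and ``rho_muscle`` (mg/cc), the HU→
density map is the exact two-point line

    slope     = (rho_muscle - rho_fat) / (H_muscle - H_fat)
    intercept = rho_fat - slope * H_fat

and vBMD = slope * H_trab + intercept. Because the line is fitted inside
each scan, scanner-to-scanner differences in HU response cancel — the
point of phantom-less calibration.

This module also fits per-device HU–vBMD regressions (ordinary least
squares with Pearson r), used to show that raw CT numbers are not
interchangeable across scanners even though calibrated vBMD is.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .classification import BMDResult, classify_qct
from .config import RunConfig
from .ct_io import CTVolume
from .errors import DegenerateTissueContrastError, PLQCTError
from .roi_selection import (
    locate_vertebral_level,
    place_tissue_rois,
    place_trabecular_roi,
    roi_statistics,
)


@dataclass
class CalibrationModel:
    """Two-point linear HU→vBMD map with its tissue anchors."""

    slope: float        # mg/cc per HU
    intercept: float    # mg/cc
    hu_fat: float
    hu_muscle: float
    rho_fat: float
    rho_muscle: float

    def __post_init__(self):
        if self.hu_muscle <= self.hu_fat:
            raise DegenerateTissueContrastError(
                "muscle must attenuate more than fat (hu_muscle > hu_fat)")


@dataclass
class DeviceRegression:
    """OLS fit of vBMD on raw HU for one scanner."""

    device: str
    slope: float
    intercept: float
    pearson_r: float
    n: int


def fit_internal_calibration(hu_fat: float, hu_muscle: float,
                             rho_fat: float, rho_muscle: float,
                             min_contrast_hu: float = 10.0) -> CalibrationModel:
    """Exact two-point line through (hu_fat, rho_fat), (hu_muscle, rho_muscle).

    Rejects scans where the fat/muscle attenuation contrast is below
    ``min_contrast_hu`` — with nearly coincident anchors the line (and
    every density derived from it) is numerically unreliable.
    """
    if abs(hu_muscle - hu_fat) < min_contrast_hu:
        raise DegenerateTissueContrastError(
            f"degenerate tissue contrast: |{hu_muscle:.1f} - {hu_fat:.1f}| "
            f"< {min_contrast_hu} HU")
    slope = (rho_muscle - rho_fat) / (hu_muscle - hu_fat)
    intercept = rho_fat - slope * hu_fat
    return CalibrationModel(slope=slope, intercept=intercept,
                            hu_fat=hu_fat, hu_muscle=hu_muscle,
                            rho_fat=rho_fat, rho_muscle=rho_muscle)


def apply_calibration(model: CalibrationModel, hu_trab: float) -> float:
    """vBMD (mg/cc) for a trabecular attenuation under the fitted line.

    Negative outputs for pathologic inputs are returned as-is (flagged
    by callers), never clamped.
    """
    if not math.isfinite(hu_trab):
        raise PLQCTError("non-finite trabecular HU", stage="calibration")
    return model.slope * hu_trab + model.intercept


def measure_vbmd(vol: CTVolume, config: RunConfig | None = None,
                 level: str = "T12") -> BMDResult:
    """Full phantom-less measurement on one volume.

    Pipeline: locate the vertebral level → place trabecular and tissue
    ROIs → trimmed ROI statistics → internal calibration → vBMD and
    diagnostic category. Each stage's errors propagate with their stage
    tag; the result carries all ROI statistics and the calibration line
    for audit.
    """
    cfg = config or RunConfig()
    center = locate_vertebral_level(vol, level=level, config=cfg.roi)
    trab_roi = place_trabecular_roi(vol, center, cfg.roi)
    fat_roi, ml_roi, mr_roi = place_tissue_rois(vol, center, cfg.roi)

    stats = {roi.label: roi_statistics(vol, roi, config=cfg.roi)
             for roi in (trab_roi, fat_roi, ml_roi, mr_roi)}
    hu_fat = stats["fat"].mean_hu
    # symmetric weighting of the two paraspinal ROIs
    hu_muscle = 0.5 * (stats["muscle_left"].mean_hu
                       + stats["muscle_right"].mean_hu)
    model = fit_internal_calibration(
        hu_fat, hu_muscle,
        cfg.calibration.rho_fat_mgcc, cfg.calibration.rho_muscle_mgcc,
        cfg.calibration.min_tissue_contrast_hu)
    vbmd = apply_calibration(model, stats["trabecular"].mean_hu)

    flags = [f"unreliable_roi:{s.label}" for s in stats.values()
             if not s.reliable]
    if vbmd < 0:
        flags.append("negative_vbmd")
    return BMDResult(patient_id=vol.patient_id,
                     vbmd_mgcc=vbmd,
                     category=classify_qct(vbmd, cfg.classification),
                     roi_stats=stats,
                     calibration=model,
                     flags=flags)


def fit_device_regression(hu, vbmd, device: str = "") -> DeviceRegression:
    """OLS slope/intercept and Pearson r of vBMD against raw HU."""
    x = np.asarray(hu, dtype=float)
    y = np.asarray(vbmd, dtype=float)
    if x.size != y.size or x.size < 3:
        raise PLQCTError("need >= 3 paired observations", stage="regression")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise PLQCTError("non-finite observations", stage="regression")
    sxx = float(np.sum((x - x.mean()) ** 2))
    syy = float(np.sum((y - y.mean()) ** 2))
    if sxx == 0:
        raise PLQCTError("zero variance in HU; regression undefined",
                         stage="regression")
    sxy = float(np.sum((x - x.mean()) * (y - y.mean())))
    slope = sxy / sxx
    intercept = float(y.mean() - slope * x.mean())
    r = sxy / math.sqrt(sxx * syy) if syy > 0 else float("nan")
    return DeviceRegression(device=device, slope=slope, intercept=intercept,
                            pearson_r=r, n=int(x.size))
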