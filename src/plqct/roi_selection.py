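"""Vertebral-level localization and automatic ROI placement.

The measurement needs four regions at the level of interest (T12 by
default): an elliptical ROI in the anterior-central trabecular
compartment of the vertebral body, two paraspinal-muscle ROIs, and a
subcutaneous-fat ROI. Placement is fully deterministic: bone is found by
HU thresholding inside a posterior-midline corridor, vertebral bodies
are the z-runs of bone area separated by disc gaps, and tissue ROIs are
the scaled inscribed ellipses of morphologically cleaned HU-window
candidate masks. All windows, margins and minimum sizes live in
:class:`~plqct.config.ROIConfig`.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from .config import ROIConfig
from .ct_io import CTVolume
from .errors import (
    DegenerateROIError,
    EmptyROIError,
    LevelNotInFOVError,
    NoSpineFoundError,
    TissueROINotFoundError,
)

#: Thoracic + lumbar levels, cranial to caudal, used to map a level label
#: to a body index counted from the most cranial fully-imaged body.
VERTEBRAL_LEVELS = tuple(f"T{i}" for i in range(1, 13)) + \
    tuple(f"L{i}" for i in range(1, 6))


@dataclass
class ROISpec:
    """A parametric elliptical ROI: center voxel, in-plane semi-axes (mm),
    and the number of axial slices it spans (centered on the mid slice)."""

    label: str                       # trabecular | muscle_left | muscle_right | fat
    center_voxel: tuple[int, int, int]   # (z, y, x)
    semi_axes_mm: tuple[float, float]    # (a along rows/y, b along cols/x)
    slice_span: int = 1
    shape: str = "ellipse"

    def __post_init__(self):
        if self.semi_axes_mm[0] <= 0 or self.semi_axes_mm[1] <= 0:
            raise DegenerateROIError("ROI semi-axes must be positive")
        if self.slice_span < 1:
            raise DegenerateROIError("slice_span must be >= 1")

    def to_dict(self) -> dict:
        return {"label": self.label, "center_voxel": list(self.center_voxel),
                "semi_axes_mm": list(self.semi_axes_mm),
                "slice_span": self.slice_span, "shape": self.shape}


@dataclass
class ROIStats:
    label: str
    mean_hu: float
    sd_hu: float
    n_voxels: int
    trimmed: bool
    reliable: bool = True


def save_roi_set(rois, path: str | Path) -> None:
    """JSON sidecar describing a set of ROIs, for audit/overlay."""
    Path(path).write_text(json.dumps([r.to_dict() for r in rois], indent=1))


def roi_mask(vol: CTVolume, roi: ROISpec) -> np.ndarray:
    """Rasterize an ROI into a boolean voxel mask (same shape as volume)."""
    nz, ny, nx = vol.shape
    cz, cy, cx = roi.center_voxel
    sy, sx = vol.spacing_mm[1], vol.spacing_mm[2]
    a, b = roi.semi_axes_mm
    z0 = max(0, cz - roi.slice_span // 2)
    z1 = min(nz, z0 + roi.slice_span)
    yy, xx = np.indices((ny, nx))
    inplane = (((yy - cy) * sy / a) ** 2 + ((xx - cx) * sx / b) ** 2) <= 1.0
    mask = np.zeros(vol.shape, dtype=bool)
    mask[z0:z1] = inplane
    return mask


def _slice_span(cfg: ROIConfig, spacing_z: float) -> int:
    return max(1, int(math.floor(cfg.slice_span_mm / spacing_z)))


def find_vertebral_bodies(vol: CTVolume, config: ROIConfig | None = None):
    """Detect vertebral bodies as z-runs of bone area in the spine corridor.

    Returns a list of dicts (cranial to caudal) with keys ``slices``,
    ``center_voxel`` and ``full`` (False when the run touches the top or
    bottom of the scan and may be only partially imaged).
    """
    cfg = config or ROIConfig()
    sz, sy, sx = vol.spacing_mm
    bone = vol.voxels > cfg.bone_threshold_hu
    if not bone.any():
        raise NoSpineFoundError("no spine found: no bone-level voxels")
    xs = np.nonzero(bone)[2]
    x_mid = float(np.median(xs))
    nx = vol.shape[2]
    cols = np.arange(nx, dtype=float)
    corridor_cols = np.abs(cols - x_mid) * sx <= cfg.corridor_halfwidth_mm
    corridor_bone = bone & corridor_cols[None, None, :]
    area_mm2 = corridor_bone.sum(axis=(1, 2)) * sy * sx
    has_body = area_mm2 >= cfg.min_bone_area_mm2
    if not has_body.any():
        raise NoSpineFoundError("no spine found: bone area below minimum")

    # contiguous runs of body-bearing slices = vertebral bodies
    runs: list[list[int]] = []
    run: list[int] = []
    for z in range(vol.shape[0]):
        if has_body[z]:
            run.append(z)
        elif run:
            runs.append(run)
            run = []
    if run:
        runs.append(run)

    bodies = []
    nz = vol.shape[0]
    for r in runs:
        zmid = int(np.median(r))
        sub = corridor_bone[r[0]:r[-1] + 1]
        com = ndimage.center_of_mass(sub)
        bodies.append({
            "slices": list(r),
            "center_voxel": (zmid, int(round(com[1])), int(round(com[2]))),
            "full": r[0] > 0 and r[-1] < nz - 1,
        })
    # slice index increases toward the head: cranial-most body first
    bodies.sort(key=lambda b: -b["slices"][0])
    return bodies


def locate_vertebral_level(vol: CTVolume, level: str = "T12",
                           config: ROIConfig | None = None,
                           top_level: str | None = None) -> tuple[int, int, int]:
    """Return the mid-body voxel of the requested vertebral level.

    Bodies are counted caudally from the most cranial fully-imaged body,
    whose label is ``top_level`` (config default T12, matching a chest
    scan whose last complete body is T12). Raises when the requested
    level lies outside the imaged range — the situation that excluded
    patients whose scans stopped at T11.
    """
    cfg = config or ROIConfig()
    top = top_level or cfg.top_level
    if level not in VERTEBRAL_LEVELS or top not in VERTEBRAL_LEVELS:
        raise LevelNotInFOVError(f"unknown vertebral label: {level!r}")
    bodies = find_vertebral_bodies(vol, cfg)
    full = [b for b in bodies if b["full"]] or bodies
    index = VERTEBRAL_LEVELS.index(level) - VERTEBRAL_LEVELS.index(top)
    if index < 0 or index >= len(full):
        raise LevelNotInFOVError(
            f"level not in field of view: {level} "
            f"(scan covers {len(full)} bodies from {top})")
    return full[index]["center_voxel"]


def place_trabecular_roi(vol: CTVolume, center_voxel: tuple[int, int, int],
                         config: ROIConfig | None = None) -> ROISpec:
    """Largest safe circular ROI in the trabecular core.

    The radius is grown from the body center and then pulled back so no
    ROI voxel comes within ``margin_mm`` of cortical-level HU, keeping
    the dense shell and its partial-volume skirt out of the ROI.
    """
    cfg = config or ROIConfig()
    sz, sy, sx = vol.spacing_mm
    nz = vol.shape[0]
    cz, cy, cx = center_voxel
    span = _slice_span(cfg, sz)
    z0 = max(0, cz - span // 2)
    z1 = min(nz, z0 + span)
    span = z1 - z0

    r_mm = cfg.max_trabecular_radius_mm
    for z in range(z0, z1):
        cortical = vol.voxels[z] > cfg.cortical_threshold_hu
        if cortical.any():
            dist = ndimage.distance_transform_edt(~cortical, sampling=(sy, sx))
            r_mm = min(r_mm, float(dist[cy, cx]) - cfg.margin_mm)
    if r_mm <= 0:
        raise DegenerateROIError("trabecular ROI degenerate: margin exceeds body")
    roi = ROISpec(label="trabecular", center_voxel=(cz, cy, cx),
                  semi_axes_mm=(r_mm, r_mm), slice_span=span)
    if roi_mask(vol, roi).sum() < cfg.min_roi_voxels:
        raise DegenerateROIError("trabecular ROI degenerate: too few voxels")
    return roi


def _largest_component(mask: np.ndarray, spacing_yx, min_area_mm2: float):
    labels, n = ndimage.label(mask)
    if n == 0:
        return None
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, range(1, n + 1))
    best = int(np.argmax(sizes)) + 1      # ties: first label (deterministic)
    if sizes[best - 1] * spacing_yx[0] * spacing_yx[1] < min_area_mm2:
        return None
    return labels == best


def _inscribed_ellipse(component: np.ndarray, spacing_yx, scale: float):
    """Scaled largest inscribed circle of a 2-D component (center, radius mm)."""
    dist = ndimage.distance_transform_edt(component, sampling=spacing_yx)
    r = float(dist.max())
    if r <= 0:
        return None
    cy, cx = np.unravel_index(int(np.argmax(dist)), dist.shape)
    return (int(cy), int(cx)), r * scale


def place_tissue_rois(vol: CTVolume, center_voxel: tuple[int, int, int],
                      config: ROIConfig | None = None):
    """Place the calibration-tissue ROIs at the vertebral level.

    Muscle: HU-window candidates restricted to two paraspinal regions
    (within the lateral corridor, posterior to the vertebral centroid),
    opened to remove noise speckle and closed to suppress pinholes;
    the largest component per side receives a scaled inscribed ellipse.
    Fat: same treatment on the fat window over the subcutaneous band.

    Returns ``(fat, muscle_left, muscle_right)`` ROISpecs.
    """
    cfg = config or ROIConfig()
    sz, sy, sx = vol.spacing_mm
    cz, cy, cx = center_voxel
    img = vol.voxels[cz]
    ny, nx = img.shape
    yy, xx = np.indices((ny, nx))
    struct = np.ones((3, 3), dtype=bool)
    span = _slice_span(cfg, sz)

    def clean(mask):
        m = ndimage.binary_opening(mask, structure=struct)
        return ndimage.binary_closing(m, structure=struct)

    # keep tissue candidates clear of bone (vertebral trabecular HU can
    # fall inside the muscle window at low densities)
    bone = img > cfg.bone_threshold_hu
    if bone.any():
        away_from_bone = ndimage.distance_transform_edt(
            ~bone, sampling=(sy, sx)) > cfg.tissue_bone_margin_mm
    else:
        away_from_bone = np.ones_like(bone)

    lo, hi = cfg.muscle_window_hu
    muscle = clean((img >= lo) & (img <= hi) & away_from_bone
                   & (np.abs(xx - cx) * sx <= cfg.muscle_lateral_max_mm)
                   & (yy > cy))

    rois = {}
    for side, side_mask in (("muscle_right", xx < cx), ("muscle_left", xx > cx)):
        comp = _largest_component(muscle & side_mask, (sy, sx),
                                  cfg.min_tissue_area_mm2)
        if comp is None:
            raise TissueROINotFoundError(f"tissue ROI not found: {side}")
        fit = _inscribed_ellipse(comp, (sy, sx), cfg.inscribed_ellipse_scale)
        if fit is None:
            raise TissueROINotFoundError(f"tissue ROI not found: {side}")
        (my, mx), r = fit
        rois[side] = ROISpec(label=side, center_voxel=(cz, my, mx),
                             semi_axes_mm=(r, r), slice_span=span)

    lo, hi = cfg.fat_window_hu
    fat_comp = _largest_component(clean((img >= lo) & (img <= hi)
                                        & away_from_bone),
                                  (sy, sx), cfg.min_tissue_area_mm2)
    if fat_comp is None:
        raise TissueROINotFoundError("tissue ROI not found: fat")
    fit = _inscribed_ellipse(fat_comp, (sy, sx), cfg.inscribed_ellipse_scale)
    if fit is None:
        raise TissueROINotFoundError("tissue ROI not found: fat")
    (fy, fx), r = fit
    fat = ROISpec(label="fat", center_voxel=(cz, fy, fx),
                  semi_axes_mm=(r, r), slice_span=span)
    return fat, rois["muscle_left"], rois["muscle_right"]


def roi_statistics(vol: CTVolume, roi: ROISpec,
                   trim_fraction: float | None = None,
                   config: ROIConfig | None = None) -> ROIStats:
    """Mean/SD of HU over the ROI after symmetric trimming.

    ``trim_fraction`` of the lowest and highest HU values (default 0.05
    per tail) are discarded before the mean and (population) SD, which
    robustifies the tissue references against stray dense or airy
    voxels. An ROI below the configured minimum voxel count is flagged
    unreliable, not rejected.
    """
    cfg = config or ROIConfig()
    frac = cfg.trim_fraction if trim_fraction is None else trim_fraction
    values = vol.voxels[roi_mask(vol, roi)]
    n = values.size
    if n == 0:
        raise EmptyROIError(f"empty ROI: {roi.label}")
    k = int(math.floor(frac * n))
    trimmed = k > 0
    if 2 * k >= n:
        k = 0
        trimmed = False
    values = np.sort(values)
    core = values[k:n - k] if k else values
    return ROIStats(label=roi.label,
                    mean_hu=float(np.mean(core)),
                    sd_hu=float(np.std(core)),
                    n_voxels=int(n),
                    trimmed=trimmed,
                    reliable=n >= cfg.min_roi_voxels)
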