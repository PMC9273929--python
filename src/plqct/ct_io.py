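"""CT volume and cohort-table input/output.

Volumes are carried as :class:`CTVolume`: a 3-D Hounsfield-unit array in
(slice, row, col) order with (z, y, x) spacing in mm. The fixed
coordinate convention — slice index increasing toward the head, row
increasing anterior to posterior, column increasing patient-right to
patient-left — is shared by the phantom generator and the ROI code.

DICOM axial series are read-only input (raw pixel values are rescaled to
HU exactly once via the stored slope/intercept); NIfTI-1 is the internal
interchange format. Oblique acquisitions are rejected rather than
resampled so the geometry stays exact for densitometry.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
import nibabel as nib
import numpy as np
import pandas as pd

from .errors import (
    AmbiguousInputError,
    CohortSchemaError,
    InputError,
    IrregularGeometryError,
    WrongModalityError,
)


@dataclass
class DeviceMeta:
    """Acquisition device description (scanner model and HU rescale)."""

    manufacturer_model: str = "synthetic:unknown"
    kVp: float = 120.0
    mA: float = 250.0
    slice_thickness_mm: float = 3.0
    rescale_slope: float = 1.0
    rescale_intercept: float = 0.0

    def __post_init__(self):
        if self.kVp <= 0:
            raise InputError("kVp must be positive")
        if self.slice_thickness_mm <= 0:
            raise InputError("slice thickness must be positive")


@dataclass
class CTVolume:
    """A calibrated-HU voxel grid with geometry and device metadata.

    ``voxels`` is indexed (slice, row, col); ``spacing_mm`` and
    ``origin_mm`` are (z, y, x). ``hu_normalized`` records that the
    rescale slope/intercept has already been applied — it is applied
    exactly once, on load.
    """

    voxels: np.ndarray
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    device: DeviceMeta = field(default_factory=DeviceMeta)
    patient_id: str = ""
    hu_normalized: bool = True

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3 or min(self.voxels.shape) < 1:
            raise InputError("voxel array must be non-empty and 3-D")
        if any(s <= 0 for s in self.spacing_mm):
            raise InputError("all spacing components must be positive")
        if not np.all(np.isfinite(self.voxels)):
            raise InputError("HU values must be finite")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        self.origin_mm = tuple(float(s) for s in self.origin_mm)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape


def save_volume(vol: CTVolume, path: str | Path, format: str = "nifti") -> None:
    """Write a volume as NIfTI-1 plus a JSON metadata sidecar.

    The sidecar (``<path>.meta.json``) carries device metadata and the
    patient id, which NIfTI headers cannot hold. ``load_volume`` on the
    written pair reproduces voxels, spacing and origin exactly.
    """
    if format != "nifti":
        raise InputError(f"unsupported output format: {format}")
    path = Path(path)
    sz, sy, sx = vol.spacing_mm
    oz, oy, ox = vol.origin_mm
    affine = np.diag([sx, sy, sz, 1.0])
    affine[:3, 3] = (ox, oy, oz)
    # NIfTI stores (i,j,k) = (x,y,z); our arrays are (z,y,x)
    data = np.ascontiguousarray(np.transpose(vol.voxels, (2, 1, 0)))
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms((sx, sy, sz))
    tmp = path.with_name(f".tmp-{path.name}")   # same suffix for format sniffing
    try:
        nib.save(img, str(tmp))
    except Exception as exc:
        tmp.unlink(missing_ok=True)
        raise InputError(f"cannot write volume: {exc}") from exc
    tmp.replace(path)
    meta = {
        "patient_id": vol.patient_id,
        "hu_normalized": vol.hu_normalized,
        # NIfTI-1 headers hold geometry in float32; keep full precision here
        "spacing_mm": list(vol.spacing_mm),
        "origin_mm": list(vol.origin_mm),
        "device": {
            "manufacturer_model": vol.device.manufacturer_model,
            "kVp": vol.device.kVp,
            "mA": vol.device.mA,
            "slice_thickness_mm": vol.device.slice_thickness_mm,
            "rescale_slope": vol.device.rescale_slope,
            "rescale_intercept": vol.device.rescale_intercept,
        },
    }
    sidecar = path.with_name(path.name + ".meta.json")
    sidecar.write_text(json.dumps(meta, indent=1))


def load_volume(path: str | Path, format: str | None = None) -> CTVolume:
    """Load a CT volume from a NIfTI file or an axial DICOM series directory.

    Pixel data are normalized to HU on load (DICOM rescale applied
    exactly once); slices are sorted by physical z position.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such path: {path}")
    if format is None:
        format = "dicom_dir" if path.is_dir() else "nifti"
    if format == "nifti":
        return _load_nifti(path)
    if format == "dicom_dir":
        return _load_dicom_dir(path)
    raise InputError(f"unknown format: {format}")


def _load_nifti(path: Path) -> CTVolume:
    try:
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
    except Exception as exc:
        raise InputError(f"unreadable NIfTI {path.name}: {exc}") from exc
    if data.ndim != 3:
        raise InputError("NIfTI volume must be 3-D")
    aff = img.affine
    rot = aff[:3, :3]
    if np.any(np.abs(rot - np.diag(np.diag(rot))) > 1e-3 * np.abs(np.diag(rot)).max()):
        raise IrregularGeometryError("oblique NIfTI volumes are not supported")
    sx, sy, sz = (float(z) for z in img.header.get_zooms()[:3])
    ox, oy, oz = (float(v) for v in aff[:3, 3])
    voxels = np.transpose(data, (2, 1, 0))
    meta = DeviceMeta()
    patient_id = ""
    spacing = (sz, sy, sx)
    origin = (oz, oy, ox)
    sidecar = path.with_name(path.name + ".meta.json")
    if sidecar.exists():
        doc = json.loads(sidecar.read_text())
        meta = DeviceMeta(**doc.get("device", {}))
        patient_id = doc.get("patient_id", "")
        if "spacing_mm" in doc:
            spacing = tuple(doc["spacing_mm"])
        if "origin_mm" in doc:
            origin = tuple(doc["origin_mm"])
    return CTVolume(voxels=voxels, spacing_mm=spacing, origin_mm=origin,
                    device=meta, patient_id=patient_id, hu_normalized=True)


def _load_dicom_dir(path: Path) -> CTVolume:
    import pydicom

    files = sorted(p for p in path.iterdir() if p.is_file()
                   and not p.name.startswith("."))
    datasets = []
    for p in files:
        try:
            ds = pydicom.dcmread(str(p))
        except Exception:
            continue
        if hasattr(ds, "PixelData"):
            datasets.append(ds)
    if not datasets:
        raise AmbiguousInputError("no DICOM images found in directory")
    series = {getattr(ds, "SeriesInstanceUID", "?") for ds in datasets}
    if len(series) != 1:
        raise AmbiguousInputError(
            f"directory holds {len(series)} series; expected exactly one")
    modality = getattr(datasets[0], "Modality", "")
    if modality != "CT":
        raise WrongModalityError(f"modality {modality!r}, expected CT")
    iop = [float(v) for v in getattr(datasets[0], "ImageOrientationPatient",
                                     [1, 0, 0, 0, 1, 0])]
    if np.max(np.abs(np.array(iop) - np.array([1, 0, 0, 0, 1, 0]))) > 1e-3:
        raise IrregularGeometryError("oblique DICOM series are not supported")

    def zpos(ds):
        return float(ds.ImagePositionPatient[2])

    datasets.sort(key=zpos)
    zs = np.array([zpos(ds) for ds in datasets])
    if len(zs) > 1:
        dz = np.diff(zs)
        if np.any(dz <= 0):
            raise IrregularGeometryError("duplicate or non-monotone slice positions")
        if (dz.max() - dz.min()) > 0.1 * np.median(dz):
            raise IrregularGeometryError("inconsistent slice spacing beyond 10%")
        spacing_z = float(np.median(dz))
    else:
        spacing_z = float(getattr(datasets[0], "SliceThickness", 1.0))
    ref = datasets[0]
    py, px = (float(v) for v in ref.PixelSpacing)  # (row, col) = (y, x)
    slope = float(getattr(ref, "RescaleSlope", 1.0))
    intercept = float(getattr(ref, "RescaleIntercept", 0.0))
    slices = [ds.pixel_array.astype(np.float64) * slope + intercept
              for ds in datasets]
    voxels = np.stack(slices, axis=0)
    device = DeviceMeta(
        manufacturer_model=str(getattr(ref, "ManufacturerModelName", "unknown")),
        kVp=float(getattr(ref, "KVP", 120.0)),
        mA=float(getattr(ref, "XRayTubeCurrent", 250.0)),
        slice_thickness_mm=float(getattr(ref, "SliceThickness", spacing_z)),
        rescale_slope=slope,
        rescale_intercept=intercept,
    )
    origin = (float(zs[0]),
              float(ref.ImagePositionPatient[1]),
              float(ref.ImagePositionPatient[0]))
    return CTVolume(voxels=voxels, spacing_mm=(spacing_z, py, px),
                    origin_mm=origin, device=device,
                    patient_id=str(getattr(ref, "PatientID", "")),
                    hu_normalized=True)


# ---------------------------------------------------------------------------
# Cohort tables

#: Recognized cohort CSV columns. Flags and measurements are optional;
#: missing cells become None ("absent"), never silent zeros.
COHORT_COLUMNS = (
    "patient_id", "age", "sex", "height_cm", "weight_kg", "bmi",
    "spine_dxa_t", "fn_dxa_t", "th_dxa_t", "spine_dxa_bmd", "hip_dxa_bmd",
    "qct_vbmd", "device", "has_ldct", "has_t12", "dxa_complete",
)

_REQUIRED = ("patient_id", "age", "sex")
_NUMERIC = ("age", "height_cm", "weight_kg", "bmi", "spine_dxa_t",
            "fn_dxa_t", "th_dxa_t", "spine_dxa_bmd", "hip_dxa_bmd",
            "qct_vbmd")
_BOOL = ("has_ldct", "has_t12", "dxa_complete")


def _parse_bool(value, column: str, default: bool = True) -> bool:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return default
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    s = str(value).strip().lower()
    if s in ("true", "1", "yes", "y"):
        return True
    if s in ("false", "0", "no", "n"):
        return False
    raise CohortSchemaError(f"unparseable boolean in column {column!r}: {value!r}")


def load_cohort(path: str | Path):
    """Read a cohort CSV into a list of :class:`~plqct.evaluation.CohortRecord`.

    Unknown columns and unparseable numerics are errors; empty cells
    become explicit absent markers (None). A record whose DXA T-scores
    are incomplete is flagged ``dxa_complete=False`` (used downstream by
    the exclusion logic).
    """
    from .evaluation import CohortRecord

    df = pd.read_csv(path, dtype=str)
    unknown = [c for c in df.columns if c not in COHORT_COLUMNS]
    if unknown:
        raise CohortSchemaError(f"unknown cohort columns: {unknown}")
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise CohortSchemaError(f"missing required cohort columns: {missing}")

    records = []
    for i, row in df.iterrows():
        vals: dict[str, object] = {}
        for col in _NUMERIC:
            raw = row.get(col)
            if raw is None or (isinstance(raw, float) and math.isnan(raw)) \
                    or (isinstance(raw, str) and raw.strip() == ""):
                vals[col] = None
                continue
            try:
                vals[col] = float(raw)
            except (TypeError, ValueError):
                raise CohortSchemaError(
                    f"unparseable numeric in column {col!r}, row {i}: {raw!r}")
        sex = row["sex"]
        sex = "" if (isinstance(sex, float) and math.isnan(sex)) else str(sex).strip()
        if sex not in ("M", "F"):
            raise CohortSchemaError(f"sex must be M or F, got {sex!r} in row {i}")
        if vals["age"] is None:
            raise CohortSchemaError(f"missing age in row {i}")
        spine_t, fn_t, th_t = vals["spine_dxa_t"], vals["fn_dxa_t"], vals["th_dxa_t"]
        if "dxa_complete" in df.columns:
            dxa_complete = _parse_bool(row.get("dxa_complete"), "dxa_complete")
        else:
            dxa_complete = spine_t is not None and (fn_t is not None or th_t is not None)
        bmi = vals["bmi"]
        if bmi is None and vals["height_cm"] and vals["weight_kg"]:
            bmi = vals["weight_kg"] / (vals["height_cm"] / 100.0) ** 2
        records.append(CohortRecord(
            patient_id=str(row["patient_id"]),
            age=float(vals["age"]),
            sex=sex,
            height_cm=vals["height_cm"],
            weight_kg=vals["weight_kg"],
            bmi=bmi,
            spine_dxa_t=spine_t,
            fn_dxa_t=fn_t,
            th_dxa_t=th_t,
            spine_dxa_bmd=vals["spine_dxa_bmd"],
            hip_dxa_bmd=vals["hip_dxa_bmd"],
            qct_vbmd_mgcc=vals["qct_vbmd"],
            device=str(row["device"]) if "device" in df.columns
            and isinstance(row.get("device"), str) else "unknown",
            has_ldct=_parse_bool(row.get("has_ldct"), "has_ldct")
            if "has_ldct" in df.columns else True,
            has_t12=_parse_bool(row.get("has_t12"), "has_t12")
            if "has_t12" in df.columns else True,
            dxa_complete=dxa_complete,
        ))
    return records


def save_cohort(records, path: str | Path) -> None:
    """Write cohort records back to the documented CSV schema."""
    rows = []
    for r in records:
        rows.append({
            "patient_id": r.patient_id, "age": r.age, "sex": r.sex,
            "height_cm": r.height_cm, "weight_kg": r.weight_kg, "bmi": r.bmi,
            "spine_dxa_t": r.spine_dxa_t, "fn_dxa_t": r.fn_dxa_t,
            "th_dxa_t": r.th_dxa_t, "spine_dxa_bmd": r.spine_dxa_bmd,
            "hip_dxa_bmd": r.hip_dxa_bmd, "qct_vbmd": r.qct_vbmd_mgcc,
            "device": r.device, "has_ldct": r.has_ldct, "has_t12": r.has_t12,
            "dxa_complete": r.dxa_complete,
        })
    pd.DataFrame(rows).to_csv(path, index=False)
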