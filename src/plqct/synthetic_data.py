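"""Digital chest-CT phantoms and simulated cohorts with known ground truth.

The patient scans behind the clinical validation are not available, so
every pipeline stage is exercised on phantoms built here: an axial chest
section with air background, two lung fields, a soft-tissue thorax, a
subcutaneous fat band, two paraspinal muscle ellipses, and one or more
vertebral bodies (dense cortical shell around a trabecular core of known
equivalent density). Each scanner is a linear HU response

    HU(rho) = hu_per_density_slope * rho + hu_offset

applied consistently to fat, muscle and trabecular bone, so the internal
calibration can (and, as the tests verify, does) undo it. Additive
Gaussian voxel noise stands in for quantum noise; beam hardening and
reconstruction physics are out of scope.

The cohort generator emulates the clinical population structure: decade
age bins whose mean trabecular density declines linearly between the
observed endpoints (women 155.19 mg/cc at 30-39 down to 66.59 at 80+;
men 161.7 down to 72.2), a DXA T-score that is an affine function of
true density plus noise, and an age-increasing fraction of patients
whose DXA is inflated by osteophytes/vascular calcification — the
mechanism behind DXA false negatives.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .ct_io import CTVolume, DeviceMeta
from .errors import PLQCTError
from .evaluation import AGE_BIN_EDGES, CohortRecord
from .roi_selection import VERTEBRAL_LEVELS


@dataclass
class DeviceModel:
    """A scanner's linear HU response to equivalent density (mg/cc)."""

    name: str = "A"
    hu_per_density_slope: float = 1.0
    hu_offset: float = 0.0

    def __post_init__(self):
        if self.hu_per_density_slope <= 0:
            raise PLQCTError("device slope must be positive", stage="synthetic")

    def hu_of_density(self, rho: float) -> float:
        return self.hu_per_density_slope * rho + self.hu_offset


#: Four synthetic scanners with distinct HU responses (the study used four
#: models with different acquisition parameters; these are not those
#: machines, just four distinguishable linear responses).
SYNTHETIC_DEVICES = (
    DeviceModel("A", 1.00, 0.0),
    DeviceModel("B", 0.92, 0.0),
    DeviceModel("C", 1.08, -6.0),
    DeviceModel("D", 1.00, 5.0),
)


@dataclass
class PhantomSpec:
    """Everything needed to render one phantom reproducibly."""

    grid_shape: tuple[int, int, int] = (32, 96, 96)     # (z, y, x) voxels
    spacing_mm: tuple[float, float, float] = (3.0, 1.5, 1.5)
    true_trabecular_density: float = 130.0              # mg/cc
    device: DeviceModel = field(default_factory=DeviceModel)
    rho_fat: float = -50.0      # reference equivalent densities the
    rho_muscle: float = 40.0    # device response is anchored to
    hu_air: float = -1000.0
    hu_lung: float = -800.0
    hu_soft_tissue: float = 5.0
    hu_cortical: float = 800.0
    noise_sd_hu: float = 0.0
    seed: int = 0
    top_level: str = "T12"      # label of the most cranial body
    inplane_offset_mm: tuple[float, float] = (0.0, 0.0)  # (y, x) table shift
    # geometry (mm, in-plane coordinates relative to grid center)
    body_semi_mm: tuple[float, float] = (64.0, 65.0)
    fat_thickness_mm: float = 10.0
    vertebra_center_y_mm: float = 26.0
    vertebra_outer_radius_mm: float = 14.0
    cortical_thickness_mm: float = 2.5
    vertebra_height_mm: float = 27.0
    disc_gap_mm: float = 10.0
    muscle_center_mm: tuple[float, float] = (34.0, 28.0)  # (y, +/-x)
    muscle_semi_mm: tuple[float, float] = (8.0, 11.0)
    lung_center_mm: tuple[float, float] = (-18.0, 28.0)
    lung_semi_mm: tuple[float, float] = (20.0, 18.0)

    def __post_init__(self):
        if self.noise_sd_hu < 0:
            raise PLQCTError("noise SD must be >= 0", stage="synthetic")
        if self.fat_thickness_mm <= 0 or self.vertebra_outer_radius_mm <= \
                self.cortical_thickness_mm:
            raise PLQCTError("compartments geometrically impossible",
                             stage="synthetic")


@dataclass
class GroundTruthManifest:
    """Everything needed to score any pipeline stage without re-derivation."""

    true_density: float
    hu_trabecular: float
    device_name: str
    top_level: str
    body_labels: list[str]
    body_centers_voxel: list[tuple[int, int, int]]
    compartment_hu: dict[str, float]
    masks: dict[str, np.ndarray] = field(repr=False, default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        doc = {k: v for k, v in dataclasses.asdict(self).items()
               if k != "masks"}
        doc["body_centers_voxel"] = [list(c) for c in self.body_centers_voxel]
        Path(path).write_text(json.dumps(doc, indent=1))


def _render(spec: PhantomSpec, n_bodies: int):
    nz, ny, nx = spec.grid_shape
    sz, sy, sx = spec.spacing_mm
    oy, ox = spec.inplane_offset_mm
    dev = spec.device

    hu_fat = dev.hu_of_density(spec.rho_fat)
    hu_muscle = dev.hu_of_density(spec.rho_muscle)
    hu_trab = dev.hu_of_density(spec.true_trabecular_density)

    y = (np.arange(ny) - (ny - 1) / 2.0) * sy - oy
    x = (np.arange(nx) - (nx - 1) / 2.0) * sx - ox
    yy, xx = np.meshgrid(y, x, indexing="ij")

    def ellipse(cy, cx, a, b):
        return ((yy - cy) / a) ** 2 + ((xx - cx) / b) ** 2 <= 1.0

    by, bx = spec.body_semi_mm
    t = spec.fat_thickness_mm
    body = ellipse(0, 0, by, bx)
    inner = ellipse(0, 0, by - t, bx - t)
    fat = body & ~inner
    la, lb = spec.lung_semi_mm
    lcy, lcx = spec.lung_center_mm
    lungs = ellipse(lcy, -lcx, la, lb) | ellipse(lcy, lcx, la, lb)
    ma, mb = spec.muscle_semi_mm
    mcy, mcx = spec.muscle_center_mm
    muscle_r = ellipse(mcy, -mcx, ma, mb)   # patient-right = lower col
    muscle_l = ellipse(mcy, mcx, ma, mb)
    vy = spec.vertebra_center_y_mm
    shell_out = ellipse(vy, 0, spec.vertebra_outer_radius_mm,
                        spec.vertebra_outer_radius_mm)
    core = ellipse(vy, 0,
                   spec.vertebra_outer_radius_mm - spec.cortical_thickness_mm,
                   spec.vertebra_outer_radius_mm - spec.cortical_thickness_mm)
    shell = shell_out & ~core

    base = np.full((ny, nx), spec.hu_air)
    base[body] = spec.hu_soft_tissue
    base[fat] = hu_fat
    base[lungs] = spec.hu_lung
    base[muscle_r | muscle_l] = hu_muscle
    with_vert = base.copy()
    with_vert[shell] = spec.hu_cortical
    with_vert[core] = hu_trab

    # stack vertebral bodies along z, cranial (high z) to caudal
    h, gap = spec.vertebra_height_mm, spec.disc_gap_mm
    total = n_bodies * h + (n_bodies - 1) * gap
    z = (np.arange(nz) - (nz - 1) / 2.0) * sz
    if total > (nz - 3) * sz:
        raise PLQCTError(
            f"{n_bodies} bodies ({total:.0f} mm) overflow the grid",
            stage="synthetic")
    top = total / 2.0
    centers_mm = [top - h / 2.0 - i * (h + gap) for i in range(n_bodies)]

    vol = np.broadcast_to(base, (nz, ny, nx)).copy()
    trab_mask = np.zeros((nz, ny, nx), dtype=bool)
    cort_mask = np.zeros((nz, ny, nx), dtype=bool)
    centers_voxel = []
    for zc in centers_mm:
        sel = np.abs(z - zc) <= h / 2.0
        vol[sel] = with_vert
        trab_mask[sel] = core
        cort_mask[sel] = shell
        iz = int(np.argmin(np.abs(z - zc)))
        iy = int(np.argmin(np.abs(y - vy)))
        ix = int(np.argmin(np.abs(x - 0.0)))
        centers_voxel.append((iz, iy, ix))

    if spec.noise_sd_hu > 0:
        rng = np.random.default_rng(spec.seed)
        vol = vol + rng.normal(0.0, spec.noise_sd_hu, vol.shape)

    start = VERTEBRAL_LEVELS.index(spec.top_level)
    labels = [VERTEBRAL_LEVELS[min(start + i, len(VERTEBRAL_LEVELS) - 1)]
              for i in range(n_bodies)]

    rep = lambda m: np.broadcast_to(m, (nz, ny, nx)).copy()
    manifest = GroundTruthManifest(
        true_density=spec.true_trabecular_density,
        hu_trabecular=hu_trab,
        device_name=dev.name,
        top_level=spec.top_level,
        body_labels=labels,
        body_centers_voxel=centers_voxel,
        compartment_hu={"air": spec.hu_air, "lung": spec.hu_lung,
                        "soft_tissue": spec.hu_soft_tissue, "fat": hu_fat,
                        "muscle": hu_muscle, "cortical": spec.hu_cortical,
                        "trabecular": hu_trab},
        masks={"trabecular": trab_mask, "cortical": cort_mask,
               "fat": rep(fat), "muscle_left": rep(muscle_l),
               "muscle_right": rep(muscle_r), "lung": rep(lungs)},
    )
    meta = DeviceMeta(manufacturer_model=f"synthetic:{dev.name}",
                      slice_thickness_mm=sz)
    ct = CTVolume(voxels=vol, spacing_mm=spec.spacing_mm, device=meta,
                  patient_id=f"phantom-{spec.seed}")
    return ct, manifest


def generate_phantom_volume(spec: PhantomSpec):
    """Render a single-vertebra chest phantom. Returns (CTVolume, manifest)."""
    return _render(spec, n_bodies=1)


def generate_multi_vertebra_phantom(spec: PhantomSpec, n_bodies: int):
    """Render stacked vertebral bodies separated by disc gaps."""
    if n_bodies < 1:
        raise PLQCTError("n_bodies must be >= 1", stage="synthetic")
    return _render(spec, n_bodies=n_bodies)


def simulate_repeat_scans(spec: PhantomSpec, n_repeats: int,
                          reposition_jitter_mm: float = 1.0):
    """Re-render the same subject with fresh noise and small table shifts.

    Feeds the precision (RMS-SD / CV%) computation: the phantom is
    unchanged; only noise realizations and an ROI-independent in-plane
    translation vary between repeats.
    """
    if n_repeats < 2:
        raise PLQCTError("need n_repeats >= 2", stage="synthetic")
    rng = np.random.default_rng(spec.seed)
    volumes = []
    for k in range(n_repeats):
        if reposition_jitter_mm > 0:
            off = tuple(rng.normal(0.0, reposition_jitter_mm, 2))
        else:
            off = (0.0, 0.0)
        sub = dataclasses.replace(spec, seed=spec.seed + 1 + k,
                                  inplane_offset_mm=off)
        vol, _ = generate_phantom_volume(sub)
        volumes.append(vol)
    return volumes


# ---------------------------------------------------------------------------
# Cohorts

def _interp_bin_means(start: float, end: float, under30: float) -> tuple:
    """Linear decline from the 30-39 bin to the 80+ bin; <30 set explicitly."""
    steps = np.linspace(start, end, 6)
    return (under30, *[float(v) for v in steps])


@dataclass
class CohortModel:
    """Population structure for simulated cohorts.

    Per-bin mean true vBMD declines linearly between the 30-39 and 80+
    endpoints for each sex; the <30 bin sits at the ~160 mg/cc level
    seen in young adults. The DXA linkage maps density 80 mg/cc to
    T = -2.5 and 120 mg/cc to T = -1.0 so that, noise- and
    inflation-free, the two classifications agree by construction.
    """

    n: int = 649
    female_fraction: float = 383 / 649
    age_mean: float = 57.99
    age_sd: float = 11.54
    age_range: tuple[float, float] = (20.0, 95.0)
    bin_means_f: tuple = _interp_bin_means(155.19, 66.59, 160.0)
    bin_means_m: tuple = _interp_bin_means(161.7, 72.2, 165.0)
    bin_sd: float = 25.0
    qct_noise_sd: float = 5.0          # mg/cc measurement noise
    dxa_t_per_mgcc: float = 1.5 / 40.0  # linkage slope
    dxa_anchor: tuple[float, float] = (80.0, -2.5)
    dxa_noise_t: float = 0.3
    inflation_base_p: float = 0.08      # at age 40, rising with age
    inflation_p_per_year: float = 0.005
    inflation_max_p: float = 0.4
    inflation_t_range: tuple[float, float] = (0.5, 2.5)
    p_no_ldct: float = 58 / 741
    p_no_t12: float = 4 / 741
    p_dxa_incomplete: float = 30 / 741
    seed: int = 0

    def true_t(self, vbmd: float) -> float:
        v0, t0 = self.dxa_anchor
        return t0 + self.dxa_t_per_mgcc * (vbmd - v0)

    def bin_mean(self, sex: str, age: float) -> float:
        means = self.bin_means_f if sex == "F" else self.bin_means_m
        for i, (lo, hi) in enumerate(zip(AGE_BIN_EDGES[:-1], AGE_BIN_EDGES[1:])):
            if lo <= age < hi:
                return means[i]
        raise PLQCTError(f"age {age} outside bins", stage="synthetic")


# Table-1 anthropometric structure (mean, SD) per sex
_ANTHRO = {"M": {"height": (171.80, 5.71), "weight": (76.68, 12.29)},
           "F": {"height": (159.76, 5.21), "weight": (63.74, 10.08)}}


def generate_cohort(model: CohortModel | None = None,
                    exclusion_counts: tuple[int, int, int] | None = None):
    """Draw a simulated cohort. Returns (records, ground-truth DataFrame).

    ``exclusion_counts`` forces exact disjoint numbers of records flagged
    (no LDCT, no T12, incomplete DXA) instead of per-record Bernoulli
    draws — used to reconstruct a screening flow with known counts.
    """
    m = model or CohortModel()
    rng = np.random.default_rng(m.seed)
    records, truth_rows = [], []
    devices = [d.name for d in SYNTHETIC_DEVICES]
    for i in range(m.n):
        sex = "F" if rng.random() < m.female_fraction else "M"
        age = float(np.clip(rng.normal(m.age_mean, m.age_sd), *m.age_range))
        v_true = float(rng.normal(m.bin_mean(sex, age), m.bin_sd))
        qct = v_true + (float(rng.normal(0, m.qct_noise_sd))
                        if m.qct_noise_sd > 0 else 0.0)
        t_true = m.true_t(v_true)
        p_infl = np.clip(m.inflation_base_p
                         + m.inflation_p_per_year * (age - 40.0),
                         0.0, m.inflation_max_p)
        inflated = bool(rng.random() < p_infl)
        infl_t = float(rng.uniform(*m.inflation_t_range)) if inflated else 0.0
        spine_t = t_true + infl_t + (float(rng.normal(0, m.dxa_noise_t))
                                     if m.dxa_noise_t > 0 else 0.0)
        th_t = t_true + infl_t + (float(rng.normal(0, m.dxa_noise_t))
                                  if m.dxa_noise_t > 0 else 0.0)
        fn_t = t_true + infl_t + (float(rng.normal(0, m.dxa_noise_t))
                                  if m.dxa_noise_t > 0 else 0.0)
        height = float(rng.normal(*_ANTHRO[sex]["height"]))
        weight = float(rng.normal(*_ANTHRO[sex]["weight"]))
        if exclusion_counts is None:
            no_ldct = rng.random() < m.p_no_ldct
            no_t12 = rng.random() < m.p_no_t12
            dxa_inc = rng.random() < m.p_dxa_incomplete
        else:
            no_ldct = no_t12 = dxa_inc = False
        records.append(CohortRecord(
            patient_id=f"sim-{i:05d}", age=age, sex=sex,
            height_cm=height, weight_kg=weight,
            bmi=weight / (height / 100.0) ** 2,
            spine_dxa_t=spine_t, fn_dxa_t=fn_t, th_dxa_t=th_t,
            qct_vbmd_mgcc=qct,
            device=devices[int(rng.integers(len(devices)))],
            has_ldct=not no_ldct, has_t12=not no_t12,
            dxa_complete=not dxa_inc))
        truth_rows.append({"patient_id": records[-1].patient_id,
                           "true_vbmd": v_true, "t_true": t_true,
                           "inflated": inflated, "inflation_t": infl_t})
    if exclusion_counts is not None:
        a, b, c = exclusion_counts
        if a + b + c > m.n:
            raise PLQCTError("exclusion counts exceed cohort size",
                             stage="synthetic")
        idx = rng.permutation(m.n)
        for j in idx[:a]:
            records[j].has_ldct = False
        for j in idx[a:a + b]:
            records[j].has_t12 = False
        for j in idx[a + b:a + b + c]:
            records[j].dxa_complete = False
    return records, pd.DataFrame(truth_rows)
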