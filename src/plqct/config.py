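"""Run configuration: every tunable of the pipeline in one document.

The defaults encode the measurement protocol: HU windows for tissue
candidate masks, ROI geometry and safety margins, the reference
equivalent densities used by the internal calibration, and the
diagnostic thresholds. A YAML file with the same nesting overrides any
subset; unknown keys are rejected rather than silently ignored.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigError


@dataclass
class ROIConfig:
    """Geometry and thresholds for vertebral localization and ROI placement."""

    bone_threshold_hu: float = 200.0      # marks vertebral bone for localization
    cortical_threshold_hu: float = 400.0  # cortical shell level to keep clear of
    margin_mm: float = 3.0                # trabecular ROI clearance from cortical HU
    max_trabecular_radius_mm: float = 10.0
    slice_span_mm: float = 9.0            # axial extent of ROIs, in mm
    min_roi_voxels: int = 50              # below this, stats flagged unreliable
    fat_window_hu: tuple[float, float] = (-190.0, -30.0)
    muscle_window_hu: tuple[float, float] = (10.0, 100.0)
    muscle_lateral_max_mm: float = 60.0   # paraspinal corridor half-width
    tissue_bone_margin_mm: float = 6.0    # keep tissue ROIs clear of bone
    corridor_halfwidth_mm: float = 40.0   # posterior-midline spine-search corridor
    min_bone_area_mm2: float = 50.0       # per-slice bone area to count as a body
    min_tissue_area_mm2: float = 40.0
    inscribed_ellipse_scale: float = 0.8
    trim_fraction: float = 0.05           # per-tail trim for ROI statistics
    top_level: str = "T12"                # most cranial fully-imaged vertebra


@dataclass
class CalibrationConfig:
    """Reference equivalent densities for the two-tissue internal calibration.

    The fat and muscle reference densities are expressed on the same
    mg/cc equivalent-density scale as the reported vBMD. They are
    deliberate config constants (literature-range values), not measured
    quantities, and the synthetic device models are anchored to whatever
    values are configured here.
    """

    rho_fat_mgcc: float = -50.0
    rho_muscle_mgcc: float = 40.0
    min_tissue_contrast_hu: float = 10.0


@dataclass
class ClassificationConfig:
    """Diagnostic thresholds.

    QCT thresholds follow the ACR criteria (80 / 120 mg/cc); boundary
    inclusivity is osteoporosis strictly below 80 and osteopenia on the
    closed interval [80, 120]. DXA T-score criteria follow WHO
    (osteoporosis at T <= -2.5, osteopenia at -2.5 < T <= -1.0).
    """

    qct_osteoporosis_mgcc: float = 80.0
    qct_osteopenia_upper_mgcc: float = 120.0
    dxa_osteoporosis_t: float = -2.5
    dxa_osteopenia_t: float = -1.0


@dataclass
class EvaluationConfig:
    ci_method: str = "delong"   # or "bootstrap"
    bootstrap_reps: int = 2000
    seed: int = 0


@dataclass
class RunConfig:
    roi: ROIConfig = field(default_factory=ROIConfig)
    calibration: CalibrationConfig = field(default_factory=CalibrationConfig)
    classification: ClassificationConfig = field(default_factory=ClassificationConfig)
    evaluation: EvaluationConfig = field(default_factory=EvaluationConfig)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        return cls.from_dict(doc)

    @classmethod
    def from_dict(cls, doc: dict) -> "RunConfig":
        if not isinstance(doc, dict):
            raise ConfigError("config document must be a mapping")
        cfg = cls()
        sections = {f.name: f for f in dataclasses.fields(cls)}
        for key, sub in doc.items():
            if key not in sections:
                raise ConfigError(f"unknown config section: {key!r}")
            section = getattr(cfg, key)
            names = {f.name for f in dataclasses.fields(section)}
            if not isinstance(sub, dict):
                raise ConfigError(f"config section {key!r} must be a mapping")
            for k, v in sub.items():
                if k not in names:
                    raise ConfigError(f"unknown config key: {key}.{k}")
                current = getattr(section, k)
                if isinstance(current, tuple) and isinstance(v, (list, tuple)):
                    v = tuple(v)
                setattr(section, k, v)
        return cfg

    def resolved(self) -> dict:
        """Fully-resolved config as a plain dict (logged with every run)."""
        return dataclasses.asdict(self)

    def to_json(self) -> str:
        return json.dumps(self.resolved(), indent=2)
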