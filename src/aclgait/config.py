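"""Run configuration: one flat document driving generate -> sweep -> report.

All ~20 pipeline parameters live in a YAML-serializable `RunConfig` whose
defaults are the documented study conditions: the n = 7 cohort, the §-mean
gait landmarks, the generic ACL geometry, and the calibrated joint-space
offset that makes the centre-position graft taut during stance.  A single
master seed drives every source of randomness via deterministic per-subject
seed derivation.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .gait_synth import GaitLandmarks, GaitShape
from .knee_model import FrameConvention, KneeCoupling
from .ligament import LigamentSpec
from .tis_sweep import DEFAULT_MAGNITUDES_MM

__all__ = ["RunConfig", "DEFAULT_TY_OFFSET_CM"]

# Constant superoinferior joint-space offset (cm) of the generic coupling
# table.  Calibrated once so that the centre-position graft is taut through
# stance (peak strain ~ a few percent above slack, peak force in the
# 100-200 N regime) and slack through swing; see docs/methods.md.
DEFAULT_TY_OFFSET_CM = 0.80


@dataclass
class RunConfig:
    # gait generator
    landmarks: GaitLandmarks = field(default_factory=GaitLandmarks)
    shape: GaitShape = field(default_factory=GaitShape)
    n_subjects: int = 7
    height_mean_m: float = 1.63
    height_sd_m: float = 0.098  # printed cohort SD of 0.98 m read as 0.098 m
    mass_mean_kg: float = 72.04
    mass_sd_kg: float = 15.22
    generic_height_m: float = 1.70
    variability: float = 1.0
    master_seed: int = 0
    n_points: int = 101
    # ligament + knee geometry
    ligament: LigamentSpec = field(default_factory=LigamentSpec)
    coupling_flexion_deg: tuple = (0.0, 20.0, 40.0, 60.0, 80.0, 100.0, 120.0)
    coupling_tx_cm: tuple = (0.0, -0.08, -0.16, -0.24, -0.31, -0.37, -0.42)
    coupling_ty_cm: tuple = (DEFAULT_TY_OFFSET_CM,) * 7
    origin_offset_cm: tuple = (0.0, -40.0, 0.0)
    side: str = "right"
    # sweep + statistics
    grid_magnitudes_mm: tuple = DEFAULT_MAGNITUDES_MM
    peak_split: float = 0.30
    alpha: float = 0.05
    alpha_strong: float = 0.01
    ultimate_force_annotation_N: float = 600.0
    out_dir: str = "aclgait_out"

    # -- derived objects -------------------------------------------------
    def convention(self) -> FrameConvention:
        return FrameConvention(side=self.side)

    def coupling(self) -> KneeCoupling:
        return KneeCoupling(
            self.coupling_flexion_deg, self.coupling_tx_cm, self.coupling_ty_cm
        )

    def validate(self) -> None:
        self.landmarks.validate()
        self.convention()
        self.coupling()
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.variability < 0:
            raise ValueError("variability must be >= 0")
        if self.landmarks.stance_fraction <= self.peak_split:
            raise ValueError("stance_fraction must exceed peak_split")

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key, value in list(d.items()):
            if isinstance(value, tuple):
                d[key] = list(value)
        d["ligament"] = {
            "femoral_insertion_cm": list(self.ligament.femoral_insertion),
            "tibial_insertion_cm": list(self.ligament.tibial_insertion),
            "resting_length_cm": self.ligament.resting_length,
            "stiffness_N": self.ligament.stiffness,
            "linear_strain_limit": self.ligament.linear_strain_limit,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "landmarks" in d:
            d["landmarks"] = GaitLandmarks(**d["landmarks"])
        if "shape" in d:
            d["shape"] = GaitShape(**d["shape"])
        if "ligament" in d:
            lig = d["ligament"]
            d["ligament"] = LigamentSpec(
                femoral_insertion=tuple(lig["femoral_insertion_cm"]),
                tibial_insertion=tuple(lig["tibial_insertion_cm"]),
                resting_length=lig["resting_length_cm"],
                stiffness=lig["stiffness_N"],
                linear_strain_limit=lig["linear_strain_limit"],
            )
        for key in (
            "coupling_flexion_deg",
            "coupling_tx_cm",
            "coupling_ty_cm",
            "origin_offset_cm",
            "grid_magnitudes_mm",
        ):
            if key in d:
                d[key] = tuple(d[key])
        cfg = cls(**d)
        cfg.validate()
        return cfg

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))
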