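"""Tibial insertion-site (TIS) grid and the kinematics-to-force sweep.

A single-bundle graft's tibial tunnel rarely lands exactly on the centre of
the native footprint.  The sweep quantifies the consequence: the tibial
insertion is displaced from the centre in 2.5 mm steps (2.5/5.0/7.5 mm) in
the anterior, posterior, medial and lateral directions — 13 conditions
including the centre — while the femoral insertion stays fixed, and the
ligament force is evaluated over every subject's normalized gait cycle.
Offsets are applied to the unscaled generic footprint (a surgical placement
on the anatomy, which scales with the subject) before subject scaling.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .gait_synth import GaitKinematics, SubjectProfile
from .knee_model import (
    DEFAULT_ORIGIN_OFFSET,
    FrameConvention,
    KneeCoupling,
    KneePose,
    RigidTransform,
    batch_femur_to_tibia,
    femur_to_tibia_transform,
)
from .ligament import LigamentSpec, ligament_force, scale_ligament, strain

__all__ = [
    "TISOffset",
    "TISGrid",
    "ForceCurve",
    "SweepResult",
    "make_tis_grid",
    "simulate_force_curve",
    "run_sweep",
]

DIRECTIONS = ("center", "anterior", "posterior", "medial", "lateral")
DEFAULT_MAGNITUDES_MM = (2.5, 5.0, 7.5)


@dataclass(frozen=True)
class TISOffset:
    """One insertion-site displacement: a direction and a magnitude in mm."""

    direction: str
    magnitude_mm: float = 0.0

    def __post_init__(self) -> None:
        if self.direction not in DIRECTIONS:
            raise ValueError(f"unknown direction {self.direction!r}")
        if self.direction == "center" and self.magnitude_mm != 0.0:
            raise ValueError("center offset must have magnitude 0")
        if self.direction != "center" and self.magnitude_mm <= 0.0:
            raise ValueError("non-center offsets need a positive magnitude")

    @property
    def label(self) -> str:
        if self.direction == "center":
            return "center"
        return f"{self.direction}_{self.magnitude_mm:g}mm"

    def displacement_cm(self, convention: FrameConvention) -> np.ndarray:
        """Displacement vector in the tibia frame (cm); y is never moved."""
        d = self.magnitude_mm / 10.0
        if self.direction == "center":
            return np.zeros(3)
        if self.direction == "anterior":
            return np.array([d, 0.0, 0.0])
        if self.direction == "posterior":
            return np.array([-d, 0.0, 0.0])
        if self.direction == "medial":
            return np.array([0.0, 0.0, convention.medial_sign * d])
        return np.array([0.0, 0.0, -convention.medial_sign * d])  # lateral


@dataclass(frozen=True)
class TISGrid:
    """Ordered insertion-site conditions with resolved tibial coordinates."""

    offsets: tuple[TISOffset, ...]
    coordinates: tuple[tuple[float, float, float], ...]  # tibia frame, cm

    def __post_init__(self) -> None:
        if len(self.offsets) != len(self.coordinates):
            raise ValueError("offsets and coordinates must align")
        labels = [o.label for o in self.offsets]
        if len(set(labels)) != len(labels):
            raise ValueError("grid offsets must be unique")

    def __len__(self) -> int:
        return len(self.offsets)

    def __iter__(self):
        return iter(zip(self.offsets, self.coordinates))


def make_tis_grid(
    center,
    convention: FrameConvention = FrameConvention(),
    magnitudes_mm=DEFAULT_MAGNITUDES_MM,
) -> TISGrid:
    """Build the insertion-site grid around ``center`` (tibia frame, cm).

    Default magnitudes (2.5, 5.0, 7.5 mm) in all four directions give the
    13-condition grid (centre + 4 x 3).  The femoral insertion is never part
    of the grid — it is held fixed throughout.
    """
    center = np.asarray(center, dtype=float)
    offsets = [TISOffset("center")]
    for direction in ("anterior", "posterior", "medial", "lateral"):
        for mag in magnitudes_mm:
            offsets.append(TISOffset(direction, float(mag)))
    coords = tuple(tuple(center + o.displacement_cm(convention)) for o in offsets)
    return TISGrid(offsets=tuple(offsets), coordinates=coords)


@dataclass
class ForceCurve:
    """One subject x one TIS: ligament force (N) over the normalized cycle."""

    subject_id: str
    offset: TISOffset
    force: np.ndarray
    all_slack: bool = field(init=False)
    stance_fraction: float = 0.60

    def __post_init__(self) -> None:
        self.force = np.asarray(self.force, dtype=float)
        if np.any(self.force < 0) or not np.all(np.isfinite(self.force)):
            raise ValueError("force trace must be finite and non-negative")
        self.all_slack = not bool(np.any(self.force > 0))

    @property
    def n_points(self) -> int:
        return self.force.size

    @property
    def cycle_time(self) -> np.ndarray:
        return np.linspace(0.0, 1.0, self.n_points)


def simulate_force_curve(
    kin: GaitKinematics,
    spec: LigamentSpec,
    coupling: KneeCoupling | None = None,
    convention: FrameConvention = FrameConvention(),
    origin_offset=DEFAULT_ORIGIN_OFFSET,
) -> ForceCurve:
    """Pose -> transform -> length -> strain -> force at every cycle sample."""
    kin.validate()
    sgn = 1.0 if convention.side == "right" else -1.0
    Rt, tt = batch_femur_to_tibia(
        kin.flexion,
        sgn * kin.adduction,
        sgn * kin.internal_rotation,
        coupling=coupling,
        origin_offset=origin_offset,
    )
    fem_t = np.einsum("nij,j->ni", Rt, spec.femoral) + tt
    lengths = np.linalg.norm(fem_t - spec.tibial, axis=1)
    e = strain(lengths, spec.resting_length)
    force = ligament_force(e, spec.stiffness, spec.linear_strain_limit)
    return ForceCurve(
        subject_id=kin.subject_id,
        offset=TISOffset("center"),
        force=force,
        stance_fraction=kin.stance_fraction,
    )


@dataclass
class SweepResult:
    """All force curves of a sweep, subject-major in grid order."""

    curves: list[ForceCurve]
    manifest: dict

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.curves:
            pct = np.round(c.cycle_time * 100).astype(int)
            rows.append(
                pd.DataFrame(
                    {
                        "subject_id": c.subject_id,
                        "direction": c.offset.direction,
                        "magnitude_mm": c.offset.magnitude_mm,
                        "cycle_pct": pct,
                        "force_N": c.force,
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)

    def write(self, out_dir: str | Path) -> tuple[Path, Path]:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        csv_path = out_dir / "sweep_curves.csv"
        self.to_frame().to_csv(csv_path, index=False, float_format="%.9g")
        manifest_path = out_dir / "sweep_manifest.json"
        manifest_path.write_text(json.dumps(self.manifest, indent=2, sort_keys=True))
        return csv_path, manifest_path

    @classmethod
    def from_frame(cls, df: pd.DataFrame, stance_fraction: float = 0.60) -> "SweepResult":
        curves = []
        keys = df[["subject_id", "direction", "magnitude_mm"]].drop_duplicates()
        for _, row in keys.iterrows():
            sub = df[
                (df["subject_id"] == row["subject_id"])
                & (df["direction"] == row["direction"])
                & (df["magnitude_mm"] == row["magnitude_mm"])
            ].sort_values("cycle_pct")
            curves.append(
                ForceCurve(
                    subject_id=str(row["subject_id"]),
                    offset=TISOffset(str(row["direction"]), float(row["magnitude_mm"])),
                    force=sub["force_N"].to_numpy(),
                    stance_fraction=stance_fraction,
                )
            )
        return cls(curves=curves, manifest={})


def run_sweep(
    cohort: list[tuple[SubjectProfile, GaitKinematics]],
    grid: TISGrid,
    spec: LigamentSpec = LigamentSpec(),
    coupling: KneeCoupling | None = None,
    convention: FrameConvention = FrameConvention(),
    origin_offset=DEFAULT_ORIGIN_OFFSET,
) -> SweepResult:
    """Run the full cohort x grid cross-product of force simulations.

    Per subject, each grid condition replaces the (unscaled) tibial
    insertion, the geometry is then scaled to the subject (insertions,
    frame offset and coupling translations all by ``uniform_scale``;
    stiffness untouched), and the force curve is simulated.  Any failing
    cell aborts the sweep with the (subject, offset) cell identified.
    """
    if not cohort:
        raise ValueError("cohort is empty")
    if len(grid) == 0:
        raise ValueError("TIS grid is empty")
    coupling = coupling or KneeCoupling.generic()
    origin_offset = np.asarray(origin_offset, dtype=float)
    default_pose_T = femur_to_tibia_transform(
        KneePose(0.0, 0.0, 0.0), coupling, origin_offset
    )
    curves: list[ForceCurve] = []
    provenance = []
    for profile, kin in cohort:
        s = profile.uniform_scale
        coupling_s = KneeCoupling(
            coupling.flexion_deg, s * coupling.tx_cm, s * coupling.ty_cm, kind=coupling.kind
        )
        for offset, coords in grid:
            try:
                spec_o = replace(spec, tibial_insertion=tuple(coords))
                spec_s = scale_ligament(spec_o, s, default_pose_T)
                curve = simulate_force_curve(
                    kin, spec_s, coupling_s, convention, s * origin_offset
                )
            except Exception as exc:
                raise RuntimeError(
                    f"sweep cell failed: subject={profile.subject_id} "
                    f"offset={offset.label}: {exc}"
                ) from exc
            curve.subject_id = profile.subject_id
            curve.offset = offset
            curves.append(curve)
            provenance.append(
                {
                    "subject_id": profile.subject_id,
                    "offset": offset.label,
                    "rng_seed": profile.rng_seed,
                    "uniform_scale": s,
                    "resting_length_cm": spec_s.resting_length,
                }
            )
    manifest = {
        "n_subjects": len(cohort),
        "n_conditions": len(grid),
        "side": convention.side,
        "grid": [o.label for o, _ in grid],
        "cells": provenance,
    }
    return SweepResult(curves=curves, manifest=manifest)
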