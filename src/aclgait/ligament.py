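"""Passive ACL element: straight-line path, strain, and the nonlinear force law.

The ligament is modelled as a single passive elastic strand on a straight
line between its femoral insertion (femur frame) and tibial insertion
(tibia frame).  Its tension depends only on its length L through the strain
e = (L - L0)/L0 and the standard toe-region force law

    f(e) = 0                      e <= 0        (slack)
    f(e) = 0.25 k e^2 / e_l       0 <= e <= 2 e_l  (quadratic toe region)
    f(e) = k (e - e_l)            e >= 2 e_l    (linear region)

with stiffness k (N), linear strain limit e_l (default 0.03) and resting
length L0 (cm).  The two non-zero branches agree at e = 2 e_l (both give
k e_l), so the law is continuous and monotone.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .knee_model import RigidTransform

__all__ = [
    "LigamentSpec",
    "LigamentState",
    "ligament_length",
    "strain",
    "ligament_force",
    "scale_ligament",
]


@dataclass(frozen=True)
class LigamentSpec:
    """Geometry and material parameters of the single-strand ACL element.

    Defaults are the generic-model ACL: femoral insertion on the lateral
    condyle wall near the knee centre (femur frame, cm), tibial insertion on
    the anteromedial tibial plateau (tibia frame, cm), resting length 2.8 cm
    and stiffness 3100 N.
    """

    femoral_insertion: tuple[float, float, float] = (-1.1, -40.5, 0.7)
    tibial_insertion: tuple[float, float, float] = (1.2, -3.2, -0.1)
    resting_length: float = 2.8  # cm
    stiffness: float = 3100.0  # N
    linear_strain_limit: float = 0.03

    def __post_init__(self) -> None:
        if self.resting_length <= 0:
            raise ValueError("resting_length must be > 0")
        if self.stiffness <= 0:
            raise ValueError("stiffness must be > 0")
        if not 0.0 < self.linear_strain_limit < 1.0:
            raise ValueError("linear_strain_limit must lie in (0, 1)")

    @property
    def femoral(self) -> np.ndarray:
        return np.asarray(self.femoral_insertion, dtype=float)

    @property
    def tibial(self) -> np.ndarray:
        return np.asarray(self.tibial_insertion, dtype=float)


@dataclass(frozen=True)
class LigamentState:
    """Length (cm), strain and force (N) of the element at one pose."""

    length: float
    strain: float
    force: float

    @classmethod
    def from_length(cls, spec: LigamentSpec, length: float) -> "LigamentState":
        e = strain(length, spec.resting_length)
        f = float(ligament_force(e, spec.stiffness, spec.linear_strain_limit))
        return cls(length=length, strain=e, force=f)


def ligament_length(spec: LigamentSpec, transform: RigidTransform) -> float:
    """Straight-line path length (cm): femoral insertion mapped into the
    tibia frame, Euclidean distance to the tibial insertion."""
    return float(np.linalg.norm(transform.apply(spec.femoral) - spec.tibial))


def strain(length, resting_length):
    """Engineering strain e = (L - L0) / L0; negative when slack."""
    if np.any(np.asarray(resting_length) <= 0):
        raise ValueError("resting_length must be > 0")
    return (np.asarray(length, dtype=float) - resting_length) / resting_length


def ligament_force(e, k: float, e_l: float):
    """Tension (N) from strain via the three-branch toe-region law.

    Vectorized over ``e``; scalars in give scalars out.
    """
    if k <= 0 or e_l <= 0:
        raise ValueError("stiffness and linear strain limit must be positive")
    e = np.asarray(e, dtype=float)
    toe = 0.25 * k * e**2 / e_l
    linear = k * (e - e_l)
    out = np.where(e <= 0, 0.0, np.where(e <= 2 * e_l, toe, linear))
    return out if out.ndim else float(out)


def scale_ligament(
    spec: LigamentSpec, uniform_scale: float, default_pose_transform: RigidTransform
) -> LigamentSpec:
    """Scale the ligament geometry to a subject; stiffness is not scaled.

    Insertion coordinates are multiplied by ``uniform_scale`` and the
    resting length by the ratio of the default-pose path lengths after and
    before scaling (bone geometry — here the frame origin offset inside the
    transform's translation — scales with the subject too).  For a uniform
    scale the ratio equals the scale factor, so the default-pose strain is
    preserved exactly.
    """
    if uniform_scale <= 0:
        raise ValueError("uniform_scale must be > 0")
    before = ligament_length(spec, default_pose_transform)
    if before == 0.0:
        raise ValueError("default-pose path length is zero; cannot scale resting length")
    scaled = replace(
        spec,
        femoral_insertion=tuple(uniform_scale * spec.femoral),
        tibial_insertion=tuple(uniform_scale * spec.tibial),
    )
    scaled_transform = RigidTransform(
        rotation=default_pose_transform.rotation,
        translation=uniform_scale * default_pose_transform.translation,
    )
    after = ligament_length(scaled, scaled_transform)
    return replace(scaled, resting_length=spec.resting_length * after / before)
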