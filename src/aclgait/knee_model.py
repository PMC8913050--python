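"""Knee frames, rotation convention and flexion-coupled tibiofemoral translation.

Both the femur frame (origin at the femoral head) and the tibia frame
(origin at the epicondylar midpoint, i.e. the knee centre, at the default
pose) use x anterior, y proximal, z lateral.  The three knee angles are
independent rotations applied as successive body-fixed rotations in the
order flexion (about z, flexion positive), adduction (about x), internal
rotation (about y); the anteroposterior and superoinferior positions of the
tibia frame relative to the femur are coupled to the flexion angle through
small interpolated knot tables, as in generic musculoskeletal knee models.

Angle sign convention: rotations are about the +x/+y/+z frame axes, which
for a *right* knee means positive adduction tilts the distal tibia medially
and positive internal rotation turns the tibial tuberosity medially.  Left
knees are handled upstream by mirroring the angle signs and the z
coordinates of any attached geometry (see `mirror_pose`), which leaves all
distances unchanged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

logger = logging.getLogger(__name__)

__all__ = [
    "FrameConvention",
    "KneePose",
    "KneeCoupling",
    "RigidTransform",
    "DEFAULT_ORIGIN_OFFSET",
    "femur_to_tibia_transform",
    "batch_femur_to_tibia",
    "mirror_pose",
]

# Femoral-head -> knee-centre offset at the default pose, femur frame, cm.
DEFAULT_ORIGIN_OFFSET = (0.0, -40.0, 0.0)


@dataclass(frozen=True)
class FrameConvention:
    """Right-handed body frame (x anterior, y proximal, z lateral) plus side."""

    side: str = "right"

    def __post_init__(self) -> None:
        if self.side not in ("right", "left"):
            raise ValueError(f"side must be 'right' or 'left', got {self.side!r}")

    @property
    def medial_sign(self) -> float:
        """Multiplier mapping the 'medial' direction onto the +z axis."""
        return -1.0 if self.side == "right" else 1.0


@dataclass(frozen=True)
class KneePose:
    """Knee angles in degrees (anatomical sense: flexion/adduction/internal +)."""

    flexion: float
    adduction: float
    internal_rotation: float

    def validate(self) -> None:
        if not all(np.isfinite([self.flexion, self.adduction, self.internal_rotation])):
            raise ValueError("pose angles must be finite")


class KneeCoupling:
    """Flexion-coupled tibiofemoral translations, piecewise interpolation knots.

    ``tx`` is the anteroposterior and ``ty`` the superoinferior position (cm)
    of the tibia-frame origin relative to its default-pose location, each a
    function of knee flexion (degrees).  Values outside the knot domain are
    clamped (a bounded anatomical function should not be extrapolated); each
    clamp is logged.
    """

    def __init__(self, flexion_deg, tx_cm, ty_cm, kind: str = "linear"):
        self.flexion_deg = np.asarray(flexion_deg, dtype=float)
        self.tx_cm = np.asarray(tx_cm, dtype=float)
        self.ty_cm = np.asarray(ty_cm, dtype=float)
        self.kind = kind
        if self.flexion_deg.size == 0:
            raise ValueError("coupling knot table is empty")
        if not (self.flexion_deg.size == self.tx_cm.size == self.ty_cm.size):
            raise ValueError("coupling knot arrays must have equal length")
        if np.any(np.diff(self.flexion_deg) <= 0):
            raise ValueError("coupling flexion knots must be strictly increasing")
        if kind not in ("linear", "cubic"):
            raise ValueError("interpolation kind must be 'linear' or 'cubic'")
        if kind == "cubic":
            from scipy.interpolate import PchipInterpolator

            self._tx = PchipInterpolator(self.flexion_deg, self.tx_cm)
            self._ty = PchipInterpolator(self.flexion_deg, self.ty_cm)

    def __call__(self, flexion):
        """Return (tx, ty) in cm at the given flexion angle(s) in degrees."""
        flexion = np.asarray(flexion, dtype=float)
        lo, hi = self.flexion_deg[0], self.flexion_deg[-1]
        n_clamped = int(np.sum((flexion < lo) | (flexion > hi)))
        if n_clamped:
            logger.warning(
                "clamped %d flexion value(s) to the coupling domain [%g, %g] deg",
                n_clamped, lo, hi,
            )
        clamped = np.clip(flexion, lo, hi)
        if self.kind == "cubic":
            return self._tx(clamped), self._ty(clamped)
        return (
            np.interp(clamped, self.flexion_deg, self.tx_cm),
            np.interp(clamped, self.flexion_deg, self.ty_cm),
        )

    @classmethod
    def generic(cls, ty_offset: float = 0.80) -> "KneeCoupling":
        """Generic-knee stand-in coupling table.

        The anteroposterior excursion is mm-scale (≈ −0.4 cm at 120 deg
        flexion), matching published generic knee models; the prior model
        this geometry descends from does not print its coupling splines.
        ``ty_offset`` is a constant superoinferior joint-space offset (cm),
        the single calibration knob that sets how taut the centre-position
        ligament is in stance (see the default run configuration).
        """
        flex = [0.0, 20.0, 40.0, 60.0, 80.0, 100.0, 120.0]
        tx = [0.0, -0.08, -0.16, -0.24, -0.31, -0.37, -0.42]
        ty = [ty_offset] * len(flex)
        return cls(flex, tx, ty)


@dataclass
class RigidTransform:
    """Rigid map taking femur-frame point coordinates into the tibia frame."""

    rotation: np.ndarray  # 3x3, orthonormal, det +1
    translation: np.ndarray  # cm

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        if self.rotation.shape != (3, 3) or self.translation.shape != (3,):
            raise ValueError("rotation must be 3x3 and translation length 3")
        err = np.max(np.abs(self.rotation @ self.rotation.T - np.eye(3)))
        if err > 1e-9 or abs(np.linalg.det(self.rotation) - 1.0) > 1e-9:
            raise ValueError("rotation must be orthonormal with determinant +1")

    def apply(self, points: np.ndarray) -> np.ndarray:
        points = np.asarray(points, dtype=float)
        return points @ self.rotation.T + self.translation


def evaluate_coupling(coupling: KneeCoupling, flexion):
    """Functional alias for ``coupling(flexion)`` -> (tx, ty) in cm."""
    return coupling(flexion)


def mirror_pose(pose: KneePose, convention: FrameConvention) -> KneePose:
    """Map an anatomical pose onto frame-axis angles for the given side.

    For a right knee the anatomical and frame-axis senses coincide; for a
    left knee adduction and internal rotation flip sign (the mirrored frame
    keeps z lateral on the opposite side of the body).
    """
    if convention.side == "right":
        return pose
    return KneePose(pose.flexion, -pose.adduction, -pose.internal_rotation)


def _rotation_matrix(pose: KneePose) -> np.ndarray:
    # body-fixed z (flexion, negative about +z so flexion swings the tibia
    # posteriorly), then x (adduction), then y (internal rotation)
    return Rotation.from_euler(
        "ZXY",
        [-pose.flexion, pose.adduction, pose.internal_rotation],
        degrees=True,
    ).as_matrix()


def femur_to_tibia_transform(
    pose: KneePose,
    coupling: KneeCoupling | None = None,
    origin_offset=DEFAULT_ORIGIN_OFFSET,
) -> RigidTransform:
    """Rigid transform taking femur-frame coordinates into the tibia frame.

    The tibia frame sits at ``origin_offset`` (femur frame, cm) at the
    default pose, displaced by the flexion-coupled translations, and rotated
    by the knee angles.  A point ``p_f`` in femur coordinates maps to
    ``R.T @ (p_f - origin)`` in tibia coordinates.
    """
    pose.validate()
    R = _rotation_matrix(pose)
    origin = np.asarray(origin_offset, dtype=float).copy()
    if coupling is not None:
        tx, ty = coupling(pose.flexion)
        origin = origin + np.array([float(tx), float(ty), 0.0])
    return RigidTransform(rotation=R.T, translation=-R.T @ origin)


def batch_femur_to_tibia(
    flexion: np.ndarray,
    adduction: np.ndarray,
    internal_rotation: np.ndarray,
    coupling: KneeCoupling | None = None,
    origin_offset=DEFAULT_ORIGIN_OFFSET,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized transform chain for whole gait cycles.

    Returns ``(R_t, t_t)`` with shapes (n, 3, 3) and (n, 3) such that a
    femur-frame point ``p`` maps to ``R_t[i] @ p + t_t[i]`` at sample i.
    """
    angles = np.column_stack([-np.asarray(flexion, float),
                              np.asarray(adduction, float),
                              np.asarray(internal_rotation, float)])
    R = Rotation.from_euler("ZXY", angles, degrees=True).as_matrix()  # (n,3,3)
    origin = np.broadcast_to(np.asarray(origin_offset, float), (angles.shape[0], 3)).copy()
    if coupling is not None:
        tx, ty = coupling(flexion)
        origin[:, 0] += tx
        origin[:, 1] += ty
    Rt = np.transpose(R, (0, 2, 1))
    tt = -np.einsum("nij,nj->ni", Rt, origin)
    return Rt, tt
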