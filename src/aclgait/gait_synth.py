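"""Seeded synthetic knee-kinematics generator for a normalized gait cycle.

Real gait labs measure knee angles with marker-based motion capture and
time-normalize each stride to 101 samples (0–100% of the gait cycle).  This
module emulates that output for a cohort of subjects: each of the three knee
angles (flexion, adduction, internal rotation, all in degrees) is a
landmark-constrained shape-preserving cubic spline through a small set of
knots placed to reproduce normal post-reconstruction gait.  The landmark
values — stance/swing flexion maxima, the late-cycle adduction peak, and the
swing internal/external rotation extrema — are the calibration targets; the
remaining knots only shape the curve between them.

With ``variability = 0`` the generator returns the cohort-mean cycle and
attains every landmark exactly at a sample point.  With ``variability > 0``
knot amplitudes and phases are jittered per subject (seeded, reproducible),
mimicking inter-subject variability without claiming any particular
covariance structure of real gait.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import PchipInterpolator

__all__ = [
    "GaitLandmarks",
    "GaitShape",
    "SubjectProfile",
    "GaitKinematics",
    "LandmarkError",
    "generate_subject_kinematics",
    "generate_cohort",
]

# jitter scales per unit `variability` (fractional amplitude / cycle fraction)
_AMP_SD = 0.08
_PHASE_SD = 0.02
_MIN_KNOT_GAP = 0.01


class LandmarkError(ValueError):
    """Landmark values that make the constrained spline infeasible."""


@dataclass(frozen=True)
class GaitLandmarks:
    """Calibration targets of the synthetic gait cycle (degrees / cycle fraction).

    Defaults are the mean values observed in patients six months after
    single-bundle ACL reconstruction: stance flexion peaks at 14 deg, swing
    flexion at 64 deg, adduction peaks at 10 deg around 85% of the cycle, and
    swing internal/external rotation reach 7 deg / 12 deg.
    """

    stance_flexion_max: float = 14.0
    swing_flexion_max: float = 64.0
    adduction_peak: float = 10.0
    adduction_peak_time: float = 0.85
    swing_internal_rot_max: float = 7.0
    swing_external_rot_max: float = 12.0
    stance_fraction: float = 0.60

    def validate(self) -> None:
        for name in (
            "stance_flexion_max",
            "swing_flexion_max",
            "adduction_peak",
            "swing_internal_rot_max",
            "swing_external_rot_max",
        ):
            if getattr(self, name) < 0:
                raise LandmarkError(f"{name} must be >= 0")
        if not 0.0 < self.stance_fraction < 1.0:
            raise LandmarkError("stance_fraction must lie in (0, 1)")
        if not 0.0 <= self.adduction_peak_time <= 1.0:
            raise LandmarkError("adduction_peak_time must lie in [0, 1]")
        if self.swing_flexion_max <= self.stance_flexion_max:
            raise LandmarkError(
                "swing flexion maximum must exceed the stance maximum "
                f"({self.swing_flexion_max} <= {self.stance_flexion_max})"
            )


@dataclass(frozen=True)
class GaitShape:
    """Non-landmark knot defaults that shape the curves between landmarks.

    These are generator conventions for a normal-looking gait cycle, not
    measured quantities: heel-strike flexion ~5 deg, the stance flexion peak
    at 15% cycle, a mid-stance minimum ~3 deg at 40%, the swing flexion peak
    at 72%, and small (±~2 deg) transverse-plane excursions during stance.
    """

    heel_strike_flexion: float = 5.0
    stance_peak_time: float = 0.15
    midstance_flexion: float = 3.0
    midstance_time: float = 0.40
    preswing_rise: float = 0.60  # fraction of (stance max − mid-stance) at toe-off
    swing_peak_time: float = 0.72
    adduction_baseline_frac: float = 0.20
    adduction_mid_frac: float = 0.50
    stance_rotation_amp: float = 1.75
    external_rot_delay: float = 0.06  # cycle fraction after toe-off
    internal_rot_delay: float = 0.26


@dataclass(frozen=True)
class SubjectProfile:
    subject_id: str
    height: float  # m
    mass: float  # kg
    uniform_scale: float  # dimensionless, relative to the generic model
    rng_seed: int

    def validate(self) -> None:
        if self.height <= 0 or self.mass <= 0 or self.uniform_scale <= 0:
            raise ValueError("height, mass and uniform_scale must be positive")


@dataclass
class GaitKinematics:
    """One subject's knee angles over a normalized gait cycle (degrees)."""

    subject_id: str
    flexion: np.ndarray
    adduction: np.ndarray
    internal_rotation: np.ndarray
    stance_fraction: float = 0.60
    n_points: int = 101

    def __post_init__(self) -> None:
        self.flexion = np.asarray(self.flexion, dtype=float)
        self.adduction = np.asarray(self.adduction, dtype=float)
        self.internal_rotation = np.asarray(self.internal_rotation, dtype=float)

    @property
    def cycle_time(self) -> np.ndarray:
        """Cycle fraction of each sample, 0.0 .. 1.0."""
        return np.linspace(0.0, 1.0, self.n_points)

    def validate(self) -> None:
        for name in ("flexion", "adduction", "internal_rotation"):
            trace = getattr(self, name)
            if trace.shape != (self.n_points,):
                raise ValueError(f"{name} must have exactly {self.n_points} samples")
            if not np.all(np.isfinite(trace)):
                raise ValueError(f"{name} contains non-finite samples")
            if abs(trace[0] - trace[-1]) >= 1.0:
                raise ValueError(f"{name} does not close the cycle (>= 1 deg gap)")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "time": self.cycle_time,
                "knee_flexion": self.flexion,
                "knee_adduction": self.adduction,
                "knee_rotation": self.internal_rotation,
            }
        )


def _snap(t: float, n_points: int) -> float:
    """Snap a knot time onto the sampling grid so its value is attained exactly."""
    return round(t * (n_points - 1)) / (n_points - 1)


def _knots(landmarks: GaitLandmarks, shape: GaitShape, n_points: int):
    """Build (times, values) knot arrays for the three angle curves."""
    lm, sh = landmarks, shape
    sf = _snap(lm.stance_fraction, n_points)

    hs = min(sh.heel_strike_flexion, 0.5 * lm.stance_flexion_max + 0.5)
    ms = min(sh.midstance_flexion, hs)
    preswing = ms + sh.preswing_rise * (lm.stance_flexion_max - ms)
    flex_t = [0.0, _snap(sh.stance_peak_time, n_points), _snap(sh.midstance_time, n_points),
              sf, _snap(sh.swing_peak_time, n_points), 1.0]
    flex_v = [hs, lm.stance_flexion_max, ms, preswing, lm.swing_flexion_max, hs]

    pt = _snap(lm.adduction_peak_time, n_points)
    base = sh.adduction_baseline_frac * lm.adduction_peak
    mid_t = _snap(min(sh.midstance_time, pt / 2.0), n_points)
    add_t = [0.0, mid_t, pt, 1.0]
    add_v = [base, sh.adduction_mid_frac * lm.adduction_peak, lm.adduction_peak, base]
    if not 0.0 < mid_t < pt:  # peak too early in the cycle for a mid knot
        add_t = [0.0, pt, 1.0]
        add_v = [base, lm.adduction_peak, base]

    amp = min(sh.stance_rotation_amp,
              0.5 * min(lm.swing_internal_rot_max, lm.swing_external_rot_max) + 0.25)
    ext_t = _snap(lm.stance_fraction + sh.external_rot_delay, n_points)
    int_t = _snap(lm.stance_fraction + sh.internal_rot_delay, n_points)
    rot_t = [0.0, _snap(sh.stance_peak_time, n_points), _snap(sh.midstance_time, n_points),
             sf, ext_t, int_t, 1.0]
    rot_v = [0.0, amp, -amp, 0.0, -lm.swing_external_rot_max, lm.swing_internal_rot_max, 0.0]

    curves = {}
    for name, (t, v) in {
        "flexion": (flex_t, flex_v),
        "adduction": (add_t, add_v),
        "internal_rotation": (rot_t, rot_v),
    }.items():
        t = np.asarray(t, dtype=float)
        v = np.asarray(v, dtype=float)
        if np.any(np.diff(t) <= 0):
            raise LandmarkError(
                f"{name} knot times are not strictly increasing after snapping "
                f"to the {n_points}-point grid: {t.tolist()}"
            )
        curves[name] = (t, v)
    return curves


def _perturb(t: np.ndarray, v: np.ndarray, rng: np.random.Generator,
             variability: float) -> tuple[np.ndarray, np.ndarray]:
    """Jitter knot amplitudes (multiplicative) and phases (additive), seeded.

    Endpoint values share one draw so the cycle stays closed; endpoint times
    stay pinned at 0 and 1.  Draw counts are independent of `variability`, so
    the variability=0 case consumes the same random stream and simply applies
    zero perturbation.
    """
    dv = rng.normal(0.0, _AMP_SD, size=v.size) * variability
    dt = rng.normal(0.0, _PHASE_SD, size=t.size) * variability
    v2 = v * (1.0 + dv)
    v2[-1] = v[-1] * (1.0 + dv[0])
    t2 = t + dt
    t2[0], t2[-1] = 0.0, 1.0
    for i in range(1, t2.size - 1):  # keep strictly increasing inside [0, 1]
        lo = t2[i - 1] + _MIN_KNOT_GAP
        hi = 1.0 - _MIN_KNOT_GAP * (t2.size - 1 - i)
        t2[i] = min(max(t2[i], lo), hi)
    return t2, v2


def generate_subject_kinematics(
    landmarks: GaitLandmarks | None = None,
    profile: SubjectProfile | None = None,
    variability: float = 0.0,
    n_points: int = 101,
    shape: GaitShape | None = None,
) -> GaitKinematics:
    """Generate one subject's knee-angle traces over a normalized gait cycle.

    Parameters
    ----------
    landmarks
        Calibration targets; defaults reproduce the post-reconstruction
        cohort means.  With ``variability=0`` every landmark is attained
        exactly (to the sampling grid) at its stated cycle region.
    profile
        Supplies the per-subject RNG seed; ``None`` uses seed 0.
    variability
        Dimensionless jitter scale (0 = deterministic mean cycle).
    """
    landmarks = landmarks or GaitLandmarks()
    shape = shape or GaitShape()
    landmarks.validate()
    if variability < 0:
        raise ValueError("variability must be >= 0")
    if n_points < 2:
        raise ValueError("n_points must be >= 2")

    seed = profile.rng_seed if profile is not None else 0
    rng = np.random.default_rng(seed)
    x = np.linspace(0.0, 1.0, n_points)
    traces = {}
    for name, (t, v) in _knots(landmarks, shape, n_points).items():
        t2, v2 = _perturb(t, v, rng, variability)
        traces[name] = PchipInterpolator(t2, v2)(x)

    kin = GaitKinematics(
        subject_id=profile.subject_id if profile is not None else "S00",
        flexion=traces["flexion"],
        adduction=traces["adduction"],
        internal_rotation=traces["internal_rotation"],
        stance_fraction=landmarks.stance_fraction,
        n_points=n_points,
    )
    kin.validate()
    return kin


def generate_cohort(
    n_subjects: int = 7,
    landmarks: GaitLandmarks | None = None,
    height_mean: float = 1.63,
    height_sd: float = 0.098,
    mass_mean: float = 72.04,
    mass_sd: float = 15.22,
    generic_height: float = 1.70,
    variability: float = 1.0,
    master_seed: int = 0,
    n_points: int = 101,
    shape: GaitShape | None = None,
) -> list[tuple[SubjectProfile, GaitKinematics]]:
    """Generate a cohort of subjects with sampled anthropometrics.

    Per-subject seeds are derived deterministically from ``master_seed`` so
    any subject is independently reproducible.  ``uniform_scale`` is the
    sampled height over the generic model height (default 1.70 m); note the
    default height SD treats the implausible printed cohort SD of 0.98 m as
    0.098 m.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    state = np.random.SeedSequence(master_seed).generate_state(n_subjects + 1)
    anthro_rng = np.random.default_rng(int(state[0]))
    cohort = []
    for i in range(n_subjects):
        height = float(anthro_rng.normal(height_mean, height_sd))
        mass = float(anthro_rng.normal(mass_mean, mass_sd))
        height = max(height, 0.5 * height_mean)  # guard against absurd draws
        mass = max(mass, 0.5 * mass_mean)
        profile = SubjectProfile(
            subject_id=f"S{i + 1:02d}",
            height=height,
            mass=mass,
            uniform_scale=height / generic_height,
            rng_seed=int(state[i + 1]),
        )
        profile.validate()
        kin = generate_subject_kinematics(
            landmarks, profile, variability=variability, n_points=n_points, shape=shape
        )
        cohort.append((profile, kin))
    return cohort
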