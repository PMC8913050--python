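import numpy as np
import pytest

from aclgait.config import RunConfig
from aclgait.gait_synth import SubjectProfile, generate_cohort, generate_subject_kinematics
from aclgait.tis_sweep import make_tis_grid, run_sweep


@pytest.fixture(scope="session")
def default_config():
    cfg = RunConfig()
    cfg.validate()
    return cfg


@pytest.fixture(scope="session")
def mean_kinematics():
    """The variability-0 (cohort-mean) gait cycle."""
    profile = SubjectProfile("S00", 1.63, 72.04, 1.0, rng_seed=0)
    return generate_subject_kinematics(profile=profile, variability=0.0)


@pytest.fixture(scope="session")
def default_cohort(default_config):
    cfg = default_config
    return generate_cohort(
        n_subjects=cfg.n_subjects,
        landmarks=cfg.landmarks,
        height_mean=cfg.height_mean_m,
        height_sd=cfg.height_sd_m,
        mass_mean=cfg.mass_mean_kg,
        mass_sd=cfg.mass_sd_kg,
        generic_height=cfg.generic_height_m,
        variability=cfg.variability,
        master_seed=cfg.master_seed,
    )


@pytest.fixture(scope="session")
def default_sweep(default_config, default_cohort):
    cfg = default_config
    grid = make_tis_grid(
        cfg.ligament.tibial_insertion, cfg.convention(), cfg.grid_magnitudes_mm
    )
    return run_sweep(
        default_cohort,
        grid,
        spec=cfg.ligament,
        coupling=cfg.coupling(),
        convention=cfg.convention(),
        origin_offset=cfg.origin_offset_cm,
    )


def random_poses(n, seed=0):
    """Uniform random knee poses over a generous anatomical envelope."""
    rng = np.random.default_rng(seed)
    return np.column_stack(
        [
            rng.uniform(-10.0, 120.0, n),  # flexion
            rng.uniform(-20.0, 20.0, n),  # adduction
            rng.uniform(-30.0, 30.0, n),  # internal rotation
        ]
    )
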