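"""Shared fixtures: a small fast simulation config and session-scoped
end-to-end runs reused by the property and acceptance tests."""

from __future__ import annotations

import numpy as np
import pytest

from opusmon.simulate import SimulationConfig, simulate_mmode
from opusmon.mmode import FCMParams, track_lesion_depth
from opusmon.evaluate import depth_recovery_study, study_config


def make_small_config(**overrides) -> SimulationConfig:
    """Short, shallow M-mode acquisition for fast unit tests: 4.3 mm
    window, 10 s timeline, 200 A-lines."""
    base = dict(
        n_samples=700,
        prf=20.0,
        surface_depth=0.5,
        fibre_tip_depth=1.5,
        laser_on_time=2.0,
        laser_duration=6.0,
        post_laser_time=2.0,
        lesion_max_extent=1.2,
        lesion_growth_tau=1.5,
        rng_seed=0,
    )
    base.update(overrides)
    return SimulationConfig(**base)


@pytest.fixture
def small_config():
    return make_small_config()


@pytest.fixture(scope="session")
def recovery_study():
    """Ten seeded end-to-end procedures with truth extents spanning the
    3.3-8.3 mm range."""
    return depth_recovery_study(np.linspace(3.3, 8.3, 10), seed=0)


@pytest.fixture(scope="session")
def single_procedure():
    """One full-scale monitoring procedure with all intermediate artifacts."""
    cfg = study_config(6.0, rng_seed=42)
    record, truth = simulate_mmode(cfg)
    image, mask, trace = track_lesion_depth(
        record,
        laser_on_s=cfg.laser_on_time,
        laser_off_s=cfg.laser_on_time + cfg.laser_duration,
        fcm_params=FCMParams(seed=42),
        glm_fit_depth_mm=cfg.surface_depth + 0.5,
    )
    return {
        "config": cfg,
        "record": record,
        "truth": truth,
        "image": image,
        "mask": mask,
        "trace": trace,
    }
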