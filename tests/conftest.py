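import numpy as np
import pytest

from spiralcine.phantom import PhantomSpec, make_coil_maps, make_cine_phantom
from spiralcine.trajectory import build_schedule, design_spiral


@pytest.fixture(scope="session")
def arms13_small():
    """13 variable-density arms at desk scale (matrix 48, FOV 300 mm)."""
    return design_spiral(13, 48, fov_m=0.3)


@pytest.fixture(scope="session")
def arms13_96():
    return design_spiral(13, 96, fov_m=0.3)


@pytest.fixture(scope="session")
def breath_hold_schedule():
    """Nine heartbeats at 60 bpm, 48 ms frames (Ncine = 21)."""
    return build_schedule("breath_hold", t_rr_ms=1000.0, n_heartbeats=9,
                          frame_duration_ms=48.0)


@pytest.fixture(scope="session")
def phantom_small():
    spec = PhantomSpec(matrix=48, fov_mm=300.0)
    cine, masks = make_cine_phantom(spec, 8)
    return spec, cine, masks


@pytest.fixture(scope="session")
def coil_maps8_48():
    return make_coil_maps(8, 48, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def trained_score_64():
    """Toy score network trained on 64x64 phantom frames (2000 DSM steps).

    Shared between the training-progress and reconstruction tests; the
    training run is the dominant fixture cost and is built once per session.
    """
    from spiralcine.diffusion import DiffusionSchedule, TrainConfig, train_score

    spec = PhantomSpec(matrix=64)
    cine, _ = make_cine_phantom(spec, 16, frame_duration_ms=60.0)
    frames = cine.frames / np.abs(cine.frames).max(axis=(1, 2), keepdims=True)
    schedule = DiffusionSchedule(0.01, 378.0, 2000)
    cfg = TrainConfig(
        n_steps=3000, warmup_steps=500, channels=24, n_hidden=3, seed=3
    )
    return train_score(frames, schedule, cfg), frames
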