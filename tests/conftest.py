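import numpy as np
import pytest

import ptystream as ps


@pytest.fixture(scope="session")
def full_geometry():
    return ps.make_geometry(8.0, 256, 75e-6, 3.67)


@pytest.fixture(scope="session")
def scaled_scene():
    """Small (64 px frames) scene shared across engine/compare tests."""
    return ps.build_scene(ps.scaled_scene_config(step_px=4.0, n_points=60))


@pytest.fixture(scope="session")
def scaled_noiseless_dataset(scaled_scene):
    return ps.simulate_scene_dataset(scaled_scene, noiseless=True)


@pytest.fixture(scope="session")
def scaled_noisy_dataset(scaled_scene):
    return ps.simulate_scene_dataset(scaled_scene, seed=7)


@pytest.fixture(scope="session")
def star_crop(scaled_scene):
    """A structured complex image (central star region) for metric tests."""
    obj = scaled_scene.object_truth.field
    lo = obj.shape[0] // 2 - 24
    return obj[lo : lo + 48, lo : lo + 48].copy()


@pytest.fixture(scope="session")
def truth_state(scaled_scene, scaled_noiseless_dataset):
    """Engine state initialised exactly at the ground-truth solution."""

    def _build(config=None):
        config = config or ps.EngineConfig()
        initial = ps.InitialEstimates(
            object=scaled_scene.object_truth.field.astype(np.complex64),
            probe=scaled_scene.probe_truth.field.astype(np.complex64),
        )
        state = ps.initialize_state(scaled_noiseless_dataset, initial, config)
        ps.activate_frames(state, scaled_noiseless_dataset.n_frames)
        return state

    return _build
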